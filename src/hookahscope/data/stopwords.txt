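a
about
above
after
again
against
all
am
an
and
any
are
as
at
be
because
been
before
being
below
between
both
but
by
did
do
does
doing
down
during
each
few
for
from
further
had
has
have
having
he
her
here
hers
herself
him
himself
his
how
i
id
if
ill
im
in
into
is
it
its
itself
ive
just
me
more
most
my
myself
no
nor
not
now
of
off
on
once
only
or
other
our
ours
ourselves
out
over
own
same
she
shes
should
so
some
such
than
that
thats
the
their
theirs
them
themselves
then
there
these
they
theyre
this
those
through
to
too
under
until
up
very
was
we
were
weve
what
when
where
which
while
who
whom
why
will
with
you
youd
youll
your
youre
yours
yourself
yourselves
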