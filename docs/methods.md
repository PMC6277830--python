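# Methods

## The analysis model

`hookahscope` treats topic surveillance as deterministic rule evaluation over
a prepared corpus. Let a corpus of short posts be tracked on one collection
term ("hookah"). After exclusion filtering, each post is reduced to a
normalized lemma sequence; each of eight topics owns a keyword lexicon of
unigrams and bigrams in that same normalized space; and a post carries a
topic label iff at least one of the topic's unigrams appears as a whole
token, or one of its bigrams as a contiguous token pair. Matching is never
substring-based ("hit" cannot fire inside "white") and is multi-label by
construction. Prevalence of a topic is its labeled count over the full
analytic corpus (not over covered posts); coverage is the share of posts
with at least one label; overlap (i, j) is the count of posts labeled with
both topics. All percentages are `100·count/N` rounded half-up to two
decimals, uniformly.

Key modeling assumptions: the collection term itself is not a keyword
(every post contains it, so it would be a degenerate 100% topic);
person-tagging is detected solely through the canonical `@username` token;
and lexicons are stored lemmatized because classification operates on the
lemmatized sequence.

## Filtering

Three exclusions, in order: retweets (platform flag OR case-sensitive
`RT @` text prefix — reshared content duplicates the original signal);
non-English posts (by the record's language code; posts coded `und` are kept
unless the caller supplies a detector hook, so results never silently depend
on a third-party detector); bot-authored posts. Bot scoring is an upstream
input carried on the record as a probability in [0, 1]; removal is
account-level (every tweet of a flagged account drops) at a default
threshold of 0.5, the conventional midpoint of bot-probability scorers.
Account-level removal is the stricter of the two possible readings of
"tweets from accounts identified as social bots" and is the package's
choice. No text-level deduplication is performed: "unique posts" is read as
unique tweet ids. Each filter is idempotent, order-preserving, and a subset
operation.

## Normalization

Six steps in fixed order: mention canonicalization → lowercase →
non-printable/emoji removal → punctuation removal → stop-word removal →
lemmatization. Mentions are canonicalized first so punctuation stripping
cannot destroy the `@` marker. Apostrophes are deleted within words by
default (`don't` → `dont`) so the dislike bigram "dont hookah" survives as a
matchable pair; a `split` policy is available. Hashtags lose their symbol
(`#hookah` → `hookah`) since the tracked term and its hashtag form are one
collection term. The stop list is a packaged ~130-word English function-word
list (versioned in the repo so results are library-independent); negation
contractions (`dont`, `cant`) are deliberately excluded from it, and the
list is re-applied after lemmatization so the no-stop-word output invariant
holds unconditionally.

The lemmatizer is an in-package dictionary-plus-suffix-rule engine: a small
irregular table (bought→buy, used→use, …), Porter-style handling of -ing/-ed
(undoubling, final-e restoration on short CVC stems, an -ing-noun exception
list), and conservative plural rules. It satisfies the cats/cat's→cat
contract, leaves every packaged keyword a fixed point, and is pinned by a
golden-table test. It is not a full morphological analyzer; rare forms may
stem imperfectly, which only perturbs frequency tables, never the planted
keyword matching used in validation.

## Lexicons and expansion

The packaged default is the eight-topic set with the published common-word
lists, stored normalized; per-keyword provenance distinguishes `seed` terms
from `expanded-accepted` ones (the on-disk format does not persist
provenance; re-read files default to seed). The lists are exemplar lists,
not exhaustive vocabularies.

Expansion trains skip-gram embeddings with negative sampling — implemented
in numpy inside the package, strictly sequential and seeded so training is
bit-reproducible. Defaults: dimension 100, window 5 (per-position reduced
window, as in standard skip-gram training), min_count 5, 5 epochs, 5
negative samples from the unigram^0.75 noise distribution, learning rate
0.025 decayed linearly. For each seed unigram in the vocabulary, up to
top_k=20 neighbors with cosine ≥ 0.5 are proposed, excluding stop words and
existing lexicon members. Bigram seeds are not queried (phrase induction is
out of scope); bigram additions arrive through review rows. Review is
mandatory and auditable: a TSV worksheet (topic, seed, candidate, cosine,
decision) is edited by hand and re-ingested; only `accept` rows are folded
in, growth is monotone, and seeds are never removed.

## Synthetic corpora and what they show

The generator emulates the tracked stream with exact ground truth. Every
post contains the collection term; topic labels are drawn per-topic
Bernoulli at planted rates (defaulting to the published prevalence profile:
0.2158, 0.2020, 0.1812, 0.1167, 0.1095, 0.0937, 0.0166, 0.0059), with an
optional pairwise joint-draw boost (default: buying–appeal at 0.025, the
pair whose observed overlap most exceeds independence). Each drawn topic
injects one uniformly chosen keyword in a randomized surface form (mixed
case, trailing punctuation, `@handle` for person tagging) that is verified
at generation time to normalize back to the lexicon form. Filler is a
pseudo-word vocabulary built to be disjoint — after lemmatization — from
every keyword, stop word, and the collection term. Retweets are `RT @user `
plus an earlier original's text (55%), non-English originals carry non-`en`
codes (10%), and bot accounts (35% of users) score ≥ 0.90 vs ≤ 0.10
otherwise; these rates reproduce the attrition shape of the original
collection (about one-third of the raw stream surviving to the analytic
sample, roughly half of the post-language sample removed as bots). Default
account structure is ~2 tweets per user.

Because keyword injection is the only source of topic signal, the full
filter → normalize → classify chain recovers the planted prevalence and
overlap *exactly*, and filter survivors equal the planted clean subset
exactly — these are counting identities, not statistical statements, and the
test suite asserts them at n = 50,000. What passing does **not** show:
robustness to real linguistic variation (slang, misspellings, sarcasm,
keywords the lexicons miss) or to bot-score noise near the threshold; on
real corpora the rule classifier inherits all the usual limitations of
keyword matching.

## Numerical and design choices

- Rounding: half-up to two decimals everywhere (`decimal`-based), matching
  the published arithmetic convention. Three published percentages are
  inconsistent with their own printed fractions at two decimals; the package
  follows the fractions.
- Ranking ties (prevalence tables, n-gram top-k, neighbor lists) break
  lexicographically for determinism.
- Degenerate inputs: empty texts are invalid records; texts that normalize
  to nothing are valid and yield empty token tuples; empty corpora are valid
  everywhere except embedding training and prevalence denominators.
- Problem sizes: the shipped study uses a 50,000-post corpus (≈13k clean),
  which makes every planted-rate comparison well-resolved (3 binomial
  standard errors ≈ 1 percentage point at the largest rates) while the whole
  analysis runs in seconds.
- The embedding demonstration corpus plants one synonym pair
  ("want"/"crave") in interchangeable contexts against a control token in
  disjoint contexts; recovery of the held-out synonym among the appeal
  topic's candidates is the expansion stage's acceptance check.

## Known limitations

Single collection term; English only; no text deduplication beyond retweet
removal; no probabilistic classification, sentiment, or per-user analysis;
the lemmatizer and stop list are pinned package artifacts rather than
linguistic ground truth; the synthetic generator does not model user
networks, temporal bursts, or realistic grammar.
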