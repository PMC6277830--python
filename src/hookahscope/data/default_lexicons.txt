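# Default eight-topic hookah lexicons, stored in normalized (lowercase,
# lemmatized, apostrophe-deleted) form. Keywords are whole-token unigrams or
# contiguous-token bigrams. "hookah" itself is never a keyword: every post in a
# hookah-tracked corpus contains it.
[topic: Person Tagging]
@username
[topic: Promotional or Social Events]
bar
food
friday
lounge
night
party
saturday
[topic: Appeal or Abuse Liability]
crave
enjoy
everyday
get
like
love
need
want
[topic: Hookah Use Behavior]
hit
pass
puff
smoke
use
[topic: Polysubstance Use]
alcohol
beer
blunt
cig
cocktail
drink
juul
liquor
margarita
vape
vodka
weed
wine
[topic: Buying or Selling]
buy
order
pay
purchase
sell
[topic: Flavors]
apple
blueberry
candy
cinnamon
flavor
fruit
grape
guava
mango
mint
orange
peach
watermelon
[topic: Dislike of Hookah]
dislike
dont hookah
hate
quit
quit hookah
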