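# Default topic lexicons: eight topics of Swisher-related Twitter chatter,
# each a set of unigram/bigram keywords. Entries are run through the same
# normalization convention as tweet text when loaded, so surface variants
# ("Don't", "White-owl", "Bought") land on the matching lemma.
# Order fixed: most to least prevalent, the order the overlap matrix uses.
Person tagging:
  unigrams: ["@person"]
Flavors:
  unigrams: [cherry, flavor, grape, mango, peach, pineapple, pumpkin, strawberry]
Swisher use:
  unigrams: [hit, pass, puff, smoke, try]
Cannabis use:
  unigrams: [blunt, gut, marijuana, roll, weed]
Appeal:
  unigrams: [crave, enjoy, like, love, need, want]
Dislike:
  unigrams: [damn, "don't", fuck, "no", shit]
Purchases:
  unigrams: [buy, bought, grab, pay]
Cigar comparison:
  unigrams: [backwoods, white-owl]
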