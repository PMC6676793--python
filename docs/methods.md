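# Methods

`cigartopics` implements a dictionary-based (rule-based) surveillance
pipeline for brand-related chatter on Twitter, of the kind used in
infodemiology to characterize tobacco-product conversations. The target
design is a year-long corpus of public posts containing the brand term
"swisher" (the market-leading little-cigar brand): posts are filtered to
an analytic sample, normalized to lemma sequences, classified into eight
topics by keyword lexicons, and summarized as a prevalence/overlap
matrix. Because such corpora are private platform data and cannot be
redistributed, the package pairs the pipeline with a synthetic-corpus
generator whose planted structure makes every stage verifiable.

## Pipeline

### 1. Ingestion and exclusion filtering (`cigartopics.ingest`)

Corpora are read from JSON-lines or CSV (columns `tweet_id, text, lang,
is_retweet, author_id, timestamp`). Four exclusion rules plus the
keyword-containment requirement produce the analytic sample:

1. **non-English** — trust the corpus `lang` field; a tweet with empty
   `lang` goes through a pluggable detector hook (default: accept as
   English; a stop-word-overlap heuristic is provided).
2. **retweet** — the `is_retweet` flag. Quote-tweets are not treated
   specially; whether they count as retweets is the upstream flag's
   decision.
3. **bot** — list-based: the caller supplies known bot account ids.
   Behavioral bot *detection* is outside this package's scope; the list
   is the integration point for any external detector.
4. **surname** — a heuristic: the keyword flagged as a person's surname
   when immediately preceded by a capitalized given name from a shipped
   list ("Interview with Kara Swisher"). No published procedure exists
   for this step; the heuristic is documented as such and can be
   disabled (`surname_filter=False`).
5. **no-keyword** — the keyword must occur at a token start,
   case-insensitively, as a token or token prefix (so possessives and
   plurals count).

The rules are applied in that fixed order so each excluded tweet is
counted under exactly one reason and the filter report always balances
(`n_retained + Σ exclusions = n_input`). The order is a reporting
convention only; the retained set is order-independent.

### 2. Normalization (`cigartopics.normalize`)

The chain runs in a fixed stage order: URL removal, @-mention
canonicalization (any token-initial `@handle` becomes the common token
`@person`), hashtag deletion, lowercasing, punctuation stripping,
non-printable/emoji removal, whitespace tokenization, stop-word removal,
lemmatization. Mentions and URLs must be handled before punctuation
stripping destroys their patterns; that constraint fixes the order.
Details that matter:

- **In-word apostrophes and hyphens collapse the word** rather than
  splitting it: `don't → dont`, `White-Owl → whiteowl`,
  `Swisher's → swishers → swisher`. This keeps multi-character lexicon
  entries one token.
- **Hashtags are deleted wholesale** by default; a config flag
  (`keep_hashtag_words=True`) retains the bare word instead, recording
  a genuine ambiguity in how such pipelines treat tags.
- **Stop words** come from a versioned snapshot shipped in the package,
  not from a library at run time, so results are stable across
  installations. The snapshot deliberately excludes negations ("no",
  "don't") and appraisal verbs ("like", "love", "need", "want") because
  the topic lexicons key on them — a standard library stop list would
  silently erase the Dislike and Appeal topics. A test asserts the
  snapshot is disjoint from every default lexicon lemma. Stop words are
  filtered again after lemmatization so no base form in the list
  survives (e.g. "cans" → "can").
- **Lemmatization** is a deterministic rule system: an irregular-form
  table (`bought → buy`), then suffix rules (`-ies/-ing/-ed/-es/-s`)
  whose stripped candidates are validated against a shipped vocabulary
  (with e-restoration and consonant de-doubling: `smoking → smoke`,
  `hitting → hit`); unknown tokens pass through unchanged. The two data
  files are versioned with the package and the behavior is locked by
  golden-file tests. This trades recall on rare inflections for exact
  reproducibility — acceptable because classification only needs the
  lexicon lemmas and their common inflections to land correctly, and
  the vocabulary pins exactly those.

### 3. Classification (`cigartopics.classify`)

A tweet's n-gram set is its token set plus all adjacent ordered bigrams,
formed **after** stop-word removal (so "smoke a swisher" yields the
bigram `(smoke, swisher)`). A tweet is assigned every topic whose
lexicon shares at least one unigram or bigram with it — multi-label, no
scoring, no tie-breaking, exact lemma match only. Lexicon entries are
passed through the same normalization chain (minus stop-word removal)
at load time, so lexicon and corpus always share one lemma convention.

The shipped default is the eight-topic keyword set for Swisher chatter —
Person tagging (`@person`), Flavors, Swisher use, Cannabis use, Appeal,
Dislike, Purchases, Cigar comparison. Keyword lists of this kind are
never exhaustive, so lexicons are fully user-configurable (YAML mapping
`topic -> {unigrams, bigrams}`); the default set is the starting point,
not a claim of completeness. `ngram_frequencies` exposes the
word-frequency exploration step such topic sets are built from.

A note on one boundary case: the example post "Hey! @person Try
Swisher's new grape flavor" is assigned Person tagging and Flavors — and
also Swisher use, because "try" is itself a Swisher-use keyword and the
any-keyword rule admits no exceptions. The pipeline applies the rule
uniformly.

### 4. Aggregation (`cigartopics.aggregate`)

The overlap matrix is lower-triangular: cell (i,i) counts tweets
assigned topic i, cell (i,j) tweets assigned both i and j. Overlap cells
are pairwise intersections regardless of other labels — a tweet with
three topics increments three diagonal and three pairwise cells; that is
the only structure a pairwise matrix can hold. Percentages are
**round-half-up** to two decimals (`decimal.Decimal`, not banker's
rounding): this convention reproduces a printed percentage exactly from
its count and sample size. Coverage is the fraction of the analytic
sample with at least one topic; tweets absent from the assignment
sequence count as unclassified rather than erroring, which supports
streaming pipelines. Note coverage (a union) is **not** recoverable from
the matrix (marginals and pairwise intersections only); it is reported
separately.

## Synthetic corpora (`cigartopics.synthetic`)

The generator emulates the statistical structure the classifier sees,
not linguistic realism — no grammar, no slang drift, no topic keywords
in contexts that reverse their meaning. Consequences: passing tests
demonstrate that the pipeline recovers whatever keyword structure is
present, exactly; they do not demonstrate that the eight keyword lists
capture real-world topic semantics, which is a lexicon-curation question
outside any automated check.

Per clean tweet, a topic set is sampled, then text is built from one
uniformly chosen lexicon keyword per topic (mention keywords realized as
random `@handles`, bigrams as adjacent words), the mandatory corpus
keyword, and 3–8 neutral filler words, shuffled, with light punctuation,
emoji, URL and hashtag decoration to exercise the normalizer. The filler
vocabulary is a fixed shipped list verified disjoint (after
normalization) from every default lexicon lemma, so clean-corpus
recovery is exact — classifier correctness is thereby separated from
lexicon-collision effects, which get their own adversarial test in which
a colliding filler word must surface as false-positive prevalence.

**Topic coupling.** Independent Bernoulli sampling cannot reproduce the
large pairwise overlaps real topics show, so designated pairs can be
coupled by a mixture: with probability `b` (the pair's boost weight) the
pair is forced jointly present; otherwise every topic is drawn
independently with adjusted probability `q_T = (p_T − B_T)/(1 − B_T)`,
where `B_T` sums the boosts of pairs containing `T`. This preserves
every planted marginal exactly in expectation and requires `B_T ≤ p_T`
(validated, with the offending pair named). `boost_for_joint` inverts
the single-pair case by bisection to hit a target joint probability.
Negative coupling (a joint below independence) is not representable and
is rejected.

**Contamination.** Each tweet draws one category — retweet, non-English,
bot, surname, or clean — so contamination types are mutually exclusive
by construction and the filter report can be checked against ground
truth *exactly*, not statistically. Non-English tweets are French filler
with `lang="fr"`; surname tweets use the "FirstName Swisher" pattern and
carry no topic keywords; retweet and bot tweets carry normal topic
structure (they are realistic posts excluded for other reasons).
Ground-truth marginal and pairwise counts are tallied over clean tweets
only, matching what the analytic sample should contain.

**Randomness.** One `random.Random(seed)` stream drives everything; no
global state. Identical spec + seed gives a byte-identical corpus, and
the stdlib generator's stability makes that hold across platforms.

## Default study conditions (`study_spec`)

The shipped study-scale conditions mirror the published analysis this
pipeline design comes from: 111,263 input tweets; the eight published
marginal prevalences (32.77, 20.96, 17.44, 6.26, 5.92, 3.53, 1.90,
1.64 %); the strongest published overlap (Flavors–Swisher use, 12.87 %)
planted via one boosted pair (b ≈ 0.124 by `boost_for_joint`); and
quantities the publication reports only in aggregate, fixed once as
package choices:

- **Contamination split**: only the total reduction to 81,333 retained
  tweets (73.10 %) is published, not per-rule counts. Defaults: retweet
  0.15, non-English 0.06, bot 0.04, surname 0.019 (sum 0.269). Retweets
  dominate by design — they typically dwarf the other exclusions in
  streaming-API keyword corpora.
- **Author pool**: 1.007 × n, which under uniform authorship makes the
  expected unique-author count among retained tweets match the
  published 57,838-of-81,333 ratio.
- **Second published overlap not planted**: Flavors–Person tagging is
  printed at 5.57 %, *below* the 6.87 % the planted marginals imply
  under independence; a mixture boost cannot plant negative coupling,
  so this pair is left independent and the generated overlap sits near
  6.9 %.
- **Coverage is emergent, not planted**: under these conditions the
  union coverage comes out near 58–59 %, versus a published 62.95 %.
  The gap is expected: the real corpus's dependence structure beyond
  one pairwise coupling is unpublished and cannot be reconstructed from
  marginals plus one joint. The pipeline reports coverage as computed.

## Problem sizes used in checks

The test suite runs the full pipeline on corpora of 200–20,000 tweets;
the statistical parameter-recovery check uses clean 20,000-tweet corpora
across 20 seeds, asserting each recovered prevalence within 3 binomial
standard errors of its planted value (at most one exceedance across the
160 comparisons, the 3-SE coverage expectation). The analysis drivers
and the acceptance script run the full 111,263-tweet study scale, which
completes in seconds.

## Known limitations

- The surname and language rules are heuristics; on real data they
  would need validation against manual review.
- The lemmatizer's validation-vocabulary design means inflections of
  words outside the vocabulary fall back to plural-stripping or
  identity; this is intentional determinism, not full morphology.
- Non-ASCII text is dropped at the non-printable stage; accented
  English loanwords lose their accented characters.
- The generator's uniform keyword choice and uniform authorship are
  simplifications; real keyword frequencies and author activity are
  heavy-tailed. Marginal-recovery checks are insensitive to this;
  per-keyword frequency checks would not be.
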