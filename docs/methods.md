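# Methods

## Problem and data model

The pipeline analyses public short posts ("tweets") in which users
self-disclose loneliness — an explicit or implied attribution of the
feeling to the poster — and asks how disclosure volume, vocabulary and
received engagement differ between female- and male-presenting authors,
particularly around the first COVID-19 lockdown (March 15 – June 1, 2020).
Each post record carries the text, an English-language tag, timestamps,
four response counts (likes, retweets, replies, quotes), retweet/URL
markers, and a snapshot of the author profile at posting time (free-form
display name, account creation date, cumulative status count). All day
boundaries are UTC.

Real collections of this kind cannot be shipped, so the package includes a
generator that emulates the collection's statistical structure with known
ground truth. Everything the tests establish is therefore *parameter
recovery under the generator's assumptions*; see "What the synthetic data
does not show" below.

## Synthetic corpus generator

**Posting process.** Disclosing users per gender per day are Poisson with
intensity `base_daily_rate` before the lockdown date and
`base_daily_rate × lockdown_multiplier` from it on (default 1.8, matching
the near-doubling a lockdown produces). Each selected user posts once
that day; timestamps are uniform within the UTC day. Configurable outage
dates are dropped after generation, as a stream outage would drop them.

**Text.** Posts are bags of words: one collection keyword ("lonely" or
"loneliness"), two class cue tokens, one planted marker word, and 3–8
filler tokens from a shared pseudo-word vocabulary (default 500 words)
mixed with common stopwords. Disclosures and keyword-noise posts use
disjoint cue vocabularies, which makes the disclosure classification task
linearly separable — deliberately, so the harness can be validated at
ceiling. No grammar is modelled; every downstream operation except
tokenization is order-insensitive, and tokenization has dedicated
fixtures.

**Planted lexical markers.** Each gender owns `marker_words_per_gender`
(default 20) marker words. Marker slots are allocated by stratified
quota: own-gender markers carry `marker_effect` (default 5) times the
weight of other-gender markers, quotas are rounded by largest remainder
and randomly permuted over posts. Stratification realizes the planted
usage-probability ratio tightly at modest corpus sizes, where iid draws
would leave the per-marker frequency ratio dominated by sampling noise;
placement within posts remains random.

**Contaminants.** Lyric posts (verbatim phrases from a packaged
*synthetic* lyric list — the file is labelled synthetic because no real
lyric list is shipped), URL posts, retweets and keyword-noise posts are
layered on top of the disclosure stream at per-day Poisson rates chosen so
their expected share of the total stream equals the configured fractions
(defaults 0.02 / 0.08 / 0.08 / 0.10).

**Spam.** A `spam_fraction` of accounts (default 0.05) is spam, split
between two planted mechanisms: high-rate accounts whose profile-implied
posting rate (status count ÷ account age) is drawn at or above
`spam_rate_per_day` (default 30, and never below the 16/day screen
boundary), and "deleter" accounts with moderate rates whose cumulative
status count strictly decreases across their observed posts. The
"emission" of a spam account is its profile-implied rate, not its volume
in the corpus: the screen operates on profile fields, and literal 16+
posts/day in-corpus would drown the disclosure stream. Spam posts read as
disclosures (that is the phenomenon the rate screen exists for) and are
scheduled on non-outage days so planted spam remains observable. Genuine
accounts draw rates uniformly in [0.2, 7.5] posts/day — at most half the
screen boundary — so the planted separation makes filter exactness a
well-defined target.

**Names.** Display names are "Given X." with the given name drawn from
the packaged dictionary: single-gender names matching the account's
gender, except an `ambiguous_name_fraction` (default 0.10) drawn from
names attested for both genders. Spam accounts keep unambiguous names so
the gender stage does not pre-empt the activity filter.

**Engagement.** Counts are zero-inflated discrete power laws
(`rng.zipf(engagement_tail_exponent)`, default exponent 2.5) with
per-metric zero probabilities 0.45 (likes), 0.60 (replies), 0.70
(retweets), 0.85 (quotes), chosen so medians of 0 — and 1 for likes — are
the typical outcome, matching the qualitative shape of real response
distributions. Both genders share one generating law, so the
engagement-comparison tests can check type-I calibration.

**Determinism.** All randomness flows through one
`numpy.random.Generator` seeded from the config; a config + seed pair
reproduces the corpus byte for byte.

## Analysis stages: key choices

- **Exclusion order** in the rule filter is fixed (URL → retweet → lyric →
  empty-after-cleaning) so reason counts are reproducible; "empty after
  cleaning" means empty after URL removal and deletion of all
  non-alphanumeric characters.
- **Classifier**: linear SVM (`LinearSVC`, C=1) over token counts from the
  shared tokenizer; stratified 5-fold cross-validation with pooled
  out-of-fold predictions for precision/recall, then a refit on all data.
  The fold assignment of every example is kept in the model metadata so
  the no-leakage property is checkable.
- **Cohen's κ** is computed from the closed form
  `(p_o − p_e)/(1 − p_e)` with `p_e` from marginal products; it returns
  NaN when `p_e = 1` (both annotators constant on one category), where κ
  is undefined.
- **Gender inference** uses the first whitespace token whose
  decoration-stripped remainder is pure ASCII letters; tokens containing
  digits are skipped. Honorifics are not special-cased ("DR. Anya" →
  candidate "dr" → unknown), a documented limitation of the first-token
  rule. Ambiguity is strict: any name attested for both genders is
  discarded, with no frequency thresholding across sources.
- **Posting rate** divides the latest observed status count by whole days
  from account creation to that observation, clamped to ≥ 1 day; the
  16/day boundary is closed (exactly 16 is flagged). The decreasing-count
  rule fires on any strict decrease between ordered observations.
- **Volume** counts unique users per UTC day. The comparison windows are
  the 7 days strictly before the split date and the 7 days from it on
  (the split day belongs to "post"). The t-test is the Welch
  (unequal-variance) variant, one-sided for an increase. When both
  windows are constant and equal the test is degenerate and p is reported
  as 0.5. Interpolated outage values are left as reals since they feed
  means, not counts.
- **Odds ratios** use additive smoothing α = 1. Ranking applies a minimum
  own-gender count floor (default 5); without it, hapax words with zero
  opposite-gender count dominate any top-k list. Ties break by higher
  own-gender count, then lexicographically. The reverse contrast is the
  exact reciprocal. Co-occurrence is set-based within a post (a post
  containing a word twice still contributes one), matching "number of
  posts in which the two words occur". Network exports carry
  word/OR/size/weight attributes only; force-directed layout is
  presentation and is left to downstream tools.
- **Engagement comparisons** are two-sided Mann-Whitney with tie
  correction (mandatory given zero-heavy counts); exact enumeration is
  used only for small tie-free samples (both n ≤ 20), the tie-corrected
  normal approximation otherwise. Fully tied data carry no ordering
  information and report U = n₁n₂/2, p = 1.

## Problem sizes

The default test and analysis corpora are desk-scale by design: the
shipped analysis run uses 1,600 users over 86 days (~17k posts); marker
recovery is validated at ~20,000 disclosures per gender; detection power
and type-I calibration use 200 and 1,000 replicates of the 7+7-day window
comparison at intensity 1,000/day. All sizes are configurable through
`GeneratorConfig`.

## What the synthetic data does not show

The generator validates the *machinery*, not the sociolinguistics: real
disclosures have grammar, sarcasm, topic drift and annotator disagreement;
real gendered vocabulary differences are far smaller and noisier than a
planted 5× ratio; real spam is adversarial rather than rate-separated;
real names carry frequency information this pipeline deliberately ignores.
Classifier metrics at ceiling on separable synthetic text say nothing
about accuracy on real annotations. Non-binary gender cannot be inferred
from binary name registries at all — a structural limitation, not a
sampling one.
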