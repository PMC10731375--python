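# lonelytext

Analysis pipeline for studying **gendered self-disclosure of loneliness on
social media**: who says "I am lonely" in public, how that volume reacted
to the first COVID-19 lockdown, which words distinguish female- from
male-authored disclosures, and how much response such posts receive.

Platform data of this kind cannot be redistributed, so the package is
driven by a first-class **synthetic corpus generator** that plants every
property the analysis relies on — gendered lexical markers with a known
usage ratio, a step change in daily posting intensity at a lockdown date,
spam accounts, contaminant posts (lyrics, URLs, retweets, keyword noise),
ambiguous profile names, and long-tailed engagement counts — together with
a ground-truth record, so each stage can be validated by parameter
recovery.

## Pipeline

1. **Disclosure filtering** (`disclosure_filter`) — keyword/language
   prefilter ("lonely", "loneliness"; deliberately not "alone"), rule
   exclusions (URL posts, retweets, known lyric phrases, posts empty after
   stripping special characters), and a cross-validated linear SVM over
   token counts. Annotation agreement is quantified with Cohen's κ.
2. **Gender inference** (`gender_inference`) — first name token matched
   against merged `name,gender[,count]` dictionaries; users without an
   unambiguous single-gender attestation are discarded.
3. **Spam screen** (`activity_filter`) — accounts posting ≥ 16 times/day
   over their lifetime (cumulative status count ÷ account age), or whose
   status count decreases within the dataset, are removed.
4. **Volume** (`volume_timeseries`) — daily *unique users* per gender,
   linear interpolation over collection outages, one-sided Welch t-test on
   the weeks around the lockdown date, Pearson correlation between the two
   gender series, Mann-Whitney on posts per account.
5. **Lexical contrast** (`lexical_contrast`) — smoothed odds ratio of each
   word *w* between the groups,

   `OR(w) = (Wf(w)+α)(Wm(¬w)+α) / ((Wm(w)+α)(Wf(¬w)+α))`, α = 1,

   top-100 lists per direction and period (pre-COVID year vs. first
   lockdown, 2020-03-15 to 2020-06-01), co-occurrence networks (edge
   weight = posts containing both words) exported as GraphML/GEXF with
   OR-proportional node sizes, and seeded per-word tweet sampling.
6. **Engagement** (`engagement_stats`) — likes/retweets/replies/quotes per
   gender, compared with tie-corrected two-sided Mann-Whitney tests.

## Worked example

The numbered scripts under `analysis/` run the whole study on a generated
corpus (about 17k posts from 1,600 users over 86 days, lockdown multiplier
1.8) and write tables under `results/`:

```sh
python analysis/01_generate_corpus.py
python analysis/02_filter_disclosures.py
...
python analysis/07_engagement_analysis.py
```

Output from a run (seed 20200315):

```
kept 12065/16684 posts as self-disclosures
classifier CV precision=1.000 recall=1.000
female=5470 male=5352 dropped_unknown=1243 (10.3% of disclosures)
flagged 128 accounts, removed 316 posts (sensitivity=1.0, specificity=1.0)
female: 47.9 (sd 3.4) -> 81.1 (sd 10.9) unique users/day, one-sided Welch p=5.31e-05
gender series Pearson r = 0.836
  planted-marker recovery in top-100: 100%
like_count: female median 1 (mean 1.18), male median 1 (mean 1.03), MW p=0.112
disclosures with zero replies: 60.6%
```

Reading: the rule and classifier stages cut the stream to disclosures (the
classifier is perfect here because the synthetic cue vocabulary is
separable — real text is harder); about one user in ten is dropped for an
ambiguous or unmatched name; the spam screen removes exactly the planted
spam accounts; daily disclosing users jump by ≈ 1.7× at the lockdown date
(highly significant one-sided Welch test); both genders' top-100
odds-ratio words recover all planted markers; and most disclosures get
little to no response (median 0 for everything except likes).

The same pipeline is available as a CLI
(`lonelytext generate|filter|infer-gender|despam|timeseries|contrast|engagement`);
a fixed seed reproduces every output byte for byte.

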