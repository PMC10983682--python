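# Methods

## The screening procedure

The package implements dictionary-based phenotyping of admission notes
against the six SPICT-LIS general indicators. Per note the pipeline is
deterministic and purely rule-based:

```
tokenize → find_mentions(profile) → assign_polarity → evaluate_indicators → classify
```

A patient screens positive under a profile when at least `min_general`
(default 2) general indicators are met and a clinical indicator is met.
For a cancer-registry cohort the confirmed malignant diagnosis is taken as
the clinical indicator, so `clinical_met` defaults to the record's registry
flag; both the flag and `min_general` are configurable. Indicator status is
existence-based — one affirmed mention suffices, repeated mentions carry no
weight — because nothing in the screening rule involves counts or severity.

### Tokenization

Ordinary (whitespace-delimited) script splits on whitespace; punctuation
characters become single-character `punct` tokens. Unsegmented script is
segmented by greedy left-to-right longest match against the dictionary
(maximal matching): at each position take the longest surface that matches,
else emit a one-character `unknown` token. Which letter runs are routed to
maximal matching is decided by the lexicon, not by a hard-coded script
list: the characters of its `unsegmented`/`either` surfaces (plus any
segmentation-only words) form an alphabet, letter runs are split at
ASCII/non-ASCII boundaries, and a run containing an alphabet character is
segmented. With the bundled all-English dictionary no English text is ever
chopped; a Thai dictionary automatically makes Thai runs segmentable. A
non-ASCII run with no dictionary coverage stays one `word` token — the
pipeline has no information to split it and treating it as one word keeps
word counts conservative. Token spans are non-overlapping, sorted, and
reconstruct the input exactly (property-tested), so mention offsets are
always valid slices of the original note.

Greedy maximal matching rather than a dynamic-programming segmenter is a
deliberate scope choice: it is the classical default for dictionary
segmentation, transparent to debug, and the downstream decision only needs
term presence, not optimal segmentation.

### Matching and profiles

Literal entries match on consecutive token sequences, case-insensitively
after Unicode NFC (clinical notes mix cases); regex entries match the raw
text. Profiles are nested by a validated invariant — every strict entry is
also relaxed — which makes "strict flags ⊆ relaxed flags" a structural
property rather than an empirical hope. Overlapping matches are resolved
longest-first then leftmost *within each indicator*; resolving per
indicator (rather than globally) guarantees that adding synonyms for one
indicator can never suppress another indicator's evidence. In the bundled
dictionary every containment pair (e.g. "significant weight loss" ⊃
"weight loss") has the longer surface in both profiles, so strict mention
spans are a subset of relaxed spans as well.

### Negation

A mention is negated when a pre-position cue ("no", "not", "denies",
"denied", "without", "negative for") ends within `window` tokens (default
3) before the mention's first token with no scope breaker (".", ";",
"but") between cue and mention; post-position cues work symmetrically.
These defaults are configuration on the lexicon, not constants: the window
of 3 covers "no significant weight loss" while keeping cues from reaching
across clauses, and sentence-final periods hard-limit every cue to its
sentence. The affirmed/negated vocabulary is used instead of
positive/negative sentiment labels to avoid sign confusion: an affirmed
symptom mention contributes to indicators, a negated one never does.

## Cohort filters

Records are excluded when the admission date strictly precedes the
diagnosis date (same-day admissions are kept), when the note has fewer
than `min_words = 1000` non-punctuation tokens, or when the ICD-O behavior
digit is 0 (benign) or 1 (uncertain); digits 2/3/6/9 are retained. The
word threshold is "exclude if < 1000": of the two natural readings of a
1,000-word cut-off, the operational one (notes *under* 1,000 words lack
enough text to assess the indicators) is implemented, and the threshold is
exposed for sites that prefer the other. "Words" are pipeline tokens, so
the filter is language-aware and reproducible. A record with a missing
diagnosis or admission date cannot be ordered in time; it is excluded
under an explicit `MISSING_DATE` parse flag rather than silently kept or
silently dropped. The filter report counts each patient once per reason
and once overall, so overlapping exclusion reasons are visible — cohort
flow arithmetic that does not sum is then diagnosable rather than hidden.

## The bundled dictionary

The default lexicon is a deliberately minimal English seed: the
strict/relaxed contrast for weight loss ("significant weight loss" vs
"weight loss", "underweight", "hyposthenic build", "thinner"), the
palliative-care-request terms for indicator 6, the symptom vocabulary
(pain, dyspnea, edema, delirium, xerostomia, ascites, dysphagia, anorexia)
as relaxed evidence for persistent symptoms, and short phrasings of the
remaining indicator definitions marked `artifact-seeded` in the TSV. It is
*not* a clinically validated keyword list; the TSV/JSON format, the
strict-⊆-relaxed validation, and the per-row error messages are the
contract that lets a site drop in its own (including Thai) dictionary.

## Synthetic cohorts

The generator (`simulate_cohort`) emulates the structure of a
registry-linked admission-note corpus so every pipeline stage can be
tested with exact ground truth:

* **Truth sampling.** Each patient's six-indicator truth vector is drawn
  independently from a prevalence vector whose default
  (0.243, 0.238, 0.001, 0.176, 0.003, 0.078) follows the per-indicator
  detection proportions reported for the relaxed profile in the screened
  registry cohort, making roughly 15% of patients meet the two-indicator
  rule. Independence across indicators is a simplification — real
  indicators co-occur — so generated cohorts calibrate detection, not
  indicator correlation structure.
* **Evidence planting.** Each met indicator contributes exactly one
  affirmed term sentence (a relaxed-only synonym with probability
  `relaxed_only_rate`, default 0.3, else a strict term); each unmet
  indicator contributes a negated "no <term>." sentence with probability
  `negated_mention_rate` (default 0.2). Filler text comes from a fixed
  neutral vocabulary verified at run time to be disjoint from every
  lexicon surface token, cue, and breaker, and every planted phrase is its
  own period-terminated sentence — together these make the truth labels
  exact by construction.
* **Unsegmented filler.** A `script_mix` fraction (default 0.1) of filler
  sentences are runs of a synthetic Greek-letter mini-lexicon whose eight
  3-letter words partition the alphabet, so greedy segmentation recovers
  the run exactly and no real Thai clinical vocabulary is imitated.
  `synthetic_lexicon()` (the bundled dictionary plus these segmentation
  words) must be used when analysing generated cohorts.
* **Metadata and exclusions.** Sex, religion, and stage follow the
  published cohort's marginal distributions; notes default to 1,050–1,300
  words (above the inclusion threshold). Exclusion cases — admission
  1–60 days before diagnosis, notes truncated to 100–400 words, behavior
  /0 or /1 morphology — are planted at configurable per-reason rates
  (default 0) and recorded per patient.

Everything derives from one `numpy` generator seeded by `config.seed`, so
identical configurations are byte-identical.

`expected_divergence` gives the closed-form expected fraction of patients
flagged by relaxed but not strict: with per-indicator truth prevalence
`p_i` and effective relaxed-only probability `r_i` (zero for indicators
without relaxed-only synonyms), it is the difference of two
Poisson-binomial tails at `min_general`, `P(Σ Bern(p_i) ≥ k) −
P(Σ Bern(p_i(1−r_i)) ≥ k)` — valid because the strict-flagged set is
contained in the relaxed-flagged set patient by patient.

What passing synthetic tests shows: the mechanics (segmentation, matching,
negation windows, aggregation, filters, statistics) are correct. What it
does not show: performance on real clinical language — misspellings,
section headers, hedging, tense, or negation phrasings outside the cue
list are all absent from the generator.

## Statistics

* **Cohen's kappa** is computed from the defining formulas: κ =
  (p_o − p_e)/(1 − p_e), SE = √(p_o(1−p_o)/(n(1−p_e)²)) (the large-sample
  form), 95% CI κ ± 1.96·SE clipped to [−1, 1]; κ is undefined (raised)
  when p_e = 1. Interpretation bands: >0.7 good, 0.4–0.7 moderate
  (inclusive at both ends), <0.4 poor.
* **Prevalence per 100** rounds half-up to one decimal — the convention
  used in printed cohort tables — via `decimal`, not banker's rounding.
* **Odds ratios** use the cross-product ad/(bc) with a Wald log-scale CI;
  any zero cell triggers the Haldane–Anscombe +0.5 correction on all four
  cells, flagged in the result rather than applied silently.
* **Fisher's exact test** (two-sided, summing hypergeometric probabilities
  ≤ the observed table's) delegates to `scipy.stats.fisher_exact`; the
  test suite checks it against an independent `math.comb` enumeration.
* **Logistic association** delegates to `statsmodels` `Logit`
  (Newton, max 200 iterations) and reports exponentiated coefficients with
  Wald 95% CIs; perfect separation or non-convergence raises an explicit
  `SeparationError` instead of returning divergent estimates. No
  multiple-testing correction is applied, matching common practice in the
  screening literature this toolkit serves.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 100–2,000 patients with
1,050–1,300-word notes (shorter 120–160-word notes where only
mention-level behaviour is exercised), 20 × 500-patient cohorts for the
monotonicity sweep, and n = 5,000 for logistic parameter recovery — sizes
at which binomial error bounds (3 SE for divergence, 99% bounds for
prevalence calibration) are tight enough to catch real defects. All
randomness flows from explicit integer seeds.

## Known limitations

* Negation is window-based with a fixed cue list; scope ambiguity,
  double negation, and hedging are out of scope.
* Greedy segmentation can mis-split genuinely ambiguous unsegmented text;
  only dictionary words are recoverable.
* The default dictionary is a seed, not a validated instrument; screening
  quality on real notes is entirely dictionary-dependent.
* Only one note per patient is considered; no temporal reasoning across
  admissions.
* Indicator truths are sampled independently in the generator; simulated
  strict/relaxed divergences inherit that independence assumption.
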