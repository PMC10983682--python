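# spictminer

Rule-based text mining of cancer patients' electronic admission notes
against the six **SPICT-LIS general indicators** (Supportive and Palliative
Care Indicators Tool for Low-Income Settings), for researchers and hospital
data teams who want to screen which inpatients might benefit from
palliative care without manually reviewing every chart.

## What it does

For each patient the pipeline takes the first admission note written after
the registry cancer diagnosis and runs:

1. **Tokenization** — whitespace/punctuation splitting for ordinary script,
   greedy longest-match (maximal matching) dictionary segmentation for
   unsegmented script such as Thai;
2. **Mention finding** — dictionary lookup of indicator terms under one of
   two nested rule profiles: *strict* (explicit wording only, e.g.
   "significant weight loss") or *relaxed* (adds broader synonyms such as
   "weight loss", "underweight", "hyposthenic build", "thinner");
3. **Negation** ("sentiment") — a mention is negated when a cue like
   "no"/"denies" occurs within a 3-token window with no scope breaker
   (".", ";", "but") in between, so "no pain" never counts as pain;
4. **Aggregation** — general indicator *i* is met iff the note carries at
   least one affirmed mention mapped to *i*; a patient screens positive when

   &nbsp;&nbsp;`n_general_met >= 2  AND  clinical_met`

   where the clinical indicator is the confirmed cancer diagnosis itself.

Around the core sit cohort ingestion (JSONL/CSV) with the study exclusion
rules (admission before diagnosis; note under 1,000 words; ICD-O behavior
digit /0 or /1), evaluation statistics (percent agreement; Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) with large-sample SE and the bands >0.7 good /
0.4–0.7 moderate / <0.4 poor; prevalence per 100; Fisher's exact test;
cross-product and logistic odds ratios), and a synthetic-cohort generator
that plants indicator terms with exact ground truth so the whole pipeline
is testable without patient data.

## Worked example

```sh
spictminer simulate --n 50 --seed 7 --out cohort.jsonl --truth truth.csv \
    --lexicon-out synthlex.tsv
spictminer filter   --in cohort.jsonl --lexicon synthlex.tsv \
    --out included.jsonl --report report.json
spictminer classify --in included.jsonl --lexicon synthlex.tsv \
    --profile strict --out strict.csv
spictminer evaluate --pred strict.csv --gold truth.csv --out agreement.json
```

prints

```
simulated 50 patients (seed 7)
included 50/50 (excluded 0)
5/50 meet criteria (10.0 per 100), profile=strict
agreement 92.0% kappa 0.672 (moderate)
```

Reading: of 50 synthetic patients none tripped an exclusion rule; the
strict profile flags 5 (a screening yield of 10.0 per 100 patients); and
against the generator's ground truth the strict algorithm agrees on 92% of
patients with κ = 0.67 — it misses the 4 patients whose planted evidence
used relaxed-only synonyms (the generator's default `relaxed_only_rate` is
0.3), exactly the behaviour that makes the strict profile specific and the
relaxed profile sensitive. Pass `--lexicon synthlex.tsv` downstream because
generated notes contain synthetic unsegmented-script filler whose
segmentation dictionary ships with the generator, not the clinical lexicon.

The same from Python:

```python
from spictminer import SynthConfig, simulate_cohort, synthetic_lexicon, classify_cohort

records, truth = simulate_cohort(SynthConfig(n_patients=50, seed=7))
df = classify_cohort(records, synthetic_lexicon(), profile="strict")
print(df.meets_criteria.sum())   # 5
```

The bundled dictionary (`spictminer lexicon export-default --out default.tsv`)
is a minimal English seed; real deployments should supply their own TSV —
the format (surface, match kind, script, indicator, profiles) and the
strict-⊆-relaxed validation are the stable contract.

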