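"""Synthetic cohorts with exact ground truth for pipeline validation.

Real admission notes are not publicly shareable, so validation runs on
generated cohorts that emulate the *structure* of the corpus the screening
pipeline targets: long free-text notes (mixed whitespace-delimited and
unsegmented script) in which indicator evidence appears as planted
affirmed or negated dictionary terms, plus patient metadata with the
exclusion cases the cohort filter must catch.

Ground truth is exact by construction:

* filler text is drawn from a fixed neutral vocabulary checked at run time
  to be disjoint from every lexicon surface token, negation cue, and scope
  breaker, so filler can never create or negate a mention;
* each met indicator gets exactly one planted affirmed term (a relaxed-only
  synonym with probability ``relaxed_only_rate``, else a strict term);
* unmet indicators optionally get a planted *negated* term ("no <term>.")
  at ``negated_mention_rate``;
* every planted phrase is its own sentence, so sentence-final periods
  (scope breakers) isolate negations.

Unsegmented-script filler uses a synthetic Greek-letter mini-lexicon whose
words partition the alphabet (no cross-boundary word exists), so greedy
maximal matching re-segments concatenated runs exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lexicon import INDICATOR_IDS, Lexicon, default_lexicon, normalize
from .records import ExclusionReason, PatientRecord
from .rules import IndicatorVector

#: Neutral clinical filler vocabulary; disjoint from the default lexicon.
FILLER_VOCAB = (
    "patient admitted ward today vital signs stable afebrile alert oriented "
    "examination unremarkable chest clear abdomen soft labs reviewed plan "
    "continue medication dose morning evening fluids monitored nursing team "
    "discussed routine imaging pending results normal limits heart rate blood "
    "pressure temperature respiration oxygen saturation room air diet "
    "tolerated ambulating physiotherapy session completed rest comfortable "
    "overnight observation continued review wound dressing intact site "
    "inspected hydration adequate intake output recorded charted rounds "
    "attending resident consult scheduled awaiting transfer bed linen changed"
).split()

#: Synthetic unsegmented-script mini-lexicon: eight 3-letter words that
#: partition the Greek lowercase alphabet, so no concatenation is ambiguous.
MINI_SEGMENT_WORDS = ("αβγ", "δεζ", "ηθι", "κλμ", "νξο", "πρσ", "τυφ", "χψω")

_MORPHOLOGY_STEMS = ("8140", "8500", "8070", "9732", "8312")


class SynthConfigError(ValueError):
    """A synthetic-cohort configuration parameter is out of range."""


def synthetic_lexicon(base: Lexicon | None = None) -> Lexicon:
    """The bundled lexicon extended with the synthetic segmentation words.

    Generated notes contain unsegmented Greek-letter runs; analysing them
    (word counts, tokenization) requires the segmenter to know the
    mini-lexicon, so use this lexicon for both generation and analysis of
    synthetic cohorts.  It produces identical mentions to the base lexicon
    (segmentation words map to no indicator).
    """
    if base is None:
        base = default_lexicon()
    extra = tuple(w for w in MINI_SEGMENT_WORDS if w not in base.segmentation_words)
    return replace(base, segmentation_words=base.segmentation_words + extra)


@dataclass(frozen=True)
class ExclusionRates:
    """Per-reason probabilities of planting an exclusion case."""

    admission_before_diagnosis: float = 0.0
    note_too_short: float = 0.0
    non_malignant_behavior: float = 0.0


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the screened registry cohort: per-indicator truth
    prevalences follow the per-indicator detection proportions reported for
    the relaxed profile (24.3, 23.8, 0.1, 17.6, 0.3, 7.8 per 100), notes run
    well past the 1000-word inclusion threshold, and a tenth of the filler
    is unsegmented script.
    """

    n_patients: int = 200
    seed: int = 0
    prevalence: tuple = (0.243, 0.238, 0.001, 0.176, 0.003, 0.078)
    negated_mention_rate: float = 0.2
    relaxed_only_rate: float = 0.3
    exclusion_rates: ExclusionRates = field(default_factory=ExclusionRates)
    script_mix: float = 0.1
    note_length_words: tuple = (1050, 1300)
    min_general: int = 2

    def __post_init__(self):
        if self.n_patients < 0:
            raise SynthConfigError("n_patients must be >= 0")
        if len(self.prevalence) != len(INDICATOR_IDS):
            raise SynthConfigError("prevalence must have six entries")
        probs = list(self.prevalence) + [
            self.negated_mention_rate, self.relaxed_only_rate, self.script_mix,
            self.exclusion_rates.admission_before_diagnosis,
            self.exclusion_rates.note_too_short,
            self.exclusion_rates.non_malignant_behavior,
        ]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise SynthConfigError(f"probability {p} outside [0, 1]")
        lo, hi = self.note_length_words
        if not (0 < lo <= hi):
            raise SynthConfigError("note_length_words must be (lo, hi) with 0 < lo <= hi")


@dataclass
class GroundTruth:
    """Exact per-patient labels for a generated cohort."""

    min_general: int
    vectors: dict            # patient_id -> IndicatorVector
    benefit: dict            # patient_id -> bool (truth under the benefit rule)
    has_relaxed_only_evidence: dict  # patient_id -> bool
    planted_exclusions: dict # patient_id -> tuple of ExclusionReason

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in self.vectors:
            row = {"patient_id": pid}
            for i in INDICATOR_IDS:
                row[f"ind{i}"] = int(self.vectors[pid][i])
            row["benefit"] = int(self.benefit[pid])
            row["has_relaxed_only_evidence"] = int(self.has_relaxed_only_evidence[pid])
            row["planted_exclusions"] = ";".join(
                r.value for r in self.planted_exclusions[pid])
            rows.append(row)
        cols = (["patient_id"] + [f"ind{i}" for i in INDICATOR_IDS]
                + ["benefit", "has_relaxed_only_evidence", "planted_exclusions"])
        return pd.DataFrame(rows, columns=cols)


def _check_filler_disjoint(lexicon: Lexicon) -> None:
    reserved = set()
    for e in lexicon.entries:
        if e.match_kind == "literal":
            reserved.update(normalize(e.surface).split())
    for cue in lexicon.cues:
        reserved.update(normalize(cue.surface).split())
    reserved.update(normalize(b) for b in lexicon.scope_breakers)
    clash = reserved & {normalize(w) for w in FILLER_VOCAB}
    if clash:
        raise SynthConfigError(
            f"filler vocabulary collides with lexicon tokens: {sorted(clash)}"
        )


def _planting_terms(lexicon: Lexicon):
    """Per indicator: (strict literal surfaces, relaxed-only literal surfaces)."""
    strict, relaxed_only = {}, {}
    for i in INDICATOR_IDS:
        entries = [e for e in lexicon.entries_for(i)
                   if e.match_kind == "literal" and e.script != "unsegmented"]
        strict[i] = sorted(e.surface for e in entries if "strict" in e.profiles)
        relaxed_only[i] = sorted(e.surface for e in entries if "strict" not in e.profiles)
        if not strict[i]:
            raise SynthConfigError(
                f"lexicon has no strict literal term for indicator {i}; "
                "cannot plant evidence"
            )
    return strict, relaxed_only


def _filler_sentences(rng, n_words: int, script_mix: float) -> list:
    """Neutral sentences totalling ~n_words tokens; some unsegmented runs."""
    sentences = []
    remaining = n_words
    vocab = np.asarray(FILLER_VOCAB)
    mini = MINI_SEGMENT_WORDS
    while remaining > 0:
        k = int(rng.integers(8, 15))
        k = min(k, remaining) if remaining >= 4 else remaining
        if rng.random() < script_mix:
            idx = rng.integers(0, len(mini), size=k)
            sentences.append("".join(mini[j] for j in idx) + ".")
        else:
            idx = rng.integers(0, len(vocab), size=k)
            sentences.append(" ".join(vocab[idx]) + ".")
        remaining -= k
    return sentences


def _sample_metadata(rng, pid: str, excl: list) -> dict:
    diagnosis = dt.date(2016, 1, 1) + dt.timedelta(days=int(rng.integers(0, 1827)))
    if ExclusionReason.ADMISSION_BEFORE_DIAGNOSIS in excl:
        admission = diagnosis - dt.timedelta(days=int(rng.integers(1, 61)))
    else:
        admission = diagnosis + dt.timedelta(days=int(rng.integers(0, 31)))
    age_days = int(rng.integers(18 * 365, 90 * 365))
    birth = diagnosis - dt.timedelta(days=age_days)
    sex = "female" if rng.random() < 0.539 else "male"
    u = rng.random()
    religion = "buddhist" if u < 0.852 else ("islam" if u < 0.995 else "other")
    u = rng.random()
    stage = ("1" if u < 0.127 else "2" if u < 0.278 else "3" if u < 0.474
             else "4" if u < 0.740 else "unknown")
    stem = _MORPHOLOGY_STEMS[int(rng.integers(0, len(_MORPHOLOGY_STEMS)))]
    if ExclusionReason.NON_MALIGNANT_BEHAVIOR in excl:
        behavior = int(rng.integers(0, 2))  # 0 or 1
    else:
        behavior = 3
    icd10 = [f"C{int(rng.integers(0, 97)):02d}.9"]
    return {
        "patient_id": pid,
        "birth_date": birth,
        "diagnosis_date": diagnosis,
        "admission_date": admission,
        "sex": sex,
        "religion": religion,
        "stage": stage,
        "icd10": icd10,
        "icdo_morphology": f"{stem}/{behavior}",
        "cancer_confirmed": True,
    }


def simulate_cohort(config: SynthConfig, lexicon: Lexicon | None = None):
    """Generate ``(records, truth)`` fully reproducibly from ``config.seed``.

    Each patient's truth indicator vector is sampled from the prevalence
    vector; the note is neutral filler plus one affirmed planted term per
    met indicator and, at ``negated_mention_rate``, a negated term per unmet
    indicator.  Exclusion cases (early admission, short note, benign /
    uncertain-behavior morphology) are planted at ``exclusion_rates``.
    """
    if lexicon is None:
        lexicon = synthetic_lexicon()
    _check_filler_disjoint(lexicon)
    strict_terms, relaxed_only_terms = _planting_terms(lexicon)
    rng = np.random.default_rng(config.seed)
    er = config.exclusion_rates

    records: list = []
    vectors: dict = {}
    benefit: dict = {}
    relaxed_flag: dict = {}
    planted_excl: dict = {}
    width = max(4, len(str(max(config.n_patients, 1))))

    for k in range(config.n_patients):
        pid = f"P{k + 1:0{width}d}"
        truth = rng.random(len(INDICATOR_IDS)) < np.asarray(config.prevalence)
        vector = IndicatorVector(tuple(bool(x) for x in truth))

        excl = []
        if rng.random() < er.admission_before_diagnosis:
            excl.append(ExclusionReason.ADMISSION_BEFORE_DIAGNOSIS)
        if rng.random() < er.note_too_short:
            excl.append(ExclusionReason.NOTE_TOO_SHORT)
        if rng.random() < er.non_malignant_behavior:
            excl.append(ExclusionReason.NON_MALIGNANT_BEHAVIOR)

        if ExclusionReason.NOTE_TOO_SHORT in excl:
            n_words = int(rng.integers(100, 401))
        else:
            lo, hi = config.note_length_words
            n_words = int(rng.integers(lo, hi + 1))
        sentences = _filler_sentences(rng, n_words, config.script_mix)

        used_relaxed_only = False
        planted: list = []
        for i in INDICATOR_IDS:
            if vector[i]:
                pool = strict_terms[i]
                if relaxed_only_terms[i] and rng.random() < config.relaxed_only_rate:
                    pool = relaxed_only_terms[i]
                    used_relaxed_only = True
                term = pool[int(rng.integers(0, len(pool)))]
                planted.append(f"{term}.")
            elif rng.random() < config.negated_mention_rate:
                pool = strict_terms[i]
                if relaxed_only_terms[i] and rng.random() < config.relaxed_only_rate:
                    pool = relaxed_only_terms[i]
                term = pool[int(rng.integers(0, len(pool)))]
                planted.append(f"no {term}.")
        for phrase in planted:
            pos = int(rng.integers(0, len(sentences) + 1))
            sentences.insert(pos, phrase)

        meta = _sample_metadata(rng, pid, excl)
        records.append(PatientRecord(note_text=" ".join(sentences), **meta))
        vectors[pid] = vector
        benefit[pid] = vector.n_met >= config.min_general  # clinical_met True by design
        relaxed_flag[pid] = used_relaxed_only
        planted_excl[pid] = tuple(excl)

    truth = GroundTruth(
        min_general=config.min_general,
        vectors=vectors,
        benefit=benefit,
        has_relaxed_only_evidence=relaxed_flag,
        planted_exclusions=planted_excl,
    )
    return records, truth


# ---------------------------------------------------------------------------
# analytic expectations


def _prob_at_least(probs, k: int) -> float:
    """P(sum of independent Bernoulli(probs) >= k) by Poisson-binomial DP."""
    dist = np.zeros(len(probs) + 1)
    dist[0] = 1.0
    for p in probs:
        dist[1:] = dist[1:] * (1 - p) + dist[:-1] * p
        dist[0] *= 1 - p
    return float(dist[k:].sum())


def expected_divergence(config: SynthConfig, lexicon: Lexicon | None = None) -> float:
    """Expected fraction of patients flagged by relaxed but not strict.

    Under the generator, the relaxed profile detects every met indicator
    while the strict profile detects a met indicator only when its planted
    evidence used a strict term (probability ``1 - relaxed_only_rate``,
    when a relaxed-only synonym exists for that indicator).  Because the
    strict-flagged set is contained in the relaxed-flagged set, the
    expected divergence is P(relaxed flags) − P(strict flags), each a
    Poisson-binomial tail at ``min_general``.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    _, relaxed_only_terms = _planting_terms(lexicon)
    p = list(config.prevalence)
    q = [
        p_i * (1 - (config.relaxed_only_rate if relaxed_only_terms[i] else 0.0))
        for p_i, i in zip(p, INDICATOR_IDS)
    ]
    k = config.min_general
    return _prob_at_least(p, k) - _prob_at_least(q, k)
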