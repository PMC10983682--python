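"""Aggregation of polarized mentions into the SPICT-LIS screening decision.

An indicator is *met* when the note contains at least one affirmed mention
of a term mapped to it; negated mentions never contribute.  A patient
screens positive ("may benefit from palliative care") when at least
``min_general`` (default 2) of the six general indicators are met AND at
least one clinical indicator is met — for a cancer-registry cohort the
confirmed cancer diagnosis itself serves as the clinical indicator, so
``clinical_met`` defaults to the record's registry flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .lexicon import INDICATOR_IDS, Lexicon
from .records import PatientRecord
from .textmine import annotate


@dataclass(frozen=True)
class IndicatorVector:
    """Met/unmet status for general indicators 1..6."""

    met: tuple  # six booleans, index 0 == indicator 1

    def __post_init__(self):
        met = tuple(bool(x) for x in self.met)
        if len(met) != len(INDICATOR_IDS):
            raise ValueError(f"expected {len(INDICATOR_IDS)} indicators, got {len(met)}")
        object.__setattr__(self, "met", met)

    @classmethod
    def from_ids(cls, ids) -> "IndicatorVector":
        ids = set(ids)
        return cls(tuple(i in ids for i in INDICATOR_IDS))

    def __getitem__(self, indicator_id: int) -> bool:
        return self.met[indicator_id - 1]

    @property
    def n_met(self) -> int:
        return sum(self.met)

    @property
    def met_ids(self) -> tuple:
        return tuple(i for i in INDICATOR_IDS if self[i])


@dataclass(frozen=True)
class Classification:
    """Outcome of the screening rule for one patient under one profile."""

    profile: str
    indicators: IndicatorVector
    clinical_met: bool
    min_general: int = 2

    @property
    def n_general_met(self) -> int:
        return self.indicators.n_met

    @property
    def meets_criteria(self) -> bool:
        return self.n_general_met >= self.min_general and self.clinical_met


def evaluate_indicators(mentions) -> IndicatorVector:
    """Indicator i is met iff >= 1 affirmed mention with indicator_id i."""
    return IndicatorVector.from_ids(m.indicator_id for m in mentions if m.affirmed)


def classify(vector: IndicatorVector, clinical_met: bool,
             profile: str = "strict", min_general: int = 2) -> Classification:
    """Apply the two-part benefit rule to an indicator vector."""
    if min_general < 0:
        raise ValueError("min_general must be >= 0")
    return Classification(
        profile=profile,
        indicators=vector,
        clinical_met=bool(clinical_met),
        min_general=min_general,
    )


def run_pipeline(record: PatientRecord, lexicon: Lexicon, profile: str,
                 min_general: int = 2,
                 clinical_met: bool | None = None) -> Classification:
    """Full per-patient pipeline: tokenize → match → negate → aggregate → rule.

    ``clinical_met`` defaults to the record's registry cancer-confirmation
    flag (the clinical indicator for this cohort).
    """
    mentions = annotate(record.note_text, lexicon, profile)
    vector = evaluate_indicators(mentions)
    if clinical_met is None:
        clinical_met = record.cancer_confirmed
    return classify(vector, clinical_met, profile=profile, min_general=min_general)


def classify_cohort(records, lexicon: Lexicon, profile: str,
                    min_general: int = 2) -> pd.DataFrame:
    """Classify every record; one row per patient.

    Columns: patient_id, profile, ind1..ind6 (0/1), n_general_met,
    clinical_met, meets_criteria.
    """
    rows = []
    for rec in records:
        c = run_pipeline(rec, lexicon, profile, min_general=min_general)
        row = {"patient_id": rec.patient_id, "profile": profile}
        for i in INDICATOR_IDS:
            row[f"ind{i}"] = int(c.indicators[i])
        row["n_general_met"] = c.n_general_met
        row["clinical_met"] = int(c.clinical_met)
        row["meets_criteria"] = int(c.meets_criteria)
        rows.append(row)
    cols = (["patient_id", "profile"] + [f"ind{i}" for i in INDICATOR_IDS]
            + ["n_general_met", "clinical_met", "meets_criteria"])
    return pd.DataFrame(rows, columns=cols)
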