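"""Patient-level data model, cohort I/O, and inclusion/exclusion filters.

A cohort is a list of :class:`PatientRecord` objects read from JSONL or CSV.
The screening study design keeps, for each cancer patient, the first
admission note written after the registry diagnosis date; records are
excluded when

* the admission date precedes the cancer diagnosis date,
* the note contains fewer than ``min_words`` (default 1000) tokens, or
* the ICD-O morphology behavior digit marks a benign (``/0``) or
  uncertain-behavior (``/1``) mass.

:func:`filter_cohort` applies those rules and returns both the retained
records and a :class:`CohortFilterReport` in the shape of a participant
flow chart.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .lexicon import Lexicon
from .textmine import count_words

SEXES = ("female", "male")
STAGES = ("1", "2", "3", "4", "unknown")
VALID_BEHAVIOR_DIGITS = (0, 1, 2, 3, 6, 9)

#: Fields a cohort file must provide for every record.
REQUIRED_FIELDS = ("patient_id", "note_text")


class SchemaError(ValueError):
    """A cohort file does not conform to the documented schema."""


class ValidationError(ValueError):
    """Record-level contract violation (e.g. duplicate patient_id)."""


@dataclass
class PatientRecord:
    patient_id: str
    note_text: str = ""
    birth_date: dt.date | None = None
    diagnosis_date: dt.date | None = None
    admission_date: dt.date | None = None
    sex: str | None = None
    religion: str | None = None
    stage: str = "unknown"
    icd10: list = field(default_factory=list)
    icdo_morphology: str | None = None
    cancer_confirmed: bool = True

    @property
    def behavior_digit(self) -> int | None:
        """ICD-O behavior digit: the digit after '/' in e.g. '8140/3'."""
        if not self.icdo_morphology or "/" not in self.icdo_morphology:
            return None
        tail = self.icdo_morphology.split("/", 1)[1].strip()
        m = re.match(r"\d", tail)
        if m is None:
            return None
        digit = int(m.group())
        if digit not in VALID_BEHAVIOR_DIGITS:
            raise ValidationError(
                f"patient {self.patient_id}: behavior digit {digit} not in "
                f"{VALID_BEHAVIOR_DIGITS} (morphology {self.icdo_morphology!r})"
            )
        return digit


class ExclusionReason(enum.Enum):
    ADMISSION_BEFORE_DIAGNOSIS = "admission_before_diagnosis"
    NOTE_TOO_SHORT = "note_too_short"
    NON_MALIGNANT_BEHAVIOR = "non_malignant_behavior"
    MISSING_DATE = "missing_date"  # parse flag: diagnosis/admission date absent


@dataclass
class CohortFilterReport:
    """Participant flow chart: who was kept, who was dropped and why."""

    n_input: int
    n_included: int
    counts: dict            # ExclusionReason -> count of patients with that reason
    excluded: list          # (patient_id, [ExclusionReason, ...])

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_included

    def to_json_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "counts": {r.value: c for r, c in self.counts.items()},
            "excluded": [
                {"patient_id": pid, "reasons": [r.value for r in reasons]}
                for pid, reasons in self.excluded
            ],
        }


# ---------------------------------------------------------------------------
# parsing helpers

_DATE_FIELDS = ("birth_date", "diagnosis_date", "admission_date")


def _parse_date(value, fallback_format: str | None = None) -> dt.date | None:
    if value is None or value == "" or isinstance(value, float):
        return None
    if isinstance(value, dt.date):
        return value
    s = str(value).strip()
    if not s:
        return None
    try:
        return dt.date.fromisoformat(s)
    except ValueError:
        pass
    if fallback_format:
        try:
            return dt.datetime.strptime(s, fallback_format).date()
        except ValueError:
            pass
    return None


def _record_from_mapping(row: dict, fallback_date_format: str | None) -> PatientRecord:
    for name in REQUIRED_FIELDS:
        if name not in row or row[name] in (None, ""):
            raise SchemaError(f"missing required field {name!r}")
    icd10 = row.get("icd10") or []
    if isinstance(icd10, str):
        icd10 = [c.strip() for c in icd10.split(";") if c.strip()]
    sex = row.get("sex") or None
    if sex is not None:
        sex = str(sex).strip().lower()
        if sex not in SEXES:
            sex = None  # unparseable optional field -> missing
    stage = str(row.get("stage") or "unknown").strip().lower()
    if stage not in STAGES:
        stage = "unknown"
    confirmed = row.get("cancer_confirmed", True)
    if isinstance(confirmed, str):
        confirmed = confirmed.strip().lower() in ("1", "true", "yes")
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        note_text=str(row["note_text"]),
        birth_date=_parse_date(row.get("birth_date"), fallback_date_format),
        diagnosis_date=_parse_date(row.get("diagnosis_date"), fallback_date_format),
        admission_date=_parse_date(row.get("admission_date"), fallback_date_format),
        sex=sex,
        religion=(str(row["religion"]).strip() or None) if row.get("religion") else None,
        stage=stage,
        icd10=list(icd10),
        icdo_morphology=(str(row["icdo_morphology"]).strip() or None)
        if row.get("icdo_morphology") else None,
        cancer_confirmed=bool(confirmed),
    )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    if suffix in (".csv", ".tsv"):
        return "csv"
    raise SchemaError(f"cannot infer cohort format from {path.name!r}; pass format=")


def read_cohort(path, format: str | None = None,
                fallback_date_format: str | None = None) -> list:
    """Read a cohort file (JSONL: one object per patient; CSV: same keys).

    Unparseable optional fields become missing; a missing required field or
    a duplicate ``patient_id`` raises.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    records: list = []
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
                try:
                    records.append(_record_from_mapping(row, fallback_date_format))
                except SchemaError as exc:
                    raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    elif fmt == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            fieldnames = reader.fieldnames or []
            for name in REQUIRED_FIELDS:
                if name not in fieldnames:
                    raise SchemaError(f"{path}: missing required column {name!r}")
            for lineno, row in enumerate(reader, start=2):
                try:
                    records.append(_record_from_mapping(row, fallback_date_format))
                except SchemaError as exc:
                    raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    else:
        raise SchemaError(f"unknown cohort format {fmt!r}")
    seen: set = set()
    for rec in records:
        if rec.patient_id in seen:
            raise ValidationError(f"duplicate patient_id {rec.patient_id!r}")
        seen.add(rec.patient_id)
    return records


def _record_to_row(rec: PatientRecord, csv_style: bool) -> dict:
    row = {
        "patient_id": rec.patient_id,
        "note_text": rec.note_text,
        "birth_date": rec.birth_date.isoformat() if rec.birth_date else ("" if csv_style else None),
        "diagnosis_date": rec.diagnosis_date.isoformat() if rec.diagnosis_date else ("" if csv_style else None),
        "admission_date": rec.admission_date.isoformat() if rec.admission_date else ("" if csv_style else None),
        "sex": rec.sex or ("" if csv_style else None),
        "religion": rec.religion or ("" if csv_style else None),
        "stage": rec.stage,
        "icd10": ";".join(rec.icd10) if csv_style else rec.icd10,
        "icdo_morphology": rec.icdo_morphology or ("" if csv_style else None),
        "cancer_confirmed": rec.cancer_confirmed,
    }
    return row


def write_cohort(records: list, path, format: str | None = None) -> None:
    """Write a cohort so that :func:`read_cohort` round-trips it exactly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(_record_to_row(rec, csv_style=False),
                                    ensure_ascii=False) + "\n")
    else:
        cols = list(_record_to_row(PatientRecord("x", "y"), csv_style=True))
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for rec in records:
                writer.writerow(_record_to_row(rec, csv_style=True))


# ---------------------------------------------------------------------------
# exclusion filters


def exclusion_reasons(rec: PatientRecord, lexicon: Lexicon,
                      min_words: int = 1000) -> list:
    """All exclusion rules a single record trips (empty list = included)."""
    reasons = []
    if rec.diagnosis_date is None or rec.admission_date is None:
        reasons.append(ExclusionReason.MISSING_DATE)
    elif rec.admission_date < rec.diagnosis_date:
        reasons.append(ExclusionReason.ADMISSION_BEFORE_DIAGNOSIS)
    if count_words(rec.note_text, lexicon) < min_words:
        reasons.append(ExclusionReason.NOTE_TOO_SHORT)
    if rec.behavior_digit in (0, 1):
        reasons.append(ExclusionReason.NON_MALIGNANT_BEHAVIOR)
    return reasons


def filter_cohort(records: list, lexicon: Lexicon,
                  min_words: int = 1000) -> tuple:
    """Apply the cohort exclusion rules.

    Returns ``(included, report)``.  Admissions on the diagnosis day itself
    are kept (only strictly earlier admissions are excluded); records with a
    missing diagnosis or admission date are excluded and flagged rather than
    silently retained.  A patient may trip several rules; the report counts
    the patient once per rule but once overall.
    """
    included: list = []
    excluded: list = []
    counts = {reason: 0 for reason in ExclusionReason}
    for rec in records:
        reasons = exclusion_reasons(rec, lexicon, min_words=min_words)
        if reasons:
            excluded.append((rec.patient_id, reasons))
            for r in reasons:
                counts[r] += 1
        else:
            included.append(rec)
    report = CohortFilterReport(
        n_input=len(records),
        n_included=len(included),
        counts=counts,
        excluded=excluded,
    )
    return included, report
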