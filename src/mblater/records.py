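"""Patient-level records and the cohort CSV schema.

A cohort is a table with one row per patient: demographics, AF
characteristics, echocardiographic and laboratory values, comorbidities,
the early-recurrence flag, and the landmark follow-up outcome (months
since ablation, very-late-recurrence event indicator).
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Iterable

import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator


class Sex(str, enum.Enum):
    male = "M"
    female = "F"


class AFType(str, enum.Enum):
    """Clinical type of atrial fibrillation before ablation."""

    paroxysmal = "paroxysmal"
    persistent = "persistent"
    longstanding_persistent = "longstanding_persistent"


class PatientRecord(BaseModel):
    """One patient's covariates, complete-case (no missing values accepted).

    eGFR is carried on two scales because the comparator scores define
    their thresholds in different units: ``egfr`` in ml/min (ALARMc) and
    ``egfr_bsa`` in ml/min/1.73 m^2 (APPLE).  ``lad_index`` is a stored
    field (anteroposterior LA diameter / body surface area, mm/m^2), not
    derived inside any scoring function.
    """

    id: str
    age: float = Field(gt=0, description="years")
    sex: Sex
    bmi: float = Field(gt=0, description="kg/m^2")
    af_type: AFType
    af_history: float = Field(ge=0, description="years since first-diagnosed AF")
    bbb: bool = Field(description="any bundle branch block on baseline ECG")
    lad: float = Field(gt=0, description="anteroposterior LA diameter, mm")
    lad_index: float = Field(gt=0, description="LAD / body surface area, mm/m^2")
    lvef: float = Field(gt=0, le=100, description="LV ejection fraction, percent")
    egfr: float = Field(gt=0, description="ml/min")
    egfr_bsa: float = Field(gt=0, description="ml/min/1.73 m^2")
    chf: bool
    hypertension: bool
    diabetes: bool
    stroke_tia: bool
    vascular_disease: bool
    copd: bool
    smoker: bool = Field(description="current smoker (or quit < 6 months ago)")
    metabolic_syndrome: bool
    eraf: bool = Field(
        description="any atrial tachyarrhythmia >30 s in the 3-month blanking period"
    )

    model_config = {"extra": "forbid"}


class Outcome(BaseModel):
    """Landmark follow-up outcome for one patient.

    ``followup_months`` is measured on the ablation clock; only patients
    arrhythmia-free through the 12-month landmark are in a cohort, so
    every follow-up time (and in particular every event time) exceeds 12.
    """

    followup_months: float = Field(gt=12.0)
    vlraf_event: bool

    @model_validator(mode="after")
    def _event_after_landmark(self) -> "Outcome":
        # gt=12 on followup_months already enforces the VLRAF definition
        return self


#: Exact column order of the cohort CSV schema.
COHORT_COLUMNS = [
    "id",
    "age_years",
    "sex",
    "bmi_kg_m2",
    "af_type",
    "af_history_years",
    "bbb",
    "lad_mm",
    "lad_index_mm_m2",
    "lvef_pct",
    "egfr_ml_min",
    "egfr_ml_min_1p73m2",
    "chf",
    "hypertension",
    "diabetes",
    "stroke_tia",
    "vascular_disease",
    "copd",
    "smoker",
    "metabolic_syndrome",
    "eraf",
    "followup_months",
    "vlraf_event",
]

_BOOL_COLUMNS = [
    "bbb",
    "chf",
    "hypertension",
    "diabetes",
    "stroke_tia",
    "vascular_disease",
    "copd",
    "smoker",
    "metabolic_syndrome",
    "eraf",
    "vlraf_event",
]

# CSV column -> PatientRecord field
_RECORD_FIELDS = {
    "id": "id",
    "age_years": "age",
    "sex": "sex",
    "bmi_kg_m2": "bmi",
    "af_type": "af_type",
    "af_history_years": "af_history",
    "bbb": "bbb",
    "lad_mm": "lad",
    "lad_index_mm_m2": "lad_index",
    "lvef_pct": "lvef",
    "egfr_ml_min": "egfr",
    "egfr_ml_min_1p73m2": "egfr_bsa",
    "chf": "chf",
    "hypertension": "hypertension",
    "diabetes": "diabetes",
    "stroke_tia": "stroke_tia",
    "vascular_disease": "vascular_disease",
    "copd": "copd",
    "smoker": "smoker",
    "metabolic_syndrome": "metabolic_syndrome",
    "eraf": "eraf",
}


class CohortValidationError(ValueError):
    """A cohort row failed validation; names the offending row and column."""

    def __init__(self, row: int | None, column: str | None, message: str):
        self.row = row
        self.column = column
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column '{column}'")
        prefix = " ".join(loc)
        super().__init__(f"{prefix}: {message}" if prefix else message)


def record_from_row(row: pd.Series, *, row_number: int | None = None) -> PatientRecord:
    """Build a validated :class:`PatientRecord` from one cohort-schema row."""
    payload = {}
    for col, field in _RECORD_FIELDS.items():
        if col not in row or pd.isna(row[col]):
            raise CohortValidationError(row_number, col, "missing value")
        value = row[col]
        if col in _BOOL_COLUMNS:
            if value not in (0, 1, True, False, "0", "1"):
                raise CohortValidationError(
                    row_number, col, f"boolean column must be 0/1, got {value!r}"
                )
            value = bool(int(value))
        payload[field] = value
    try:
        return PatientRecord(**payload)
    except ValidationError as exc:
        err = exc.errors()[0]
        field = str(err["loc"][0]) if err["loc"] else "?"
        col = next((c for c, f in _RECORD_FIELDS.items() if f == field), field)
        raise CohortValidationError(row_number, col, err["msg"]) from exc


def outcome_from_row(row: pd.Series, *, row_number: int | None = None) -> Outcome:
    for col in ("followup_months", "vlraf_event"):
        if col not in row or pd.isna(row[col]):
            raise CohortValidationError(row_number, col, "missing value")
    try:
        return Outcome(
            followup_months=float(row["followup_months"]),
            vlraf_event=bool(int(row["vlraf_event"])),
        )
    except (ValidationError, ValueError) as exc:
        msg = exc.errors()[0]["msg"] if isinstance(exc, ValidationError) else str(exc)
        raise CohortValidationError(row_number, "followup_months", msg) from exc


def validate_cohort(frame: pd.DataFrame) -> None:
    """Validate every row of a cohort table; raise on the first bad row.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(None, missing[0], "column missing from header")
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        record_from_row(row, row_number=i)
        outcome_from_row(row, row_number=i)


def records_from_frame(
    frame: pd.DataFrame, *, validate: bool = True
) -> list[PatientRecord]:
    """Materialise :class:`PatientRecord` objects for every cohort row."""
    out = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        out.append(record_from_row(row, row_number=i if validate else None))
    return out


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; malformed rows are named."""
    frame = pd.read_csv(path, dtype={"id": str, "sex": str, "af_type": str})
    validate_cohort(frame)
    return frame[COHORT_COLUMNS]


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table in the canonical CSV schema (header-only if empty)."""
    out = frame.copy()
    missing = [c for c in COHORT_COLUMNS if c not in out.columns]
    if missing:
        raise CohortValidationError(None, missing[0], "column missing")
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(int)
    out[COHORT_COLUMNS].to_csv(path, index=False)


def frame_from_records(
    records: Iterable[PatientRecord], outcomes: Iterable[Outcome]
) -> pd.DataFrame:
    """Assemble a cohort table from record/outcome pairs."""
    rows = []
    for rec, out in zip(records, outcomes):
        row = {col: getattr(rec, field) for col, field in _RECORD_FIELDS.items()}
        row["sex"] = rec.sex.value
        row["af_type"] = rec.af_type.value
        row["followup_months"] = out.followup_months
        row["vlraf_event"] = out.vlraf_event
        rows.append(row)
    frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return frame
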