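"""Domain types for polytrauma patients and cohort file I/O.

A cohort is a list of :class:`PatientRecord`, one per patient, holding the
admission physiology snapshot, anatomical injury scores, and the outcome
record (death with timing and cause, plus adjudicated complication flags).
Cohorts round-trip losslessly through a documented CSV schema
(:func:`read_cohort` / :func:`write_cohort`).

Units are fixed per field and never auto-converted: pressures in mmHg,
lactate and base excess in mmol/L, fibrinogen in g/L, platelets in 1e9/L,
prothrombin as Quick percent of normal, temperature in deg C.  Missing
measurements are represented as absent (``None``), never as sentinel
numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "PhysiologySnapshot",
    "InjuryScores",
    "OutcomeRecord",
    "PatientRecord",
    "CohortValidationError",
    "CohortSchemaError",
    "DEATH_CAUSES",
    "EARLY_LABELS",
    "LATE_LABELS",
    "COHORT_COLUMNS",
    "classify_complication_timing",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
]

DEATH_CAUSES = ("TBI", "exsanguination", "MOF", "other")

#: Complication labels counted as early (within the first 72 h) vs late.
EARLY_LABELS = frozenset({"death_72h", "death_tbi", "death_exsanguination"})
LATE_LABELS = frozenset({"pneumonia", "sepsis", "death_mof"})

#: Hours after admission up to and including which a death counts as early.
EARLY_DEATH_CUTOFF_H = 72.0


class CohortValidationError(ValueError):
    """A patient record violates a field invariant."""

    def __init__(self, patient_id: str, field_name: str, message: str):
        self.patient_id = patient_id
        self.field_name = field_name
        super().__init__(f"patient {patient_id!r}, field {field_name!r}: {message}")


class CohortSchemaError(ValueError):
    """A cohort file does not match the documented CSV schema."""


def _check_range(pid, name, value, lo, hi, integer=False):
    if value is None:
        return
    if integer and value != int(value):
        raise CohortValidationError(pid, name, f"must be an integer, got {value}")
    if not (lo <= value <= hi):
        raise CohortValidationError(pid, name, f"must be in [{lo}, {hi}], got {value}")


@dataclass
class PhysiologySnapshot:
    """Admission physiology; every field optional (absent = not measured)."""

    systolic_bp: Optional[float] = None  # mmHg
    lactate: Optional[float] = None  # mmol/L
    ph: Optional[float] = None
    base_excess: Optional[float] = None  # mmol/L, negative = acidosis
    platelet_count: Optional[float] = None  # 1e9/L
    fibrinogen: Optional[float] = None  # g/L
    prothrombin_ratio: Optional[float] = None  # Quick value, % of normal
    inr: Optional[float] = None
    prbc_2h: Optional[int] = None  # pRBC units within 2 h of admission
    prbc_24h: Optional[int] = None  # pRBC units within 24 h of injury
    temperature_core: Optional[float] = None  # deg C
    chest_ais: Optional[int] = None  # AIS 0-6
    abdomen_moore_grade: Optional[int] = None  # Moore grade 0-5
    extremity_soft_tissue_ais: Optional[int] = None  # AIS 0-6
    gcs: Optional[int] = None  # 3-15

    def validate(self, pid: str) -> None:
        _check_range(pid, "ph", self.ph, 6.5, 8.0)
        if self.lactate is not None and self.lactate < 0:
            raise CohortValidationError(pid, "lactate", f"must be >= 0, got {self.lactate}")
        for name in ("prbc_2h", "prbc_24h"):
            v = getattr(self, name)
            if v is not None:
                if v != int(v) or v < 0:
                    raise CohortValidationError(pid, name, f"must be a non-negative integer, got {v}")
        _check_range(pid, "gcs", self.gcs, 3, 15, integer=True)
        _check_range(pid, "chest_ais", self.chest_ais, 0, 6, integer=True)
        _check_range(pid, "extremity_soft_tissue_ais", self.extremity_soft_tissue_ais, 0, 6, integer=True)
        _check_range(pid, "abdomen_moore_grade", self.abdomen_moore_grade, 0, 5, integer=True)
        for name in ("systolic_bp", "platelet_count", "fibrinogen", "prothrombin_ratio", "inr"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise CohortValidationError(pid, name, f"must be >= 0, got {v}")

    def get(self, name: str):
        return getattr(self, name)


@dataclass
class InjuryScores:
    """Anatomical severity (ISS/NISS, both 0-75) and age at injury."""

    iss: int
    niss: int
    age_years: float

    def validate(self, pid: str) -> None:
        _check_range(pid, "iss", self.iss, 16, 75, integer=True)  # ISS >= 16 defines cohort inclusion
        _check_range(pid, "niss", self.niss, 0, 75, integer=True)
        if self.niss < self.iss:
            raise CohortValidationError(pid, "niss", f"NISS ({self.niss}) must be >= ISS ({self.iss})")
        if self.age_years < 16:
            raise CohortValidationError(pid, "age_years", f"must be >= 16, got {self.age_years}")

    def get(self, name: str):
        return getattr(self, name)


@dataclass
class OutcomeRecord:
    """In-hospital outcome: death (with hour and cause) and complication flags."""

    died: bool = False
    death_hour: Optional[float] = None  # hours since admission, present iff died
    death_cause: Optional[str] = None  # one of DEATH_CAUSES, present iff died
    pneumonia: bool = False
    sepsis: bool = False
    bacteraemia: bool = False
    septic_shock: bool = False
    infection: bool = False
    ards: bool = False
    mof: bool = False

    def validate(self, pid: str) -> None:
        if self.died:
            if self.death_hour is None:
                raise CohortValidationError(pid, "death_hour", "required when died is true")
            if self.death_hour < 0:
                raise CohortValidationError(pid, "death_hour", f"must be >= 0, got {self.death_hour}")
            if self.death_cause not in DEATH_CAUSES:
                raise CohortValidationError(
                    pid, "death_cause", f"must be one of {DEATH_CAUSES}, got {self.death_cause!r}"
                )
        else:
            if self.death_hour is not None:
                raise CohortValidationError(pid, "death_hour", "present although died is false")
            if self.death_cause is not None:
                raise CohortValidationError(pid, "death_cause", "present although died is false")
        if self.septic_shock and not self.sepsis:
            raise CohortValidationError(pid, "septic_shock", "septic shock implies sepsis")


@dataclass
class PatientRecord:
    patient_id: str
    physiology: PhysiologySnapshot
    injury: InjuryScores
    outcome: OutcomeRecord

    def validate(self) -> None:
        self.physiology.validate(self.patient_id)
        self.injury.validate(self.patient_id)
        self.outcome.validate(self.patient_id)

    def get(self, name: str):
        """Look a parameter up on the physiology snapshot or injury scores."""
        if hasattr(self.physiology, name):
            return getattr(self.physiology, name)
        return getattr(self.injury, name)


def classify_complication_timing(outcome: OutcomeRecord) -> frozenset[str]:
    """Map an outcome to its early/late complication labels.

    Early: death within 72 h (boundary closed, ``death_hour <= 72``), death
    from traumatic brain injury, death from exsanguination.  Late:
    pneumonia, sepsis, death from multiple organ failure.
    """
    labels: set[str] = set()
    if outcome.died:
        if outcome.death_hour is not None and outcome.death_hour <= EARLY_DEATH_CUTOFF_H:
            labels.add("death_72h")
        if outcome.death_cause == "TBI":
            labels.add("death_tbi")
        elif outcome.death_cause == "exsanguination":
            labels.add("death_exsanguination")
        elif outcome.death_cause == "MOF":
            labels.add("death_mof")
    if outcome.pneumonia:
        labels.add("pneumonia")
    if outcome.sepsis:
        labels.add("sepsis")
    return frozenset(labels)


# ---------------------------------------------------------------------------
# CSV schema

_PHYS_FIELDS = [f.name for f in fields(PhysiologySnapshot)]
_BOOL_FIELDS = ["died", "pneumonia", "sepsis", "bacteraemia", "septic_shock", "infection", "ards", "mof"]
_INT_PHYS = {"prbc_2h", "prbc_24h", "chest_ais", "abdomen_moore_grade", "extremity_soft_tissue_ais", "gcs"}

COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age_years",
    "iss",
    "niss",
    "gcs",
    "systolic_bp",
    "lactate",
    "ph",
    "base_excess",
    "platelet_count",
    "fibrinogen",
    "prothrombin_ratio",
    "inr",
    "prbc_2h",
    "prbc_24h",
    "temperature_core",
    "chest_ais",
    "abdomen_moore_grade",
    "extremity_soft_tissue_ais",
    "died",
    "death_hour",
    "death_cause",
    "pneumonia",
    "sepsis",
    "bacteraemia",
    "septic_shock",
    "infection",
    "ards",
    "mof",
)


def _opt(value, integer=False):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return int(value) if integer else float(value)


def record_from_row(row: dict) -> PatientRecord:
    """Build (and validate) one PatientRecord from a raw CSV row mapping."""
    pid = str(row["patient_id"])
    phys = PhysiologySnapshot(
        **{name: _opt(row.get(name), integer=name in _INT_PHYS) for name in _PHYS_FIELDS}
    )
    injury = InjuryScores(
        iss=int(row["iss"]), niss=int(row["niss"]), age_years=float(row["age_years"])
    )
    cause = row.get("death_cause")
    if cause is not None and (not isinstance(cause, str) or cause == ""):
        cause = None if (cause == "" or (isinstance(cause, float) and math.isnan(cause))) else str(cause)
    outcome = OutcomeRecord(
        died=bool(int(row["died"])),
        death_hour=_opt(row.get("death_hour")),
        death_cause=cause if cause else None,
        **{name: bool(int(row[name])) for name in _BOOL_FIELDS if name != "died"},
    )
    rec = PatientRecord(patient_id=pid, physiology=phys, injury=injury, outcome=outcome)
    rec.validate()
    return rec


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV, validating every record.

    Raises :class:`CohortSchemaError` when required columns are missing and
    :class:`CohortValidationError` (naming patient and field) on the first
    invariant violation.  Duplicate patient_id values are an error.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "death_cause": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort file {path} is missing columns: {missing}")
    records = [record_from_row(row) for row in df.to_dict("records")]
    seen: set[str] = set()
    for rec in records:
        if rec.patient_id in seen:
            raise CohortValidationError(rec.patient_id, "patient_id", "duplicate patient_id in cohort")
        seen.add(rec.patient_id)
    return records


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten a cohort into a DataFrame with the documented column order."""
    rows = []
    for rec in cohort:
        row = {"patient_id": rec.patient_id, "age_years": rec.injury.age_years,
               "iss": rec.injury.iss, "niss": rec.injury.niss}
        for name in _PHYS_FIELDS:
            row[name] = rec.physiology.get(name)
        row["died"] = int(rec.outcome.died)
        row["death_hour"] = rec.outcome.death_hour
        row["death_cause"] = rec.outcome.death_cause
        for name in _BOOL_FIELDS[1:]:
            row[name] = int(getattr(rec.outcome, name))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(cohort: Sequence[PatientRecord], path) -> None:
    """Write a cohort as CSV (booleans 0/1, absent optionals as empty cells)."""
    for rec in cohort:
        rec.validate()
    df = cohort_to_frame(cohort)
    df.to_csv(path, index=False)
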