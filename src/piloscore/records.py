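"""Patient-level records and their validation.

A :class:`PatientRecord` holds the nine scored factors, basic demographics
and the post-operative outcome fields.  Outcome and operative fields are
optional so that purely pre-operative records can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

#: Fields a record must carry to be scorable (order matters for reports).
SCORE_FACTOR_FIELDS = (
    "bmi",
    "sex",
    "hairy_back",
    "diabetes",
    "prior_recurrence",
    "n_midline_pits",
    "lateral_pits",
    "distance_to_anus_cm",
    "prior_abscess",
)


@dataclass
class PatientRecord:
    patient_id: str
    sex: str
    age: int
    bmi: float
    hairy_back: bool
    diabetes: bool
    prior_recurrence: bool
    n_midline_pits: int
    lateral_pits: bool
    distance_to_anus_cm: float
    prior_abscess: bool
    # outcomes / operative course (optional)
    recurrence: Optional[bool] = None
    wound_dehiscence: Optional[bool] = None
    postop_infection: Optional[bool] = None
    operative_time_min: Optional[float] = None
    hospital_stay_days: Optional[int] = None
    drain_removal_day: Optional[int] = None


#: Canonical CSV column order for cohort files.
COHORT_COLUMNS = tuple(f.name for f in fields(PatientRecord))


@dataclass(frozen=True)
class Violation:
    """One invariant breach: which field and which rule it broke."""

    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule}"


def _is_bool(x) -> bool:
    return isinstance(x, (bool,)) or x in (0, 1)


def validate_record(record: PatientRecord) -> list[Violation]:
    """Check a record against its invariants.

    Returns a (possibly empty) list of violations instead of raising, so
    callers can report every problem in one pass.
    """
    out: list[Violation] = []

    if not record.patient_id:
        out.append(Violation("patient_id", "must be non-empty"))

    if record.sex not in SEXES:
        out.append(Violation("sex", f"must be one of {SEXES}, got {record.sex!r}"))

    if record.age is None or not float(record.age).is_integer() or record.age <= 0:
        out.append(Violation("age", "must be a positive integer"))

    if record.bmi is None or not record.bmi > 0:
        out.append(Violation("bmi", "must be > 0"))

    if (
        record.n_midline_pits is None
        or not float(record.n_midline_pits).is_integer()
        or record.n_midline_pits < 0
    ):
        out.append(Violation("n_midline_pits", "must be a non-negative integer"))

    if record.distance_to_anus_cm is None or not record.distance_to_anus_cm > 0:
        out.append(Violation("distance_to_anus_cm", "must be > 0"))

    for name in ("hairy_back", "diabetes", "prior_recurrence", "lateral_pits", "prior_abscess"):
        value = getattr(record, name)
        if value is None or not _is_bool(value):
            out.append(Violation(name, "must be a boolean"))

    # optional fields are only checked when present
    if record.operative_time_min is not None and not record.operative_time_min > 0:
        out.append(Violation("operative_time_min", "must be > 0 when present"))
    if record.hospital_stay_days is not None and (
        not float(record.hospital_stay_days).is_integer() or record.hospital_stay_days < 1
    ):
        out.append(Violation("hospital_stay_days", "must be a positive integer when present"))
    if record.drain_removal_day is not None and (
        not float(record.drain_removal_day).is_integer() or record.drain_removal_day < 1
    ):
        out.append(Violation("drain_removal_day", "must be a positive integer when present"))
    for name in ("recurrence", "wound_dehiscence", "postop_infection"):
        value = getattr(record, name)
        if value is not None and not _is_bool(value):
            out.append(Violation(name, "must be a boolean when present"))

    return out
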