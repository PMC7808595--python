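"""Domain types for patient-level community-AKI cohort data.

All times are real-valued hours since enrollment; calendar dates are converted
at the I/O boundary.  Serum creatinine is carried in μmol/l throughout; the
conversion constant to mg/dl lives in :mod:`akicohort.renal`.
"""
from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: Maximum lookback for a prior baseline creatinine, hours (12 months).
BASELINE_LOOKBACK_H = 8760.0


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Phase(str, enum.Enum):
    observation = "observation"
    intervention = "intervention"


class Visit(str, enum.Enum):
    prior_baseline = "prior_baseline"
    enrollment = "enrollment"
    h48 = "h48"
    day7 = "day7"
    month1 = "month1"
    month3 = "month3"
    month6 = "month6"
    other = "other"


class Disposition(str, enum.Enum):
    sent_home = "sent_home"
    admitted = "admitted"


class ProteinGrade(enum.IntEnum):
    """Ordinal urine dipstick protein scale; positive (proteinuria) at >= plus1."""

    negative = 0
    trace = 1
    plus1 = 2
    plus2 = 3
    plus3 = 4
    plus4 = 5

    @classmethod
    def from_label(cls, label: str) -> "ProteinGrade":
        try:
            return _GRADE_FROM_LABEL[label.strip()]
        except KeyError:
            raise ValueError(f"unknown dipstick protein grade {label!r}") from None

    @property
    def label(self) -> str:
        return _GRADE_TO_LABEL[self]


_GRADE_TO_LABEL = {
    ProteinGrade.negative: "negative",
    ProteinGrade.trace: "trace",
    ProteinGrade.plus1: "1+",
    ProteinGrade.plus2: "2+",
    ProteinGrade.plus3: "3+",
    ProteinGrade.plus4: "4+",
}
_GRADE_FROM_LABEL = {v: k for k, v in _GRADE_TO_LABEL.items()}


#: Ordered names of the 12 scoreable presentation symptoms.
SYMPTOM_FIELDS = (
    "decreased_urine_output",
    "hypotension_shock",
    "coma",
    "jaundice",
    "anemia",
    "confusion",
    "dyspnea",
    "respiratory_infection",
    "petechiae",
    "ecchymosis",
    "bleeding",
    "hypertension_in_pregnancy",
)


class SymptomProfile(BaseModel):
    """Presence/absence of the 12 scoreable presentation symptoms.

    ``hypertension_in_pregnancy`` may only be flagged for pregnant patients.
    """

    model_config = ConfigDict(frozen=True)

    decreased_urine_output: bool = False
    hypotension_shock: bool = False
    coma: bool = False
    jaundice: bool = False
    anemia: bool = False
    confusion: bool = False
    dyspnea: bool = False
    respiratory_infection: bool = False
    petechiae: bool = False
    ecchymosis: bool = False
    bleeding: bool = False
    hypertension_in_pregnancy: bool = False
    is_pregnant: bool = False

    @model_validator(mode="after")
    def _pregnancy_gate(self) -> "SymptomProfile":
        if self.hypertension_in_pregnancy and not self.is_pregnant:
            raise ValueError(
                "hypertension_in_pregnancy requires is_pregnant=True"
            )
        return self

    def flags(self) -> tuple[bool, ...]:
        return tuple(getattr(self, name) for name in SYMPTOM_FIELDS)


class CreatinineSample(BaseModel):
    """One serum creatinine measurement (μmol/l) at a signed time in hours."""

    model_config = ConfigDict(frozen=True)

    value: float = Field(gt=0.0, description="serum creatinine, μmol/l")
    time: float = Field(description="hours since enrollment (negative = prior)")
    visit: Visit = Visit.other

    @model_validator(mode="after")
    def _check_times(self) -> "CreatinineSample":
        if self.visit is Visit.prior_baseline:
            if not (-BASELINE_LOOKBACK_H <= self.time < 0.0):
                raise ValueError(
                    "prior_baseline sample must lie within the 12-month lookback"
                )
        elif self.visit is Visit.enrollment and self.time != 0.0:
            raise ValueError("enrollment sample must be at time 0")
        return self


class DipstickResult(BaseModel):
    """Urine dipstick protein grade at a labelled visit."""

    model_config = ConfigDict(frozen=True)

    protein_grade: ProteinGrade
    visit: Visit = Visit.enrollment
    time: float = 0.0


class PatientRecord(BaseModel):
    """One enrollee: demographics, phase, symptoms, labs, disposition, outcomes."""

    model_config = ConfigDict(validate_assignment=True)

    patient_id: str
    age_years: float = Field(ge=0.0)
    sex: Sex
    ethnicity: Optional[str] = None
    country: Optional[str] = None
    phase: Phase
    symptoms: SymptomProfile = SymptomProfile()
    known_ckd_history: bool = False
    creatinine_series: list[CreatinineSample] = Field(default_factory=list)
    dipsticks: list[DipstickResult] = Field(default_factory=list)
    disposition: Optional[Disposition] = None
    hours_in_facility: Optional[float] = Field(default=None, ge=0.0)
    dialysis_indicated: bool = False
    dialyzed: bool = False
    received_oral_fluids: bool = False
    received_iv_fluids: bool = False
    received_diuretics: bool = False
    death_time: Optional[float] = None
    last_contact_time: Optional[float] = None
    height_cm: Optional[float] = Field(default=None, gt=0.0)

    @model_validator(mode="after")
    def _invariants(self) -> "PatientRecord":
        n_enroll = sum(
            1 for s in self.creatinine_series if s.visit is Visit.enrollment
        )
        if n_enroll > 1:
            raise ValueError("at most one enrollment creatinine sample allowed")
        if (
            self.death_time is not None
            and self.last_contact_time is not None
            and self.death_time > self.last_contact_time
        ):
            raise ValueError("death_time must not exceed last_contact_time")
        return self

    @property
    def is_adult(self) -> bool:
        return self.age_years >= 18.0

    @property
    def admitted(self) -> bool:
        """Admission status: disposition column when present, else the >24 h rule."""
        if self.disposition is not None:
            return self.disposition is Disposition.admitted
        return (self.hours_in_facility or 0.0) > 24.0

    def enrollment_sample(self) -> Optional[CreatinineSample]:
        for s in self.creatinine_series:
            if s.visit is Visit.enrollment:
                return s
        return None

    def prior_baseline_sample(self) -> Optional[CreatinineSample]:
        """Most recent prior-baseline creatinine within the 12-month lookback."""
        priors = [
            s for s in self.creatinine_series if s.visit is Visit.prior_baseline
        ]
        return max(priors, key=lambda s: s.time) if priors else None

    def enrollment_dipstick(self) -> Optional[DipstickResult]:
        for d in self.dipsticks:
            if d.visit is Visit.enrollment:
                return d
        return None

    def dipstick_at(self, visit: Visit) -> Optional[DipstickResult]:
        for d in self.dipsticks:
            if d.visit is visit:
                return d
        return None


class Cohort(BaseModel):
    """An ordered collection of patient records with provenance metadata."""

    records: list[PatientRecord] = Field(default_factory=list)
    provenance: dict = Field(default_factory=dict)

    @field_validator("records")
    @classmethod
    def _unique_ids(cls, v: list[PatientRecord]) -> list[PatientRecord]:
        seen: set[str] = set()
        for r in v:
            if r.patient_id in seen:
                raise ValueError(f"duplicate patient_id {r.patient_id!r}")
            seen.add(r.patient_id)
        return v

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]
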