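"""Core domain types for prescription-safety auditing.

The unit of analysis is an *active-prescription snapshot*: everything a
detection rule can see about one patient on one extraction date.  Records
mirror the tabular extracts of an electronic clinical workstation —
prescriptions, demographics, diagnoses, clinical-variable measurements —
plus a drug catalog mapping ATC codes to active principles and
pharmacological group tags.

Conventions
-----------
* Prescription and diagnosis activity uses the half-open interval
  ``[start, end)``: a record is active on date *d* iff ``start <= d`` and
  (no end date, or ``end > d``).  An absent end date means ongoing.
* Age is completed years at the snapshot date (floor).
* Drug codes are ATC level 5 (letter, 2 digits, 2 letters, 2 digits).
"""

from __future__ import annotations

import datetime as dt
import enum
import re
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

ATC_LEVEL5_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")


class Sex(str, enum.Enum):
    female = "female"
    male = "male"
    unknown = "unknown"


class VariableCode(str, enum.Enum):
    """Clinical variables a contraindication rule may read."""

    potassium = "potassium"  # mmol/L
    egfr = "egfr"  # mL/min/1.73m2
    other = "other"


class PatientRecord(BaseModel):
    model_config = {"frozen": True}

    patient_id: str
    physician_id: str
    birth_date: dt.date
    sex: Sex = Sex.unknown


class PrescriptionRecord(BaseModel):
    model_config = {"frozen": True}

    patient_id: str
    drug_code: str
    daily_dose_mg: Optional[float] = Field(default=None, ge=0)
    start_date: dt.date
    end_date: Optional[dt.date] = None

    @field_validator("drug_code")
    @classmethod
    def _atc(cls, v: str) -> str:
        if not ATC_LEVEL5_RE.match(v):
            raise ValueError(f"drug_code {v!r} is not an ATC level-5 code")
        return v

    @model_validator(mode="after")
    def _interval(self) -> "PrescriptionRecord":
        if self.end_date is not None and self.start_date > self.end_date:
            raise ValueError(
                f"prescription {self.drug_code} for {self.patient_id}: "
                f"start_date {self.start_date} after end_date {self.end_date}"
            )
        return self

    def active_on(self, day: dt.date) -> bool:
        """Half-open convention: active iff start <= day < end."""
        return self.start_date <= day and (self.end_date is None or self.end_date > day)


class DiagnosisRecord(BaseModel):
    model_config = {"frozen": True}

    patient_id: str
    icd10_code: str
    onset_date: dt.date
    resolved_date: Optional[dt.date] = None

    @model_validator(mode="after")
    def _interval(self) -> "DiagnosisRecord":
        if self.resolved_date is not None and self.onset_date > self.resolved_date:
            raise ValueError(
                f"diagnosis {self.icd10_code} for {self.patient_id}: "
                f"onset after resolution"
            )
        return self

    def active_on(self, day: dt.date) -> bool:
        return self.onset_date <= day and (
            self.resolved_date is None or self.resolved_date > day
        )


class ClinicalVariableRecord(BaseModel):
    model_config = {"frozen": True}

    patient_id: str
    variable_code: VariableCode
    value: float
    measured_date: dt.date

    @model_validator(mode="after")
    def _finite_nonneg(self) -> "ClinicalVariableRecord":
        import math

        if self.variable_code in (VariableCode.potassium, VariableCode.egfr):
            if not math.isfinite(self.value) or self.value < 0:
                raise ValueError(
                    f"{self.variable_code.value} value must be finite and "
                    f"non-negative, got {self.value}"
                )
        return self


class DrugCatalogEntry(BaseModel):
    """One ATC code with its active principles and pharmacological tags.

    ``component_principles`` has more than one element for combination
    products; ``group_tags`` carry both rule-facing groups (``nsaid``,
    ``ras_inhibitor`` ...) and duplication-group tags (``dup:...``).
    """

    model_config = {"frozen": True}

    drug_code: str
    name: str
    component_principles: frozenset[str]
    group_tags: frozenset[str] = frozenset()

    @field_validator("drug_code")
    @classmethod
    def _atc(cls, v: str) -> str:
        if not ATC_LEVEL5_RE.match(v):
            raise ValueError(f"drug_code {v!r} is not an ATC level-5 code")
        return v

    @field_validator("component_principles")
    @classmethod
    def _nonempty(cls, v: frozenset[str]) -> frozenset[str]:
        if not v:
            raise ValueError("component_principles must be non-empty")
        return v


def age_completed_years(birth_date: dt.date, on: dt.date) -> int:
    """Completed years of age on a given date (floor)."""
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


class ActivePrescription(BaseModel):
    """A prescription as seen at a snapshot, with its elapsed duration."""

    model_config = {"frozen": True}

    record: PrescriptionRecord
    duration_days: int

    @property
    def drug_code(self) -> str:
        return self.record.drug_code

    @property
    def daily_dose_mg(self) -> Optional[float]:
        return self.record.daily_dose_mg


class PatientState(BaseModel):
    """Everything a rule can see for one patient at one snapshot date."""

    model_config = {"frozen": True}

    patient_id: str
    snapshot_date: dt.date
    age_years: int = Field(ge=0)
    active_prescriptions: tuple[ActivePrescription, ...] = ()
    active_diagnoses: frozenset[str] = frozenset()
    latest_clinical_values: dict[str, tuple[float, dt.date]] = {}

    def active_codes(self) -> set[str]:
        return {p.drug_code for p in self.active_prescriptions}


def validate_patient_state(state: PatientState) -> None:
    """Assert the snapshot invariants of a :class:`PatientState`.

    Raises ``ValueError`` if any active prescription falls outside the
    half-open activity window or a clinical value postdates the snapshot.
    """
    for ap in state.active_prescriptions:
        rec = ap.record
        if not rec.active_on(state.snapshot_date):
            raise ValueError(
                f"prescription {rec.drug_code} not active on {state.snapshot_date}"
            )
        if ap.duration_days != (state.snapshot_date - rec.start_date).days:
            raise ValueError(f"duration_days mismatch for {rec.drug_code}")
    for code, (_, measured) in state.latest_clinical_values.items():
        if measured > state.snapshot_date:
            raise ValueError(f"clinical value {code} measured after snapshot")
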