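"""Reading, validating and writing cohort extracts.

A *cohort* bundles the four tabular extracts an electronic clinical
workstation would export: patients, active prescriptions, diagnoses and
clinical-variable measurements.  All files are plain CSV with ISO-8601
dates; empty ``end_date`` / ``resolved_date`` cells mean "still open".
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pydantic import ValidationError

from .models import (
    ActivePrescription,
    ClinicalVariableRecord,
    DiagnosisRecord,
    DrugCatalogEntry,
    PatientRecord,
    PatientState,
    PrescriptionRecord,
    age_completed_years,
)

logger = logging.getLogger(__name__)

PRESCRIPTIONS_COLUMNS = ["patient_id", "drug_code", "daily_dose_mg", "start_date", "end_date"]
PATIENTS_COLUMNS = ["patient_id", "physician_id", "birth_date", "sex"]
DIAGNOSES_COLUMNS = ["patient_id", "icd10_code", "onset_date", "resolved_date"]
CLINICAL_COLUMNS = ["patient_id", "variable_code", "value", "measured_date"]


class SchemaError(ValueError):
    """A file does not conform to its expected column schema."""


class CohortValidationError(ValueError):
    """Record-level contract violation (duplicate ids, bad dates...)."""


@dataclass
class ValidationReport:
    """Per-file counts of rows read and rejected during loading."""

    read: dict[str, int] = field(default_factory=dict)
    rejected: dict[str, int] = field(default_factory=dict)
    rejected_rows: list[tuple[str, int, str]] = field(default_factory=list)

    def add_rejection(self, file: str, row: int, reason: str) -> None:
        self.rejected[file] = self.rejected.get(file, 0) + 1
        self.rejected_rows.append((file, row, reason))


@dataclass
class Cohort:
    """Validated, cross-referenced set of records for a population."""

    patients: dict[str, PatientRecord]
    prescriptions: list[PrescriptionRecord]
    diagnoses: list[DiagnosisRecord]
    clinical: list[ClinicalVariableRecord]
    report: ValidationReport = field(default_factory=ValidationReport)

    _rx_by_patient: Optional[dict[str, list[PrescriptionRecord]]] = field(
        default=None, repr=False, compare=False
    )
    _dx_by_patient: Optional[dict[str, list[DiagnosisRecord]]] = field(
        default=None, repr=False, compare=False
    )
    _cl_by_patient: Optional[dict[str, list[ClinicalVariableRecord]]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self._rx_by_patient = _group(self.prescriptions)
        self._dx_by_patient = _group(self.diagnoses)
        self._cl_by_patient = _group(self.clinical)

    def prescriptions_for(self, patient_id: str) -> list[PrescriptionRecord]:
        return self._rx_by_patient.get(patient_id, [])

    def diagnoses_for(self, patient_id: str) -> list[DiagnosisRecord]:
        return self._dx_by_patient.get(patient_id, [])

    def clinical_for(self, patient_id: str) -> list[ClinicalVariableRecord]:
        return self._cl_by_patient.get(patient_id, [])

    def physician_of(self, patient_id: str) -> str:
        return self.patients[patient_id].physician_id


def _group(records: Iterable) -> dict[str, list]:
    out: dict[str, list] = {}
    for r in records:
        out.setdefault(r.patient_id, []).append(r)
    return out


def _parse_date(raw: object, *, file: str, row: int, column: str) -> Optional[dt.date]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return None
    try:
        return dt.date.fromisoformat(str(raw))
    except ValueError as exc:
        raise CohortValidationError(
            f"{file} row {row}: unparseable date in column {column!r}: {raw!r}"
        ) from exc


def _read_csv(path: Path, expected: list[str], name: str) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")
    return frame


def load_cohort(
    prescriptions_path: str | Path,
    patients_path: str | Path,
    diagnoses_path: str | Path,
    clinical_path: str | Path | None = None,
) -> Cohort:
    """Load and cross-validate the cohort CSV extracts.

    Records referencing a ``patient_id`` absent from the patients file are
    rejected (not fatal) and listed in the attached validation report.
    Duplicate patient ids, missing columns and unparseable dates raise.
    """
    report = ValidationReport()

    pat_frame = _read_csv(Path(patients_path), PATIENTS_COLUMNS, "patients.csv")
    patients: dict[str, PatientRecord] = {}
    for i, row in enumerate(pat_frame.itertuples(index=False), start=2):
        pid = row.patient_id
        if pid in patients:
            raise CohortValidationError(f"patients.csv row {i}: duplicate patient_id {pid!r}")
        patients[pid] = PatientRecord(
            patient_id=pid,
            physician_id=row.physician_id,
            birth_date=_parse_date(row.birth_date, file="patients.csv", row=i, column="birth_date"),
            sex=row.sex or "unknown",
        )
    report.read["patients"] = len(patients)

    prescriptions: list[PrescriptionRecord] = []
    rx_frame = _read_csv(Path(prescriptions_path), PRESCRIPTIONS_COLUMNS, "prescriptions.csv")
    for i, row in enumerate(rx_frame.itertuples(index=False), start=2):
        if row.patient_id not in patients:
            report.add_rejection("prescriptions", i, f"unknown patient_id {row.patient_id!r}")
            continue
        try:
            prescriptions.append(
                PrescriptionRecord(
                    patient_id=row.patient_id,
                    drug_code=row.drug_code,
                    daily_dose_mg=float(row.daily_dose_mg) if row.daily_dose_mg != "" else None,
                    start_date=_parse_date(row.start_date, file="prescriptions.csv", row=i, column="start_date"),
                    end_date=_parse_date(row.end_date, file="prescriptions.csv", row=i, column="end_date"),
                )
            )
        except ValidationError as exc:
            raise CohortValidationError(f"prescriptions.csv row {i}: {exc}") from exc
    report.read["prescriptions"] = len(rx_frame)

    diagnoses: list[DiagnosisRecord] = []
    dx_frame = _read_csv(Path(diagnoses_path), DIAGNOSES_COLUMNS, "diagnoses.csv")
    for i, row in enumerate(dx_frame.itertuples(index=False), start=2):
        if row.patient_id not in patients:
            report.add_rejection("diagnoses", i, f"unknown patient_id {row.patient_id!r}")
            continue
        try:
            diagnoses.append(
                DiagnosisRecord(
                    patient_id=row.patient_id,
                    icd10_code=row.icd10_code,
                    onset_date=_parse_date(row.onset_date, file="diagnoses.csv", row=i, column="onset_date"),
                    resolved_date=_parse_date(row.resolved_date, file="diagnoses.csv", row=i, column="resolved_date"),
                )
            )
        except ValidationError as exc:
            raise CohortValidationError(f"diagnoses.csv row {i}: {exc}") from exc
    report.read["diagnoses"] = len(dx_frame)

    clinical: list[ClinicalVariableRecord] = []
    if clinical_path is not None:
        cl_frame = _read_csv(Path(clinical_path), CLINICAL_COLUMNS, "clinical.csv")
        for i, row in enumerate(cl_frame.itertuples(index=False), start=2):
            if row.patient_id not in patients:
                report.add_rejection("clinical", i, f"unknown patient_id {row.patient_id!r}")
                continue
            try:
                clinical.append(
                    ClinicalVariableRecord(
                        patient_id=row.patient_id,
                        variable_code=row.variable_code,
                        value=float(row.value),
                        measured_date=_parse_date(row.measured_date, file="clinical.csv", row=i, column="measured_date"),
                    )
                )
            except ValidationError as exc:
                raise CohortValidationError(f"clinical.csv row {i}: {exc}") from exc
        report.read["clinical"] = len(cl_frame)

    if report.rejected_rows:
        logger.warning("load_cohort rejected %d row(s)", len(report.rejected_rows))
    return Cohort(patients=patients, prescriptions=prescriptions, diagnoses=diagnoses, clinical=clinical, report=report)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a cohort back to the four CSV extracts (stable order)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _d(x: Optional[dt.date]) -> str:
        return x.isoformat() if x is not None else ""

    paths = {
        "patients": out / "patients.csv",
        "prescriptions": out / "prescriptions.csv",
        "diagnoses": out / "diagnoses.csv",
        "clinical": out / "clinical.csv",
    }
    pd.DataFrame(
        [
            {"patient_id": p.patient_id, "physician_id": p.physician_id,
             "birth_date": _d(p.birth_date), "sex": p.sex.value}
            for p in sorted(cohort.patients.values(), key=lambda p: p.patient_id)
        ],
        columns=PATIENTS_COLUMNS,
    ).to_csv(paths["patients"], index=False)
    pd.DataFrame(
        [
            {"patient_id": r.patient_id, "drug_code": r.drug_code,
             "daily_dose_mg": "" if r.daily_dose_mg is None else f"{r.daily_dose_mg:g}",
             "start_date": _d(r.start_date), "end_date": _d(r.end_date)}
            for r in sorted(cohort.prescriptions, key=lambda r: (r.patient_id, r.drug_code, r.start_date))
        ],
        columns=PRESCRIPTIONS_COLUMNS,
    ).to_csv(paths["prescriptions"], index=False)
    pd.DataFrame(
        [
            {"patient_id": r.patient_id, "icd10_code": r.icd10_code,
             "onset_date": _d(r.onset_date), "resolved_date": _d(r.resolved_date)}
            for r in sorted(cohort.diagnoses, key=lambda r: (r.patient_id, r.icd10_code, r.onset_date))
        ],
        columns=DIAGNOSES_COLUMNS,
    ).to_csv(paths["diagnoses"], index=False)
    pd.DataFrame(
        [
            {"patient_id": r.patient_id, "variable_code": r.variable_code.value,
             "value": f"{r.value:g}", "measured_date": _d(r.measured_date)}
            for r in sorted(cohort.clinical, key=lambda r: (r.patient_id, r.variable_code.value, r.measured_date))
        ],
        columns=CLINICAL_COLUMNS,
    ).to_csv(paths["clinical"], index=False)
    return paths


def build_patient_state(cohort: Cohort, patient_id: str, snapshot_date: dt.date) -> PatientState:
    """Assemble the rule-evaluation context for one patient on one date.

    Active prescriptions follow the half-open ``[start, end)`` convention;
    ``latest_clinical_values`` keeps, per variable, the most recent
    measurement on or before the snapshot date.
    """
    try:
        patient = cohort.patients[patient_id]
    except KeyError:
        raise KeyError(f"unknown patient_id {patient_id!r}") from None

    active = tuple(
        ActivePrescription(record=rx, duration_days=(snapshot_date - rx.start_date).days)
        for rx in sorted(
            (r for r in cohort.prescriptions_for(patient_id) if r.active_on(snapshot_date)),
            key=lambda r: (r.drug_code, r.start_date),
        )
    )
    dx = frozenset(d.icd10_code for d in cohort.diagnoses_for(patient_id) if d.active_on(snapshot_date))
    latest: dict[str, tuple[float, dt.date]] = {}
    for m in cohort.clinical_for(patient_id):
        if m.measured_date > snapshot_date:
            continue
        code = m.variable_code.value
        if code not in latest or m.measured_date > latest[code][1]:
            latest[code] = (m.value, m.measured_date)

    return PatientState(
        patient_id=patient_id,
        snapshot_date=snapshot_date,
        age_years=age_completed_years(patient.birth_date, snapshot_date),
        active_prescriptions=active,
        active_diagnoses=dx,
        latest_clinical_values=latest,
    )


def load_drug_catalog(path: str | Path) -> dict[str, DrugCatalogEntry]:
    """Load a drug catalog CSV (``|``-separated principle and tag lists)."""
    frame = _read_csv(Path(path), ["drug_code", "name", "component_principles", "group_tags"], "drug_catalog.csv")
    catalog: dict[str, DrugCatalogEntry] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        entry = DrugCatalogEntry(
            drug_code=row.drug_code,
            name=row.name,
            component_principles=frozenset(s for s in row.component_principles.split("|") if s),
            group_tags=frozenset(s for s in row.group_tags.split("|") if s),
        )
        if entry.drug_code in catalog:
            raise CohortValidationError(f"drug_catalog.csv row {i}: duplicate drug_code {entry.drug_code}")
        catalog[entry.drug_code] = entry
    return catalog
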