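from __future__ import annotations

import datetime as dt
from typing import Optional

import numpy as np
import pytest

from selfaudit.catalog import RuleCatalog, builtin_catalog
from selfaudit.io import Cohort
from selfaudit.models import (
    ActivePrescription,
    ClinicalVariableRecord,
    DiagnosisRecord,
    PatientRecord,
    PatientState,
    PrescriptionRecord,
)

SNAPSHOT = dt.date(2016, 4, 1)


@pytest.fixture(scope="session")
def catalog_2016() -> RuleCatalog:
    return builtin_catalog("2016")


@pytest.fixture(scope="session")
def catalog_2017() -> RuleCatalog:
    return builtin_catalog("2017")


@pytest.fixture(scope="session")
def catalog_2018() -> RuleCatalog:
    return builtin_catalog("2018")


def make_state(
    *,
    age: int = 60,
    drugs: list[tuple] = (),  # (code, dose) or (code, dose, duration_days)
    diagnoses: list[str] = (),
    clinical: Optional[dict[str, float]] = None,
    snapshot: dt.date = SNAPSHOT,
    patient_id: str = "P1",
) -> PatientState:
    """Build a PatientState directly (no cohort files needed)."""
    aps = []
    for spec in drugs:
        code, dose = spec[0], spec[1]
        duration = spec[2] if len(spec) > 2 else 100
        aps.append(
            ActivePrescription(
                record=PrescriptionRecord(
                    patient_id=patient_id,
                    drug_code=code,
                    daily_dose_mg=dose,
                    start_date=snapshot - dt.timedelta(days=duration),
                ),
                duration_days=duration,
            )
        )
    return PatientState(
        patient_id=patient_id,
        snapshot_date=snapshot,
        age_years=age,
        active_prescriptions=tuple(aps),
        active_diagnoses=frozenset(diagnoses),
        latest_clinical_values={
            k: (v, snapshot - dt.timedelta(days=7)) for k, v in (clinical or {}).items()
        },
    )


def make_cohort(
    patients: list[tuple],  # (patient_id, physician_id, birth_date)
    prescriptions: list[tuple] = (),  # (pid, code, dose, start, end)
    diagnoses: list[tuple] = (),  # (pid, icd10, onset, resolved)
    clinical: list[tuple] = (),  # (pid, variable, value, measured)
) -> Cohort:
    return Cohort(
        patients={
            pid: PatientRecord(patient_id=pid, physician_id=phys, birth_date=birth)
            for pid, phys, birth in patients
        },
        prescriptions=[
            PrescriptionRecord(
                patient_id=pid, drug_code=code, daily_dose_mg=dose,
                start_date=start, end_date=end,
            )
            for pid, code, dose, start, end in prescriptions
        ],
        diagnoses=[
            DiagnosisRecord(patient_id=pid, icd10_code=icd, onset_date=onset, resolved_date=res)
            for pid, icd, onset, res in diagnoses
        ],
        clinical=[
            ClinicalVariableRecord(patient_id=pid, variable_code=var, value=val, measured_date=md)
            for pid, var, val, md in clinical
        ],
    )


def random_states(catalog: RuleCatalog, n: int, seed: int, snapshot: dt.date = SNAPSHOT):
    """Stream of random PatientStates spanning the catalog's drug space,
    a pool of relevant and irrelevant diagnoses, and clinical values."""
    rng = np.random.default_rng(seed)
    codes = sorted(catalog.drug_catalog)
    dx_pool = [
        "E11.9", "I50.9", "G20", "I25.1", "I80.2", "K70.3", "I61.0", "I47.2",
        "C54.1", "K50.9", "I63.9", "I73.9", "Z89.4", "J45.0", "M17.1", "F41.1",
    ]
    doses = [None, 5.0, 10.0, 15.0, 20.0, 25.0, 40.0, 45.0, 60.0, 100.0, 200.0, 1200.0]
    for i in range(n):
        n_drugs = int(rng.integers(0, 9))
        picked = rng.choice(len(codes), size=n_drugs, replace=False) if n_drugs else []
        drugs = [
            (codes[int(k)], doses[int(rng.integers(len(doses)))], int(rng.integers(1, 2500)))
            for k in picked
        ]
        n_dx = int(rng.integers(0, 4))
        dx = [dx_pool[int(k)] for k in rng.choice(len(dx_pool), size=n_dx, replace=False)] if n_dx else []
        clinical = {}
        if rng.random() < 0.4:
            clinical["egfr"] = float(rng.uniform(10, 120))
        if rng.random() < 0.4:
            clinical["potassium"] = float(rng.uniform(3.0, 6.5))
        yield make_state(
            age=int(rng.integers(18, 96)),
            drugs=drugs,
            diagnoses=dx,
            clinical=clinical,
            snapshot=snapshot,
            patient_id=f"R{i}",
        )
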