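"""Detect medication-related problems for a handful of patients.

Builds a tiny in-memory cohort, runs the 2016 rule catalog on one
extraction date, and prints every alert: the rule that fired, the drugs
and diagnoses that triggered it, and whether it counts toward the
incentive-based safety indicator.
"""

import datetime as dt

from selfaudit import builtin_catalog, build_patient_state, evaluate_patient
from selfaudit.io import Cohort
from selfaudit.models import DiagnosisRecord, PatientRecord, PrescriptionRecord

D = dt.date
cohort = Cohort(
    patients={
        # an 81-year-old on the acute-kidney-injury risk triple
        "P1": PatientRecord(patient_id="P1", physician_id="D1", birth_date=D(1935, 2, 1)),
        # a 56-year-old on a high citalopram dose plus two anti-inflammatories
        "P2": PatientRecord(patient_id="P2", physician_id="D1", birth_date=D(1960, 1, 1)),
    },
    prescriptions=[
        PrescriptionRecord(patient_id="P1", drug_code="M01AE01", daily_dose_mg=1200,
                           start_date=D(2016, 2, 1)),   # ibuprofen
        PrescriptionRecord(patient_id="P1", drug_code="C09AA02", daily_dose_mg=20,
                           start_date=D(2015, 5, 1)),   # enalapril
        PrescriptionRecord(patient_id="P1", drug_code="C03CA01", daily_dose_mg=40,
                           start_date=D(2015, 8, 1)),   # furosemide
        PrescriptionRecord(patient_id="P2", drug_code="N06AB04", daily_dose_mg=60,
                           start_date=D(2016, 1, 1)),   # citalopram, above 40 mg/day
        PrescriptionRecord(patient_id="P2", drug_code="M01AE01", daily_dose_mg=1200,
                           start_date=D(2016, 1, 1)),   # ibuprofen
        PrescriptionRecord(patient_id="P2", drug_code="M01AE02", daily_dose_mg=1000,
                           start_date=D(2016, 3, 1)),   # naproxen: duplication
    ],
    diagnoses=[
        DiagnosisRecord(patient_id="P1", icd10_code="E11.9", onset_date=D(2010, 1, 1)),
    ],
    clinical=[],
)

catalog = builtin_catalog("2016")
snapshot_date = D(2016, 4, 1)

for pid in sorted(cohort.patients):
    state = build_patient_state(cohort, pid, snapshot_date)
    print(f"\n{pid} (age {state.age_years}, {len(state.active_prescriptions)} active drugs):")
    for alert in evaluate_patient(state, catalog):
        linked = "indicator-linked" if alert.indicator_linked else "not linked"
        print(f"  [{alert.category.value}] {alert.rule_id}: "
              f"drugs={','.join(alert.triggering_drugs) or '-'} "
              f"dx={','.join(alert.triggering_diagnoses) or '-'} ({linked})")

# P1 fires the Triple Whammy (NSAID + RAS inhibitor + diuretic at age >= 75);
# P2 fires the citalopram dose alert and an anti-inflammatory duplication.
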