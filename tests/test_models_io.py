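"""Domain types, cohort loading/validation and patient-state assembly."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selfaudit.io import (
    CohortValidationError,
    SchemaError,
    build_patient_state,
    load_cohort,
    write_cohort,
)
from selfaudit.models import (
    PrescriptionRecord,
    age_completed_years,
    validate_patient_state,
)

from conftest import make_cohort, make_state

D = dt.date


class TestRecords:
    def test_atc_pattern_enforced(self):
        with pytest.raises(ValueError, match="ATC"):
            PrescriptionRecord(
                patient_id="P1", drug_code="NOTATC", start_date=D(2016, 1, 1)
            )

    def test_interval_order_enforced(self):
        with pytest.raises(ValueError, match="end_date"):
            PrescriptionRecord(
                patient_id="P1", drug_code="N06AB04",
                start_date=D(2016, 5, 1), end_date=D(2016, 4, 1),
            )

    @pytest.mark.parametrize(
        "start,end,day,active",
        [
            (D(2016, 4, 1), None, D(2016, 4, 1), True),  # closed at start
            (D(2016, 1, 1), D(2016, 4, 1), D(2016, 4, 1), False),  # open at end
            (D(2016, 1, 1), D(2016, 4, 2), D(2016, 4, 1), True),
            (D(2016, 4, 2), None, D(2016, 4, 1), False),
        ],
    )
    def test_half_open_activity(self, start, end, day, active):
        rx = PrescriptionRecord(
            patient_id="P1", drug_code="N06AB04", start_date=start, end_date=end
        )
        assert rx.active_on(day) is active

    @pytest.mark.parametrize(
        "birth,on,expected",
        [
            (D(1950, 6, 15), D(2016, 6, 14), 65),
            (D(1950, 6, 15), D(2016, 6, 15), 66),
            (D(1950, 6, 15), D(2016, 7, 1), 66),
        ],
    )
    def test_age_completed_years(self, birth, on, expected):
        assert age_completed_years(birth, on) == expected


class TestBuildPatientState:
    def _cohort(self):
        return make_cohort(
            patients=[("P1", "D1", D(1950, 6, 15))],
            prescriptions=[
                ("P1", "N06AB04", 20.0, D(2016, 4, 1), None),  # starts on snapshot
                ("P1", "M01AE01", 1200.0, D(2016, 1, 1), D(2016, 4, 1)),  # ends on snapshot
                ("P1", "C03CA01", 40.0, D(2016, 3, 2), None),
            ],
            clinical=[
                ("P1", "egfr", 50.0, D(2016, 1, 10)),
                ("P1", "egfr", 28.0, D(2016, 3, 20)),
                ("P1", "egfr", 99.0, D(2016, 5, 1)),  # after snapshot: ignored
            ],
        )

    def test_boundaries_and_latest_values(self):
        state = build_patient_state(self._cohort(), "P1", D(2016, 4, 1))
        assert state.active_codes() == {"N06AB04", "C03CA01"}
        assert state.age_years == 65
        assert state.latest_clinical_values["egfr"] == (28.0, D(2016, 3, 20))
        durations = {ap.drug_code: ap.duration_days for ap in state.active_prescriptions}
        assert durations == {"N06AB04": 0, "C03CA01": 30}
        validate_patient_state(state)

    def test_unknown_patient_raises(self):
        with pytest.raises(KeyError, match="P9"):
            build_patient_state(self._cohort(), "P9", D(2016, 4, 1))

    @settings(max_examples=50, deadline=None)
    @given(offset=st.integers(min_value=1, max_value=400), before=st.booleans())
    def test_inactive_prescription_never_changes_state(self, offset, before):
        """Adding a prescription whose interval excludes the snapshot date
        leaves the built state unchanged."""
        snapshot = D(2016, 4, 1)
        base = self._cohort()
        if before:
            extra = ("P1", "A02BC01", 20.0,
                     snapshot - dt.timedelta(days=offset + 10),
                     snapshot - dt.timedelta(days=offset - 1))
        else:
            extra = ("P1", "A02BC01", 20.0, snapshot + dt.timedelta(days=offset), None)
        augmented = make_cohort(
            patients=[("P1", "D1", D(1950, 6, 15))],
            prescriptions=[
                ("P1", "N06AB04", 20.0, D(2016, 4, 1), None),
                ("P1", "M01AE01", 1200.0, D(2016, 1, 1), D(2016, 4, 1)),
                ("P1", "C03CA01", 40.0, D(2016, 3, 2), None),
                extra,
            ],
        )
        s0 = build_patient_state(base, "P1", snapshot)
        s1 = build_patient_state(augmented, "P1", snapshot)
        assert s0.active_codes() == s1.active_codes()
        assert s0.age_years == s1.age_years


class TestLoadCohort:
    def _write(self, tmp_path, prescriptions_rows, patients_rows):
        (tmp_path / "prescriptions.csv").write_text(
            "patient_id,drug_code,daily_dose_mg,start_date,end_date\n"
            + "".join(prescriptions_rows)
        )
        (tmp_path / "patients.csv").write_text(
            "patient_id,physician_id,birth_date,sex\n" + "".join(patients_rows)
        )
        (tmp_path / "diagnoses.csv").write_text(
            "patient_id,icd10_code,onset_date,resolved_date\n"
        )

    def test_well_formed_cohort_loads_cleanly(self, tmp_path):
        self._write(
            tmp_path,
            ["P1,N06AB04,20,2016-01-01,\n", "P2,M01AE01,1200,2016-02-01,2016-06-01\n"],
            ["P1,D1,1950-06-15,female\n", "P2,D1,1940-01-01,male\n", "P3,D2,1980-03-03,unknown\n"],
        )
        cohort = load_cohort(
            tmp_path / "prescriptions.csv", tmp_path / "patients.csv", tmp_path / "diagnoses.csv"
        )
        assert len(cohort.patients) == 3
        assert len(cohort.prescriptions) == 2
        assert cohort.report.rejected == {}

    def test_unknown_patient_reference_is_rejected_and_reported(self, tmp_path):
        self._write(
            tmp_path,
            ["P1,N06AB04,20,2016-01-01,\n", "GHOST,M01AE01,1200,2016-02-01,\n"],
            ["P1,D1,1950-06-15,female\n"],
        )
        cohort = load_cohort(
            tmp_path / "prescriptions.csv", tmp_path / "patients.csv", tmp_path / "diagnoses.csv"
        )
        assert len(cohort.prescriptions) == 1
        assert cohort.report.rejected["prescriptions"] == 1
        assert any("GHOST" in reason for _, _, reason in cohort.report.rejected_rows)

    def test_missing_column_names_it(self, tmp_path):
        (tmp_path / "prescriptions.csv").write_text("patient_id,drug_code\nP1,N06AB04\n")
        (tmp_path / "patients.csv").write_text(
            "patient_id,physician_id,birth_date,sex\nP1,D1,1950-06-15,female\n"
        )
        (tmp_path / "diagnoses.csv").write_text("patient_id,icd10_code,onset_date,resolved_date\n")
        with pytest.raises(SchemaError, match="start_date"):
            load_cohort(tmp_path / "prescriptions.csv", tmp_path / "patients.csv", tmp_path / "diagnoses.csv")

    def test_bad_date_reports_row_number(self, tmp_path):
        self._write(tmp_path, ["P1,N06AB04,20,not-a-date,\n"], ["P1,D1,1950-06-15,female\n"])
        with pytest.raises(CohortValidationError, match="row 2"):
            load_cohort(tmp_path / "prescriptions.csv", tmp_path / "patients.csv", tmp_path / "diagnoses.csv")

    def test_duplicate_patient_id_rejected(self, tmp_path):
        self._write(tmp_path, [], ["P1,D1,1950-06-15,female\n", "P1,D2,1960-01-01,male\n"])
        with pytest.raises(CohortValidationError, match="duplicate patient_id"):
            load_cohort(tmp_path / "prescriptions.csv", tmp_path / "patients.csv", tmp_path / "diagnoses.csv")

    def test_round_trip(self, tmp_path):
        cohort = make_cohort(
            patients=[("P1", "D1", D(1950, 6, 15)), ("P2", "D2", D(1941, 2, 2))],
            prescriptions=[
                ("P1", "N06AB04", 20.0, D(2016, 1, 1), None),
                ("P2", "M01AE01", None, D(2016, 2, 1), D(2016, 6, 1)),
            ],
            diagnoses=[("P1", "E11.9", D(2015, 1, 1), None)],
            clinical=[("P2", "potassium", 5.9, D(2016, 3, 1))],
        )
        paths = write_cohort(cohort, tmp_path)
        reloaded = load_cohort(
            paths["prescriptions"], paths["patients"], paths["diagnoses"], paths["clinical"]
        )
        assert reloaded.patients == cohort.patients
        assert sorted(reloaded.prescriptions, key=str) == sorted(cohort.prescriptions, key=str)
        assert reloaded.diagnoses == cohort.diagnoses
        assert reloaded.clinical == cohort.clinical


def test_state_validator_rejects_inconsistent_state():
    state = make_state(drugs=[("N06AB04", 20.0, 50)])
    broken = state.model_copy(update={"snapshot_date": state.snapshot_date + dt.timedelta(days=1)})
    with pytest.raises(ValueError):
        validate_patient_state(broken)
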