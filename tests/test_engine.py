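"""Detection-engine behaviour: worked examples for each rule kind,
determinism, monotonicity, and snapshot bookkeeping."""

from __future__ import annotations

import datetime as dt

import pytest

from selfaudit.engine import (
    detect_duplications,
    detect_duration,
    detect_polymedication,
    detect_triple_whammy,
    evaluate_patient,
    evaluate_rule,
    run_snapshot,
)

from conftest import make_cohort, make_state

D = dt.date
INERT = ["H03AA01", "A11CC05", "B03BA01", "B03AA07", "M04AA01", "C10AA05",
         "C10AA01", "J01CA04", "C07AB02", "C08CA01", "N03AX12"]


class TestDoseThreshold:
    def test_citalopram_high_dose_fires(self, catalog_2016):
        rule = catalog_2016.rule("citalopram_dose")
        state = make_state(age=50, drugs=[("N06AB04", 60.0)])
        (alert,) = evaluate_rule(rule, state, catalog_2016)
        assert alert.triggering_drugs == ("N06AB04",)

    def test_citalopram_standard_dose_silent(self, catalog_2016):
        rule = catalog_2016.rule("citalopram_dose")
        state = make_state(age=50, drugs=[("N06AB04", 20.0)])
        assert evaluate_rule(rule, state, catalog_2016) == []

    def test_elderly_tier_is_strict_over_65(self, catalog_2016):
        rule = catalog_2016.rule("citalopram_dose")
        at_65 = make_state(age=65, drugs=[("N06AB04", 30.0)])
        at_66 = make_state(age=66, drugs=[("N06AB04", 30.0)])
        assert evaluate_rule(rule, at_65, catalog_2016) == []
        assert len(evaluate_rule(rule, at_66, catalog_2016)) == 1

    def test_liver_dysfunction_tier_reports_diagnosis(self, catalog_2016):
        rule = catalog_2016.rule("citalopram_dose")
        state = make_state(age=50, drugs=[("N06AB04", 30.0)], diagnoses=["K70.3"])
        (alert,) = evaluate_rule(rule, state, catalog_2016)
        assert alert.triggering_diagnoses == ("K70.3",)

    def test_missing_dose_is_skipped(self, catalog_2016):
        rule = catalog_2016.rule("citalopram_dose")
        state = make_state(age=80, drugs=[("N06AB04", None)])
        assert evaluate_rule(rule, state, catalog_2016) == []


class TestCoPrescriptionAndAge:
    def test_ivabradine_verapamil(self, catalog_2016):
        rule = catalog_2016.rule("ivabradine_verapamil")
        both = make_state(drugs=[("C01EB17", 10.0), ("C08DA01", 240.0)])
        (alert,) = evaluate_rule(rule, both, catalog_2016)
        assert alert.triggering_drugs == ("C01EB17", "C08DA01")
        alone = make_state(drugs=[("C01EB17", 10.0)])
        assert evaluate_rule(rule, alone, catalog_2016) == []

    def test_agomelatine_age_threshold_inclusive(self, catalog_2016):
        rule = catalog_2016.rule("agomelatine_age")
        assert len(evaluate_rule(rule, make_state(age=75, drugs=[("N06AX22", 25.0)]), catalog_2016)) == 1
        assert evaluate_rule(rule, make_state(age=74, drugs=[("N06AX22", 25.0)]), catalog_2016) == []

    def test_cilostazol_needs_two_other_antiplatelets(self, catalog_2016):
        rule = catalog_2016.rule("cilostazol_two_antiplatelets")
        # cilostazol is itself antiplatelet-tagged but cannot fill both slots
        two = make_state(drugs=[("B01AC23", 200.0), ("B01AC06", 100.0)])
        assert evaluate_rule(rule, two, catalog_2016) == []
        three = make_state(drugs=[("B01AC23", 200.0), ("B01AC06", 100.0), ("B01AC04", 75.0)])
        (alert,) = evaluate_rule(rule, three, catalog_2016)
        assert alert.triggering_drugs == ("B01AC04", "B01AC06", "B01AC23")


class TestComorbidityAndClinical:
    def test_aliskiren_diagnosis_or_treatment_qualifier(self, catalog_2016):
        rule = catalog_2016.rule("aliskiren_diabetes")
        with_dx = make_state(drugs=[("C09XA02", 150.0)], diagnoses=["E11.9"])
        (alert,) = evaluate_rule(rule, with_dx, catalog_2016)
        assert alert.triggering_diagnoses == ("E11.9",)
        with_drug = make_state(drugs=[("C09XA02", 150.0), ("A10BA02", 1000.0)])
        (alert,) = evaluate_rule(rule, with_drug, catalog_2016)
        assert alert.triggering_drugs == ("C09XA02",)
        neither = make_state(drugs=[("C09XA02", 150.0)])
        assert evaluate_rule(rule, neither, catalog_2016) == []

    def test_low_egfr_blocks_nsaid(self, catalog_2016):
        rule = catalog_2016.rule("nsaid_low_egfr")
        bad = make_state(drugs=[("M01AE02", 1000.0)], clinical={"egfr": 24.0})
        (alert,) = evaluate_rule(rule, bad, catalog_2016)
        assert alert.triggering_drugs == ("M01AE02",)
        ok = make_state(drugs=[("M01AE02", 1000.0)], clinical={"egfr": 60.0})
        assert evaluate_rule(rule, ok, catalog_2016) == []
        unmeasured = make_state(drugs=[("M01AE02", 1000.0)])
        assert evaluate_rule(rule, unmeasured, catalog_2016) == []


class TestTripleWhammy:
    TRIPLE = [("M01AE01", 1200.0), ("C09AA02", 20.0), ("C03CA01", 40.0)]

    def test_fires_for_elderly(self, catalog_2016):
        rule = catalog_2016.rule("triple_whammy")
        (alert,) = detect_triple_whammy(make_state(age=80, drugs=self.TRIPLE), rule, catalog_2016)
        assert alert.triggering_drugs == ("C03CA01", "C09AA02", "M01AE01")

    def test_age_or_diabetes_qualifier(self, catalog_2016):
        rule = catalog_2016.rule("triple_whammy")
        assert detect_triple_whammy(make_state(age=50, drugs=self.TRIPLE), rule, catalog_2016) == []
        diabetic = make_state(age=50, drugs=self.TRIPLE + [("A10BA02", 1000.0)])
        assert len(detect_triple_whammy(diabetic, rule, catalog_2016)) == 1

    def test_missing_group_silent(self, catalog_2016):
        rule = catalog_2016.rule("triple_whammy")
        state = make_state(age=80, drugs=[("M01AE01", 1200.0), ("C03CA01", 40.0)])
        assert detect_triple_whammy(state, rule, catalog_2016) == []

    def test_one_alert_even_with_many_candidates(self, catalog_2016):
        rule = catalog_2016.rule("triple_whammy")
        state = make_state(age=80, drugs=self.TRIPLE + [("M01AE02", 1000.0), ("C09AA05", 5.0)])
        alerts = detect_triple_whammy(state, rule, catalog_2016)
        assert len(alerts) == 1
        assert alerts[0].triggering_drugs == ("C03CA01", "C09AA02", "M01AE01")


class TestDuplications:
    def test_same_principle_two_prescriptions(self, catalog_2016):
        state = make_state(drugs=[("A02BC01", 20.0, 200), ("A02BC01", 20.0, 50)])
        (alert,) = detect_duplications(state, catalog_2016)
        assert alert.triggering_drugs == ("A02BC01",)
        assert alert.indicator_linked

    def test_same_group_two_principles(self, catalog_2016):
        state = make_state(drugs=[("M01AE01", 1200.0), ("M01AE02", 1000.0)])
        (alert,) = detect_duplications(state, catalog_2016)
        assert alert.triggering_drugs == ("M01AE01", "M01AE02")

    def test_single_drug_silent(self, catalog_2016):
        assert detect_duplications(make_state(drugs=[("M01AE01", 1200.0)]), catalog_2016) == []

    def test_principle_basis_wins_over_group(self, catalog_2016):
        # plain paracetamol + combination sharing the principle and the tag
        state = make_state(drugs=[("N02BE01", 2000.0), ("N02BE51", 2000.0)])
        (alert,) = detect_duplications(state, catalog_2016)
        assert alert.relevance.value == "high"

    def test_dose_adjustment_group_not_indicator_linked(self, catalog_2016):
        state = make_state(drugs=[("A10AB01", 40.0), ("A10AE04", 20.0)])
        (alert,) = detect_duplications(state, catalog_2016)
        assert not alert.indicator_linked
        assert alert.relevance.value == "low"


class TestDuration:
    def test_bisphosphonate_five_years(self, catalog_2016):
        rule = catalog_2016.rule("bisphosphonate_5y")
        six_years = make_state(drugs=[("M05BA04", 70.0, 6 * 365)])
        assert len(detect_duration(six_years, rule, catalog_2016)) == 1
        two_years = make_state(drugs=[("M05BA04", 70.0, 2 * 365)])
        assert detect_duration(two_years, rule, catalog_2016) == []

    def test_double_antiplatelet_overlap(self, catalog_2016):
        rule = catalog_2016.rule("dapt_12m")
        state = make_state(drugs=[("B01AC06", 100.0, 400), ("B01AC04", 75.0, 380)])
        (alert,) = detect_duration(state, rule, catalog_2016)
        assert alert.triggering_drugs == ("B01AC04", "B01AC06")
        short = make_state(drugs=[("B01AC06", 100.0, 400), ("B01AC04", 75.0, 100)])
        assert detect_duration(short, rule, catalog_2016) == []


class TestPolymedication:
    def _drugs(self, n_extra):
        return [("N05BB01", 50.0), ("N04AA01", 6.0)] + [(c, 1.0) for c in INERT[:n_extra]]

    def _sub(self, state, catalog):
        return evaluate_rule(catalog.rule("anticholinergic_combo"), state, catalog)

    def test_fires_with_eleven_drugs_2016(self, catalog_2016):
        rule = catalog_2016.rule("polymedication")
        state = make_state(age=70, drugs=self._drugs(9))  # 11 distinct drugs
        (alert,) = detect_polymedication(state, rule, catalog_2016, self._sub(state, catalog_2016))
        assert alert.triggering_drugs == ("N04AA01", "N05BB01")

    def test_age_gate_is_strict(self, catalog_2016):
        rule = catalog_2016.rule("polymedication")
        state = make_state(age=60, drugs=self._drugs(10))
        assert detect_polymedication(state, rule, catalog_2016, self._sub(state, catalog_2016)) == []

    def test_requires_qualifying_sub_alert(self, catalog_2016):
        rule = catalog_2016.rule("polymedication")
        state = make_state(age=70, drugs=[(c, 1.0) for c in INERT])
        assert detect_polymedication(state, rule, catalog_2016, []) == []

    def test_nine_drugs_fires_only_under_2018_threshold(self, catalog_2016, catalog_2017, catalog_2018):
        for catalog, expected in [(catalog_2016, 0), (catalog_2017, 0), (catalog_2018, 1)]:
            rule = catalog.rule("polymedication")
            state = make_state(age=70, drugs=self._drugs(7))  # 9 distinct drugs
            got = detect_polymedication(state, rule, catalog, self._sub(state, catalog))
            assert len(got) == expected, catalog.year_label


class TestMonotonicity:
    def test_removing_a_drug_never_adds_alerts(self, catalog_2016):
        state = make_state(
            age=80,
            drugs=[("M01AE01", 1200.0), ("C09AA02", 20.0), ("C03CA01", 40.0),
                   ("N06AB04", 60.0), ("C01BD01", 200.0)],
        )
        full = {a.identity_key for a in evaluate_patient(state, catalog_2016)}
        reduced_state = make_state(
            age=80,
            drugs=[("C09AA02", 20.0), ("C03CA01", 40.0), ("N06AB04", 60.0), ("C01BD01", 200.0)],
        )
        reduced = {a.identity_key for a in evaluate_patient(reduced_state, catalog_2016)}
        # alerts not involving the removed drug survive
        survivors = {k for k in full if "M01AE01" not in k}
        assert survivors <= reduced

    def test_adding_disjoint_drug_preserves_alerts(self, catalog_2016):
        base = make_state(age=50, drugs=[("C01EB17", 10.0), ("C08DA01", 240.0)])
        before = {a.identity_key for a in evaluate_patient(base, catalog_2016)}
        more = make_state(age=50, drugs=[("C01EB17", 10.0), ("C08DA01", 240.0), ("H03AA01", 0.1)])
        after = {a.identity_key for a in evaluate_patient(more, catalog_2016)}
        assert before <= after


class TestRunSnapshot:
    def test_empty_cohort(self, catalog_2016):
        snap = run_snapshot(make_cohort(patients=[]), catalog_2016, D(2016, 4, 1))
        assert snap.alerts == []
        assert snap.per_category_counts == {}

    def test_counts_sum_and_determinism(self, catalog_2016):
        cohort = make_cohort(
            patients=[("P1", "D1", D(1940, 1, 1)), ("P2", "D2", D(1950, 1, 1))],
            prescriptions=[
                ("P1", "C01EB17", 10.0, D(2016, 1, 1), None),
                ("P1", "C08DA01", 240.0, D(2016, 1, 1), None),
                ("P2", "N06AB04", 60.0, D(2016, 1, 1), None),
                ("P2", "N06BX06", 1000.0, D(2016, 1, 1), None),
            ],
        )
        snap = run_snapshot(cohort, catalog_2016, D(2016, 4, 1))
        assert sum(snap.per_category_counts.values()) == len(snap.alerts)
        assert sum(snap.per_physician_counts.values()) == len(snap.alerts)
        assert snap.per_physician_counts == {"D1": 1, "D2": 2}
        again = run_snapshot(cohort, catalog_2016, D(2016, 4, 1))
        assert snap.to_frame().to_csv() == again.to_frame().to_csv()
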