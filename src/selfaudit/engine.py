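"""Detection engine: evaluate MRP rules against patient states.

Every rule kind is evaluated against a :class:`~selfaudit.models.PatientState`
and emits :class:`MrpAlert` instances.  Alerts carry a stable
``identity_key`` — patient, rule and the sorted set of triggering drug
codes — which is what the longitudinal tracker matches between two
snapshot dates to classify a problem as resolved, persisting or new.

Counting semantics: one alert per distinct triggering drug-set.  For
combination rules (co-prescription, Triple Whammy) the triggering set is
the lexicographically smallest assignment of distinct active drugs that
satisfies every slot, so a patient yields at most one alert per such rule
and output is deterministic.
"""

from __future__ import annotations

import datetime as dt
import itertools
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel

from .catalog import (
    AgeRestrictionParams,
    Category,
    ClinicalVariableParams,
    ComorbidityParams,
    CoPrescriptionParams,
    DoseThresholdParams,
    DuplicationGroup,
    DurationParams,
    ListMembershipParams,
    MrpRule,
    PolymedicationParams,
    Relevance,
    RuleCatalog,
    RuleKind,
    TripleWhammyParams,
)
from .io import Cohort, build_patient_state
from .models import PatientState

logger = logging.getLogger(__name__)

# rule kinds evaluate_rule handles directly; the rest have dedicated entry
# points because they aggregate across drugs or other alerts
SIMPLE_KINDS = {
    RuleKind.dose_threshold,
    RuleKind.age_restriction,
    RuleKind.comorbidity_contraindication,
    RuleKind.co_prescription,
    RuleKind.clinical_variable,
    RuleKind.list_membership,
}


def make_identity_key(patient_id: str, rule_id: str, triggering_drugs: Iterable[str]) -> str:
    return "|".join([patient_id, rule_id, *sorted(triggering_drugs)])


class MrpAlert(BaseModel):
    model_config = {"frozen": True}

    patient_id: str
    rule_id: str
    category: Category
    relevance: Relevance
    indicator_linked: bool
    triggering_drugs: tuple[str, ...] = ()
    triggering_diagnoses: tuple[str, ...] = ()
    snapshot_date: dt.date
    physician_id: str = ""

    @property
    def identity_key(self) -> str:
        return make_identity_key(self.patient_id, self.rule_id, self.triggering_drugs)

    def sort_key(self) -> tuple[str, str]:
        return (self.rule_id, self.identity_key)


def _mk_alert(
    rule: MrpRule,
    state: PatientState,
    drugs: Iterable[str],
    diagnoses: Iterable[str] = (),
    *,
    relevance: Optional[Relevance] = None,
    indicator_linked: Optional[bool] = None,
) -> MrpAlert:
    drugs = tuple(sorted(set(drugs)))
    diagnoses = tuple(sorted(set(diagnoses)))
    if not drugs and not diagnoses:
        raise ValueError(f"rule {rule.rule_id}: alert with empty trigger sets")
    return MrpAlert(
        patient_id=state.patient_id,
        rule_id=rule.rule_id,
        category=rule.category,
        relevance=relevance if relevance is not None else rule.relevance,
        indicator_linked=indicator_linked if indicator_linked is not None else rule.indicator_linked,
        triggering_drugs=drugs,
        triggering_diagnoses=diagnoses,
        snapshot_date=state.snapshot_date,
    )


def _active_matching(state: PatientState, catalog: RuleCatalog, selector) -> list:
    out = []
    for ap in state.active_prescriptions:
        entry = catalog.entry(ap.drug_code)
        if entry is not None and selector.matches(entry):
            out.append(ap)
    return out


def _diagnoses_matching(state: PatientState, catalog: RuleCatalog, concepts: Iterable[str]) -> set[str]:
    return {
        dx
        for dx in state.active_diagnoses
        for concept in concepts
        if catalog.icd10_in_concept(dx, concept)
    }


def _co_prescription_assignment(
    state: PatientState, catalog: RuleCatalog, slots: Iterable
) -> Optional[tuple[str, ...]]:
    """Smallest (sorted-tuple) assignment of distinct active drug codes
    filling every slot's ``min_count``, or None if unsatisfiable."""
    candidates = []
    for slot in slots:
        codes = sorted({ap.drug_code for ap in _active_matching(state, catalog, slot.drug)})
        if len(codes) < slot.min_count:
            return None
        candidates.append((codes, slot.min_count))

    best: Optional[tuple[str, ...]] = None
    for combo in itertools.product(
        *(itertools.combinations(codes, k) for codes, k in candidates)
    ):
        flat = [c for group in combo for c in group]
        if len(set(flat)) != len(flat):
            continue
        key = tuple(sorted(set(flat)))
        if best is None or key < best:
            best = key
    return best


def evaluate_rule(rule: MrpRule, state: PatientState, catalog: RuleCatalog) -> list[MrpAlert]:
    """Evaluate one simple rule (dose, age, comorbidity, co-prescription,
    clinical variable, list membership) against a patient state.

    A rule that cannot apply returns an empty list, never raises.
    Prescriptions lacking a dose are skipped by dose rules (never alert on
    an unknown dose), with a warning logged.
    """
    if rule.kind not in SIMPLE_KINDS:
        raise ValueError(
            f"rule {rule.rule_id} of kind {rule.kind.value} has a dedicated entry point"
        )
    p = rule.parameters
    alerts: list[MrpAlert] = []

    if isinstance(p, DoseThresholdParams):
        fired: set[str] = set()
        for ap in _active_matching(state, catalog, p.drug):
            if ap.drug_code in fired:
                continue
            if ap.daily_dose_mg is None:
                logger.warning(
                    "rule %s: prescription %s for %s has no daily dose; skipped",
                    rule.rule_id, ap.drug_code, state.patient_id,
                )
                continue
            for tier in p.tiers:
                if tier.age_gt is not None and not state.age_years > tier.age_gt:
                    continue
                if tier.comorbidity_set is not None and not _diagnoses_matching(
                    state, catalog, [tier.comorbidity_set]
                ):
                    continue
                if ap.daily_dose_mg > tier.threshold_mg_per_day:
                    dx = (
                        _diagnoses_matching(state, catalog, [tier.comorbidity_set])
                        if tier.comorbidity_set
                        else set()
                    )
                    alerts.append(_mk_alert(rule, state, [ap.drug_code], dx))
                    fired.add(ap.drug_code)
                    break

    elif isinstance(p, AgeRestrictionParams):
        ok = state.age_years >= p.age_threshold if p.comparator == "gte" else state.age_years > p.age_threshold
        if ok:
            for code in sorted({ap.drug_code for ap in _active_matching(state, catalog, p.drug)}):
                alerts.append(_mk_alert(rule, state, [code]))

    elif isinstance(p, ComorbidityParams):
        dx = _diagnoses_matching(state, catalog, p.concept_sets)
        qualifies = bool(dx)
        if not qualifies and p.or_drug_group is not None:
            qualifies = bool(_active_matching(state, catalog, p.or_drug_group))
        if qualifies:
            for code in sorted({ap.drug_code for ap in _active_matching(state, catalog, p.drug)}):
                alerts.append(_mk_alert(rule, state, [code], dx))

    elif isinstance(p, CoPrescriptionParams):
        assignment = _co_prescription_assignment(state, catalog, p.groups)
        if assignment is not None:
            alerts.append(_mk_alert(rule, state, assignment))

    elif isinstance(p, ClinicalVariableParams):
        latest = state.latest_clinical_values.get(p.variable)
        if latest is not None:
            value = latest[0]
            cmp_ok = {
                "lt": value < p.threshold,
                "lte": value <= p.threshold,
                "gt": value > p.threshold,
                "gte": value >= p.threshold,
            }[p.comparator]
            if cmp_ok:
                for code in sorted({ap.drug_code for ap in _active_matching(state, catalog, p.drug)}):
                    alerts.append(_mk_alert(rule, state, [code]))

    elif isinstance(p, ListMembershipParams):
        if p.age_gt is None or state.age_years > p.age_gt:
            for code in sorted({ap.drug_code for ap in _active_matching(state, catalog, p.drug)}):
                alerts.append(_mk_alert(rule, state, [code]))

    alerts.sort(key=MrpAlert.sort_key)
    return alerts


def detect_triple_whammy(state: PatientState, rule: MrpRule, catalog: RuleCatalog) -> list[MrpAlert]:
    """NSAID + RAS inhibitor + diuretic in a patient aged >= 75 or under
    antidiabetic treatment.  At most one alert per patient: the minimal
    lexicographic representative triple."""
    p = rule.parameters
    assert isinstance(p, TripleWhammyParams)
    nsaids = sorted({ap.drug_code for ap in _active_matching(state, catalog, p.nsaid)})
    ras = sorted({ap.drug_code for ap in _active_matching(state, catalog, p.ras_inhibitor)})
    diuretics = sorted({ap.drug_code for ap in _active_matching(state, catalog, p.diuretic)})
    if not (nsaids and ras and diuretics):
        return []
    if state.age_years < p.age_gte and not _active_matching(state, catalog, p.antidiabetic):
        return []
    best: Optional[tuple[str, ...]] = None
    for triple in itertools.product(nsaids, ras, diuretics):
        if len(set(triple)) != 3:
            continue
        key = tuple(sorted(triple))
        if best is None or key < best:
            best = key
    if best is None:
        return []
    return [_mk_alert(rule, state, best)]


def detect_duplications(state: PatientState, catalog: RuleCatalog) -> list[MrpAlert]:
    """Therapeutic duplications: two or more active drugs sharing an
    active principle (alone or in combination) or a duplication-group tag.

    One alert per (patient, basis).  A drug set duplicated at both the
    principle and the group level yields one alert — the principle basis
    wins.  Principle-level duplications are always clinically relevant;
    group-level ones take the group's relevance flag (a "dose adjustment"
    group is detected at low relevance and not indicator-linked).
    """
    try:
        rule = next(r for r in catalog.rules if r.kind is RuleKind.duplication_group)
    except StopIteration:
        return []

    active = [ap for ap in state.active_prescriptions if catalog.entry(ap.drug_code) is not None]
    alerts: list[MrpAlert] = []
    principle_sets: list[frozenset[str]] = []

    # principle basis: >= 2 active prescriptions sharing an active principle
    by_principle: dict[str, list] = {}
    for ap in active:
        for principle in catalog.entry(ap.drug_code).component_principles:
            by_principle.setdefault(principle, []).append(ap)
    for principle in sorted(by_principle):
        aps = by_principle[principle]
        if len(aps) >= 2:
            drugs = frozenset(ap.drug_code for ap in aps)
            if drugs in principle_sets:
                continue  # same drug set already alerted via another shared principle
            principle_sets.append(drugs)
            alerts.append(
                _mk_alert(rule, state, drugs, relevance=Relevance.high, indicator_linked=rule.indicator_linked)
            )

    # group basis: >= 2 distinct principles among drugs sharing a dup tag
    for group in sorted(catalog.duplication_groups, key=lambda g: g.group_id):
        tagged = [ap for ap in active if group.member_tag in catalog.entry(ap.drug_code).group_tags]
        codes = sorted({ap.drug_code for ap in tagged})
        principles = set().union(*(catalog.entry(c).component_principles for c in codes)) if codes else set()
        if len(codes) >= 2 and len(principles) >= 2:
            drugs = frozenset(codes)
            if drugs in principle_sets:
                continue  # same drug set already alerted at principle level
            relevant = group.clinically_relevant
            alerts.append(
                _mk_alert(
                    rule,
                    state,
                    drugs,
                    relevance=Relevance.high if relevant else Relevance.low,
                    indicator_linked=rule.indicator_linked and relevant,
                )
            )

    alerts.sort(key=MrpAlert.sort_key)
    return alerts


def detect_duration(state: PatientState, rule: MrpRule, catalog: RuleCatalog) -> list[MrpAlert]:
    """Treatment-duration rules.

    ``per_drug`` (e.g. bisphosphonates >= 5 years): one alert per matching
    drug whose elapsed duration reaches ``min_days``.  ``overlap`` (double
    antiplatelet >= 12 months): one alert when >= ``min_count`` matching
    drugs are concurrently active and the overlap (minimum duration of the
    best pair) reaches ``min_days``.
    """
    p = rule.parameters
    assert isinstance(p, DurationParams)
    matching = _active_matching(state, catalog, p.drug)
    alerts: list[MrpAlert] = []

    if p.mode == "per_drug":
        for code in sorted({ap.drug_code for ap in matching if ap.duration_days >= p.min_days}):
            alerts.append(_mk_alert(rule, state, [code]))
    else:
        # longest duration per distinct drug code
        per_code: dict[str, int] = {}
        for ap in matching:
            per_code[ap.drug_code] = max(per_code.get(ap.drug_code, -1), ap.duration_days)
        if len(per_code) >= p.min_count:
            # pair with the greatest overlap; lexicographic tie-break
            ranked = sorted(per_code.items(), key=lambda kv: (-kv[1], kv[0]))
            top = ranked[: p.min_count]
            if min(d for _, d in top) >= p.min_days:
                alerts.append(_mk_alert(rule, state, [c for c, _ in top]))

    alerts.sort(key=MrpAlert.sort_key)
    return alerts


def detect_polymedication(
    state: PatientState,
    rule: MrpRule,
    catalog: RuleCatalog,
    sub_alerts: list[MrpAlert],
) -> list[MrpAlert]:
    """Polymedication in the elderly: age over the gate, at least the
    catalog's threshold of distinct active drugs, and at least one
    qualifying sub-problem (long double antiplatelet therapy, an
    anticholinergic combination, or avoidable medication)."""
    p = rule.parameters
    assert isinstance(p, PolymedicationParams)
    if not state.age_years > p.age_gt:
        return []
    n_drugs = len(state.active_codes())
    threshold_ok = (
        n_drugs >= catalog.polymedication_threshold
        if catalog.polymedication_comparator == "gte"
        else n_drugs > catalog.polymedication_threshold
    )
    if not threshold_ok:
        return []
    qualifying = [
        a for a in sub_alerts
        if a.rule_id in p.qualifying_rules and a.patient_id == state.patient_id
    ]
    if not qualifying:
        return []
    drugs = sorted({d for a in qualifying for d in a.triggering_drugs})
    return [_mk_alert(rule, state, drugs)]


@dataclass
class Snapshot:
    """All alerts for a cohort on one extraction date."""

    snapshot_date: dt.date
    year_label: str
    alerts: list[MrpAlert]
    per_category_counts: dict[str, int] = field(default_factory=dict)
    per_physician_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.per_category_counts:
            self.per_category_counts = dict(Counter(a.category.value for a in self.alerts))
        if not self.per_physician_counts:
            self.per_physician_counts = dict(Counter(a.physician_id for a in self.alerts))

    def identity_keys(self) -> set[str]:
        return {a.identity_key for a in self.alerts}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": a.patient_id,
                    "rule_id": a.rule_id,
                    "category": a.category.value,
                    "relevance": a.relevance.value,
                    "indicator_linked": a.indicator_linked,
                    "triggering_drugs": "|".join(a.triggering_drugs),
                    "triggering_diagnoses": "|".join(a.triggering_diagnoses),
                    "snapshot_date": a.snapshot_date.isoformat(),
                    "physician_id": a.physician_id,
                    "identity_key": a.identity_key,
                }
                for a in self.alerts
            ],
            columns=[
                "patient_id", "rule_id", "category", "relevance", "indicator_linked",
                "triggering_drugs", "triggering_diagnoses", "snapshot_date",
                "physician_id", "identity_key",
            ],
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "alerts.csv", index=False)
        summary = {
            "snapshot_date": self.snapshot_date.isoformat(),
            "year_label": self.year_label,
            "n_alerts": len(self.alerts),
            "per_category_counts": dict(sorted(self.per_category_counts.items())),
            "per_physician_counts": dict(sorted(self.per_physician_counts.items())),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


def evaluate_patient(state: PatientState, catalog: RuleCatalog) -> list[MrpAlert]:
    """Apply every catalog rule to one patient state (all dispatchers)."""
    alerts: list[MrpAlert] = []
    poly_rules: list[MrpRule] = []
    for rule in catalog.rules:
        if rule.kind in SIMPLE_KINDS:
            alerts.extend(evaluate_rule(rule, state, catalog))
        elif rule.kind is RuleKind.composite_triple_whammy:
            alerts.extend(detect_triple_whammy(state, rule, catalog))
        elif rule.kind is RuleKind.duration:
            alerts.extend(detect_duration(state, rule, catalog))
        elif rule.kind is RuleKind.polymedication:
            poly_rules.append(rule)
    alerts.extend(detect_duplications(state, catalog))
    for rule in poly_rules:  # needs the other alerts as qualifying input
        alerts.extend(detect_polymedication(state, rule, catalog, alerts))
    alerts.sort(key=MrpAlert.sort_key)
    return alerts


def run_snapshot(cohort: Cohort, catalog: RuleCatalog, snapshot_date: dt.date) -> Snapshot:
    """Evaluate the full catalog for every patient on one date."""
    alerts: list[MrpAlert] = []
    for patient_id in sorted(cohort.patients):
        state = build_patient_state(cohort, patient_id, snapshot_date)
        physician = cohort.physician_of(patient_id)
        for a in evaluate_patient(state, catalog):
            alerts.append(a.model_copy(update={"physician_id": physician}))
    alerts.sort(key=MrpAlert.sort_key)
    return Snapshot(snapshot_date=snapshot_date, year_label=catalog.year_label, alerts=alerts)
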