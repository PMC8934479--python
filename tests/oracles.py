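"""Independent brute-force re-implementations of the detection criteria.

Written directly from the clinical definitions (naive loops and
exhaustive enumeration, no shared code with the engine) to serve as
oracles in equivalence tests.  Each oracle returns a set of
``(frozenset(drug_codes), frozenset(diagnosis_codes))`` trigger pairs.
"""

from __future__ import annotations

import itertools

Trigger = tuple[frozenset, frozenset]


def _tags(catalog, code):
    e = catalog.drug_catalog.get(code)
    return e.group_tags if e is not None else frozenset()


def _principles(catalog, code):
    e = catalog.drug_catalog.get(code)
    return e.component_principles if e is not None else frozenset()


def _selected(catalog, selector, code):
    if selector.tag is not None:
        return selector.tag in _tags(catalog, code)
    return code in selector.codes


def _dx_matching(state, catalog, concepts):
    hits = set()
    for dx in state.active_diagnoses:
        for concept in concepts:
            for prefix in catalog.icd10_concept_sets[concept]:
                if dx.startswith(prefix):
                    hits.add(dx)
    return hits


def oracle_dose(state, rule, catalog) -> set[Trigger]:
    p = rule.parameters
    out = set()
    for ap in state.active_prescriptions:
        if not _selected(catalog, p.drug, ap.drug_code):
            continue
        if ap.daily_dose_mg is None:
            continue
        for tier in p.tiers:
            if tier.age_gt is not None and state.age_years <= tier.age_gt:
                continue
            matching_dx = frozenset()
            if tier.comorbidity_set is not None:
                matching_dx = frozenset(_dx_matching(state, catalog, [tier.comorbidity_set]))
                if not matching_dx:
                    continue
            if ap.daily_dose_mg > tier.threshold_mg_per_day:
                out.add((frozenset([ap.drug_code]), matching_dx))
                break
    # one alert per drug code: merge tiers fired by separate prescriptions
    merged = {}
    for drugs, dx in out:
        merged.setdefault(drugs, dx)
    return {(d, x) for d, x in merged.items()}


def oracle_age(state, rule, catalog) -> set[Trigger]:
    p = rule.parameters
    if p.comparator == "gte":
        if state.age_years < p.age_threshold:
            return set()
    elif state.age_years <= p.age_threshold:
        return set()
    return {
        (frozenset([ap.drug_code]), frozenset())
        for ap in state.active_prescriptions
        if _selected(catalog, p.drug, ap.drug_code)
    }


def oracle_comorbidity(state, rule, catalog) -> set[Trigger]:
    p = rule.parameters
    dx = frozenset(_dx_matching(state, catalog, p.concept_sets))
    qualifies = bool(dx)
    if not qualifies and p.or_drug_group is not None:
        qualifies = any(
            _selected(catalog, p.or_drug_group, ap.drug_code)
            for ap in state.active_prescriptions
        )
    if not qualifies:
        return set()
    return {
        (frozenset([ap.drug_code]), dx)
        for ap in state.active_prescriptions
        if _selected(catalog, p.drug, ap.drug_code)
    }


def oracle_co_prescription(state, rule, catalog) -> set[Trigger]:
    p = rule.parameters
    active = sorted({ap.drug_code for ap in state.active_prescriptions})
    best = None
    # exhaustive assignment of distinct codes to slots
    slot_candidates = []
    for slot in p.groups:
        cands = [c for c in active if _selected(catalog, slot.drug, c)]
        slot_candidates.append(list(itertools.combinations(cands, slot.min_count)))
    for assignment in itertools.product(*slot_candidates):
        flat = [c for grp in assignment for c in grp]
        if len(set(flat)) != len(flat):
            continue
        key = tuple(sorted(set(flat)))
        if best is None or key < best:
            best = key
    if best is None:
        return set()
    return {(frozenset(best), frozenset())}


def oracle_clinical(state, rule, catalog) -> set[Trigger]:
    p = rule.parameters
    got = state.latest_clinical_values.get(p.variable)
    if got is None:
        return set()
    v = got[0]
    ok = (
        (p.comparator == "lt" and v < p.threshold)
        or (p.comparator == "lte" and v <= p.threshold)
        or (p.comparator == "gt" and v > p.threshold)
        or (p.comparator == "gte" and v >= p.threshold)
    )
    if not ok:
        return set()
    return {
        (frozenset([ap.drug_code]), frozenset())
        for ap in state.active_prescriptions
        if _selected(catalog, p.drug, ap.drug_code)
    }


def oracle_list_membership(state, rule, catalog) -> set[Trigger]:
    p = rule.parameters
    if p.age_gt is not None and state.age_years <= p.age_gt:
        return set()
    return {
        (frozenset([ap.drug_code]), frozenset())
        for ap in state.active_prescriptions
        if _selected(catalog, p.drug, ap.drug_code)
    }


def oracle_triple_whammy(state, rule, catalog) -> set[Trigger]:
    p = rule.parameters
    active = sorted({ap.drug_code for ap in state.active_prescriptions})
    nsaids = [c for c in active if _selected(catalog, p.nsaid, c)]
    ras = [c for c in active if _selected(catalog, p.ras_inhibitor, c)]
    diur = [c for c in active if _selected(catalog, p.diuretic, c)]
    diabetic = any(_selected(catalog, p.antidiabetic, c) for c in active)
    if not (nsaids and ras and diur):
        return set()
    if state.age_years < p.age_gte and not diabetic:
        return set()
    best = None
    for triple in itertools.product(nsaids, ras, diur):
        if len(set(triple)) < 3:
            continue
        key = tuple(sorted(triple))
        if best is None or key < best:
            best = key
    if best is None:
        return set()
    return {(frozenset(best), frozenset())}


def oracle_duplications(state, catalog) -> set[tuple[frozenset, bool]]:
    """All duplication bases by exhaustive pairwise comparison.  Returns
    {(drug_set, clinically_relevant)}."""
    active = [ap for ap in state.active_prescriptions if ap.drug_code in catalog.drug_catalog]
    out: dict[frozenset, bool] = {}

    principle_sets = set()
    all_principles = set()
    for ap in active:
        all_principles |= _principles(catalog, ap.drug_code)
    for principle in all_principles:
        sharers = [ap for ap in active if principle in _principles(catalog, ap.drug_code)]
        if len(sharers) >= 2:
            drugs = frozenset(ap.drug_code for ap in sharers)
            principle_sets.add(drugs)
            out[drugs] = True

    for group in catalog.duplication_groups:
        codes = sorted({ap.drug_code for ap in active if group.member_tag in _tags(catalog, ap.drug_code)})
        principles = set()
        for c in codes:
            principles |= _principles(catalog, c)
        if len(codes) >= 2 and len(principles) >= 2:
            drugs = frozenset(codes)
            if drugs not in principle_sets:
                out.setdefault(drugs, group.clinically_relevant)
    return {(d, rel) for d, rel in out.items()}


def oracle_duration(state, rule, catalog) -> set[Trigger]:
    p = rule.parameters
    matching = [ap for ap in state.active_prescriptions if _selected(catalog, p.drug, ap.drug_code)]
    if p.mode == "per_drug":
        return {
            (frozenset([ap.drug_code]), frozenset())
            for ap in matching
            if ap.duration_days >= p.min_days
        }
    longest: dict[str, int] = {}
    for ap in matching:
        longest[ap.drug_code] = max(longest.get(ap.drug_code, -1), ap.duration_days)
    if len(longest) < p.min_count:
        return set()
    ranked = sorted(longest.items(), key=lambda kv: (-kv[1], kv[0]))
    chosen = ranked[: p.min_count]
    if min(d for _, d in chosen) < p.min_days:
        return set()
    return {(frozenset(c for c, _ in chosen), frozenset())}


def oracle_polymedication(state, rule, catalog, sub_alerts) -> set[Trigger]:
    p = rule.parameters
    if state.age_years <= p.age_gt:
        return set()
    n = len({ap.drug_code for ap in state.active_prescriptions})
    if catalog.polymedication_comparator == "gte":
        if n < catalog.polymedication_threshold:
            return set()
    elif n <= catalog.polymedication_threshold:
        return set()
    qualifying = [a for a in sub_alerts if a.rule_id in p.qualifying_rules]
    if not qualifying:
        return set()
    drugs = frozenset(d for a in qualifying for d in a.triggering_drugs)
    return {(drugs, frozenset())}
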