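"""Recompute the published deployment arithmetic from printed counts.

The real deployment data (Catalan primary care, 2016-2018) were never
deposited, but every printed variation, percentage, prevalence and
indicator sum is an arithmetic function of printed counts.  This module
packages those counts as a fixture and recomputes each derived figure
with the package's own functions (:func:`~selfaudit.tracking.compute_variation`,
:func:`~selfaudit.tracking.mrp_prevalence`,
:func:`~selfaudit.indicator.indicator_aggregate`), reporting per-target
pass/fail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Optional

from .indicator import indicator_aggregate
from .tracking import compute_variation, mrp_prevalence, round_half_away_from_zero


@dataclass(frozen=True)
class TargetResult:
    target_id: str
    expected: object
    computed: object
    passed: bool


def load_reference_counts() -> dict:
    """The packaged printed-count fixture."""
    path = resources.files("selfaudit").joinpath("data/reference_results.json")
    return json.loads(path.read_text())


def verify_reference_arithmetic(counts: Optional[dict] = None) -> list[TargetResult]:
    """Recompute every derived figure in the fixture and compare exactly.

    An empty fixture yields an empty report (all targets skipped); a
    perturbed count makes exactly the affected targets fail.
    """
    if counts is None:
        counts = load_reference_counts()
    results: list[TargetResult] = []

    def check(target_id: str, expected, computed) -> None:
        results.append(TargetResult(target_id, expected, computed, computed == expected))

    # per-category April -> December variations and percentages
    for year, rows in counts.get("table2", {}).items():
        for category, (baseline, final, variation, pct) in rows.items():
            check(f"table2_{year}_{category}", (variation, pct), compute_variation(baseline, final))

    # AEMPS-alert detail rows
    for year, rows in counts.get("table3", {}).items():
        for alert, (baseline, final, variation, pct) in rows.items():
            check(f"table3_{year}_{alert}", (variation, pct), compute_variation(baseline, final))

    # Triple Whammy share of all AEMPS alerts
    for year, row in counts.get("triple_whammy_share", {}).items():
        computed = round_half_away_from_zero(
            Fraction(100 * row["triple_whammy"], row["total_alerts"])
        )
        check(f"triple_whammy_share_{year}", row["share_pct"], computed)

    # MRPs per active prescription
    for year, row in counts.get("prevalence", {}).items():
        check(
            f"prevalence_{year}",
            row["pct"],
            mrp_prevalence(row["mrp_count"], row["active_prescriptions"]),
        )

    # indicator-linked resolutions
    indicator = counts.get("indicator", {})
    year_totals = []
    for year in ("2016", "2017", "2018"):
        row = indicator.get(year)
        if row is None:
            continue
        # the April baseline of linked problems = December count + net resolutions
        baseline_total = None
        if row["december_linked_total"] is not None:
            baseline_total = row["december_linked_total"] + row["total_resolved"]
        total, pct = indicator_aggregate(row["resolved"], baseline_total)
        check(f"indicator_total_{year}", row["total_resolved"], total)
        if row["resolution_pct"] is not None:
            check(f"indicator_pct_{year}", row["resolution_pct"], pct)
        year_totals.append(total)
    if "all_years_total" in indicator:
        check("indicator_all_years_total", indicator["all_years_total"], sum(year_totals))
    if "linked_share_pct" in indicator:
        computed = round_half_away_from_zero(
            Fraction(100 * indicator["all_years_total"], indicator["overall_resolved_all_mrps"])
        )
        check("indicator_linked_share", indicator["linked_share_pct"], computed)

    # December-2018 composition of the detected problems
    comp = counts.get("december_2018_composition")
    if comp:
        total = comp["total"]
        for category in ("geriatric_inadvisable", "duplicate_therapies", "contraindications"):
            row = comp[category]
            check(
                f"dec2018_share_{category}",
                row["share_pct"],
                round_half_away_from_zero(Fraction(100 * row["count"], total)),
            )
        top3 = sum(comp[c]["count"] for c in ("geriatric_inadvisable", "duplicate_therapies", "contraindications"))
        check("dec2018_top3_count", comp["top3_count"], top3)
        check(
            "dec2018_top3_share",
            comp["top3_share_pct"],
            round_half_away_from_zero(Fraction(100 * top3, total), ndigits=1),
        )
    return results


def all_passed(results: list[TargetResult]) -> bool:
    return all(r.passed for r in results)
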