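"""Longitudinal tracking: compare two snapshots of the same audit year.

A baseline problem counts as *resolved* when no alert with the same
identity key (patient, rule, triggering drug set) exists at the final
date.  The resolution reason distinguishes the two administrative
channels: the triggering diagnosis was registered as resolved, or the
causing drug(s) were dropped from the active prescription.  Problems
appearing only at the final date are *new*.

Percentage changes are integers rounded half away from zero, which is
the rounding that reproduces every checkable printed cell of the source
deployment's tables (e.g. −65.64 → −66, 2.59 → 3, −32.5 → −33).
"""

from __future__ import annotations

import datetime as dt
import enum
import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional

import pandas as pd

from .engine import MrpAlert, Snapshot
from .io import Cohort

logger = logging.getLogger(__name__)


class ResolutionReason(str, enum.Enum):
    drug_dropped = "drug_dropped"
    diagnosis_resolved = "diagnosis_resolved"


def round_half_away_from_zero(x: Fraction | float, ndigits: int = 0) -> float | int:
    """Round with ties going away from zero (not banker's rounding)."""
    frac = Fraction(x).limit_denominator(10**12) if not isinstance(x, Fraction) else x
    scaled = frac * 10**ndigits
    sign = -1 if scaled < 0 else 1
    magnitude = abs(scaled)
    rounded = int(magnitude) + (1 if (magnitude - int(magnitude)) >= Fraction(1, 2) else 0)
    value = sign * rounded / 10**ndigits
    return int(value) if ndigits == 0 else float(value)


def compute_variation(baseline_count: int, final_count: int) -> tuple[int, int]:
    """Absolute and percentage change between two counts.

    ``variation = final - baseline``; the percentage is an integer,
    rounded half away from zero.  A zero baseline with no change yields
    0%; a zero baseline with a change has no defined percentage.
    """
    if baseline_count < 0 or final_count < 0:
        raise ValueError("counts must be non-negative")
    variation = final_count - baseline_count
    if baseline_count == 0:
        if variation == 0:
            return 0, 0
        raise ZeroDivisionError("percentage undefined: baseline is 0 but counts changed")
    pct = round_half_away_from_zero(Fraction(100 * variation, baseline_count))
    return variation, pct


def mrp_prevalence(mrp_count: int, active_prescription_count: int) -> float:
    """MRPs as a percentage of active prescriptions, one decimal."""
    if active_prescription_count <= 0:
        raise ZeroDivisionError("active_prescription_count must be positive")
    return round_half_away_from_zero(
        Fraction(100 * mrp_count, active_prescription_count), ndigits=1
    )


@dataclass
class SnapshotComparison:
    baseline_date: dt.date
    final_date: dt.date
    resolved: list[tuple[MrpAlert, ResolutionReason]]
    persisting: list[MrpAlert]
    new: list[MrpAlert]
    per_category_variation: dict[str, tuple[int, int, int, Optional[int]]]
    unattributed_keys: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "baseline_date": self.baseline_date.isoformat(),
            "final_date": self.final_date.isoformat(),
            "n_resolved": len(self.resolved),
            "n_persisting": len(self.persisting),
            "n_new": len(self.new),
            "resolved": [
                {"identity_key": a.identity_key, "reason": r.value} for a, r in self.resolved
            ],
            "new": [a.identity_key for a in self.new],
            "per_category_variation": {
                k: {"baseline": b, "final": f, "variation": v, "pct": p}
                for k, (b, f, v, p) in self.per_category_variation.items()
            },
            "unattributed_keys": list(self.unattributed_keys),
        }


def _classify_reason(
    alert: MrpAlert, cohort_at_final: Cohort, final_date: dt.date
) -> tuple[ResolutionReason, bool]:
    """Returns (reason, attributed).  Diagnosis resolution is checked
    first (the more specific event); otherwise a dropped triggering drug;
    a resolution matching neither channel defaults to drug_dropped and is
    flagged unattributed."""
    if alert.triggering_diagnoses:
        all_resolved = True
        for dx in alert.triggering_diagnoses:
            records = [
                d for d in cohort_at_final.diagnoses_for(alert.patient_id)
                if d.icd10_code == dx
            ]
            if not records or any(d.active_on(final_date) for d in records):
                all_resolved = False
                break
            if not all(d.resolved_date is not None and d.resolved_date <= final_date for d in records):
                all_resolved = False
                break
        if all_resolved:
            return ResolutionReason.diagnosis_resolved, True

    active_codes = {
        rx.drug_code
        for rx in cohort_at_final.prescriptions_for(alert.patient_id)
        if rx.active_on(final_date)
    }
    if any(code not in active_codes for code in alert.triggering_drugs):
        return ResolutionReason.drug_dropped, True
    return ResolutionReason.drug_dropped, False


def compare_snapshots(
    baseline: Snapshot, final: Snapshot, cohort_at_final: Cohort
) -> SnapshotComparison:
    """Partition baseline alerts into resolved/persisting and find new ones.

    Both snapshots must come from the same audit year's catalog: the
    clinical content changes yearly, so cross-year comparison is not
    meaningful.
    """
    if baseline.year_label != final.year_label:
        raise ValueError(
            f"cannot compare snapshots from different catalog years "
            f"({baseline.year_label} vs {final.year_label})"
        )
    if not baseline.snapshot_date < final.snapshot_date:
        raise ValueError("baseline snapshot must precede the final snapshot")

    final_keys = final.identity_keys()
    baseline_keys = baseline.identity_keys()

    resolved: list[tuple[MrpAlert, ResolutionReason]] = []
    persisting: list[MrpAlert] = []
    unattributed: list[str] = []
    for alert in baseline.alerts:
        if alert.identity_key in final_keys:
            persisting.append(alert)
        else:
            reason, attributed = _classify_reason(alert, cohort_at_final, final.snapshot_date)
            if not attributed:
                unattributed.append(alert.identity_key)
                logger.warning("resolution of %s matches neither channel", alert.identity_key)
            resolved.append((alert, reason))
    new = [a for a in final.alerts if a.identity_key not in baseline_keys]

    categories = sorted(set(baseline.per_category_counts) | set(final.per_category_counts))
    per_category: dict[str, tuple[int, int, int, int]] = {}
    for cat in categories:
        b = baseline.per_category_counts.get(cat, 0)
        f = final.per_category_counts.get(cat, 0)
        if b == 0 and f > 0:
            variation, pct = f, None  # percentage undefined on a zero baseline
        else:
            variation, pct = compute_variation(b, f)
        per_category[cat] = (b, f, variation, pct)

    return SnapshotComparison(
        baseline_date=baseline.snapshot_date,
        final_date=final.snapshot_date,
        resolved=resolved,
        persisting=persisting,
        new=new,
        per_category_variation=per_category,
        unattributed_keys=unattributed,
    )


def build_category_report(comparisons: dict[str, SnapshotComparison]) -> pd.DataFrame:
    """One row per (year, category) with baseline/final/variation/pct,
    plus a total row per year whose counts are the column sums."""
    rows = []
    for year in sorted(comparisons):
        comp = comparisons[year]
        total_b = total_f = 0
        for cat, (b, f, v, p) in sorted(comp.per_category_variation.items()):
            rows.append({"year": year, "category": cat, "baseline": b, "final": f,
                         "variation": v, "pct": p})
            total_b += b
            total_f += f
        variation, pct = compute_variation(total_b, total_f) if total_b else (total_f, None)
        rows.append({"year": year, "category": "total", "baseline": total_b,
                     "final": total_f, "variation": variation, "pct": pct})
    return pd.DataFrame(rows, columns=["year", "category", "baseline", "final", "variation", "pct"])


def write_comparison(comparison: SnapshotComparison, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "comparison.json").write_text(json.dumps(comparison.to_json_dict(), indent=2) + "\n")
    pd.DataFrame(
        [
            {"category": cat, "baseline": b, "final": f, "variation": v, "pct": p}
            for cat, (b, f, v, p) in sorted(comparison.per_category_variation.items())
        ],
        columns=["category", "baseline", "final", "variation", "pct"],
    ).to_csv(out / "report.csv", index=False)
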