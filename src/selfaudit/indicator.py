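"""Incentive-based safety indicator.

The indicator tracks, per physician, the three most clinically relevant
MRP categories — relevant therapeutic duplications, regulatory (AEMPS)
safety alerts and polymedication in the elderly.  Each physician starts
the year with an April baseline count of indicator-linked alerts and a
goal: a specific number of problems fewer than that baseline.  Goal
attainment is re-evaluated at checkpoint extractions (September and
December in 2016; June, September and December from 2017).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import pandas as pd

from .engine import Snapshot
from .tracking import compute_variation, round_half_away_from_zero

INDICATOR_CATEGORY_KEYS = frozenset({"duplicate_therapy", "aemps_alert", "polymedication"})


@dataclass(frozen=True)
class IndicatorConfig:
    year_label: str
    checkpoint_dates: tuple[dt.date, ...]
    goal_reduction: float = 1
    goal_form: Literal["absolute", "fraction"] = "absolute"

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.checkpoint_dates[1:], self.checkpoint_dates)):
            raise ValueError("checkpoint_dates must be strictly increasing")
        if self.goal_form == "fraction" and not 0 <= self.goal_reduction <= 1:
            raise ValueError("fractional goal must lie in [0, 1]")
        if self.goal_form == "absolute" and self.goal_reduction < 0:
            raise ValueError("absolute goal must be non-negative")

    def required_reduction(self, baseline_count: int) -> int:
        """The number of problems the physician must shed from baseline."""
        if self.goal_form == "absolute":
            return int(self.goal_reduction)
        return math.ceil(self.goal_reduction * baseline_count)


@dataclass
class IndicatorResult:
    physician_id: str
    baseline_count: int
    per_checkpoint: dict[dt.date, tuple[int, bool]]
    final_variation: int
    final_pct: Optional[int]


def indicator_counts(snapshot: Snapshot) -> dict[str, int]:
    """Indicator-linked alerts per physician in one snapshot."""
    counts: dict[str, int] = {}
    for alert in snapshot.alerts:
        if alert.indicator_linked:
            counts[alert.physician_id] = counts.get(alert.physician_id, 0) + 1
    return counts


def goal_met(baseline_count: int, required_reduction: int, checkpoint_count: int) -> bool:
    """True iff the checkpoint count is at most baseline minus the goal."""
    return checkpoint_count <= baseline_count - required_reduction


def evaluate_indicator(
    baseline: Snapshot,
    checkpoints: Sequence[Snapshot],
    config: IndicatorConfig,
) -> list[IndicatorResult]:
    """Per-physician goal evaluation at every checkpoint.

    Physicians are taken from the baseline snapshot (patients reassigned
    during the year stay attributed to their baseline physician); a
    physician absent from a later snapshot counts zero problems there.
    """
    dates = tuple(s.snapshot_date for s in checkpoints)
    if dates != tuple(config.checkpoint_dates):
        raise ValueError(
            f"checkpoint snapshots {dates} do not match the configured dates "
            f"{tuple(config.checkpoint_dates)}"
        )
    if any(d <= baseline.snapshot_date for d in dates):
        raise ValueError("all checkpoints must fall after the baseline snapshot")

    base_counts = indicator_counts(baseline)
    cp_counts = [indicator_counts(s) for s in checkpoints]
    physicians = sorted(set(base_counts) | {p for c in cp_counts for p in c})

    results: list[IndicatorResult] = []
    for phys in physicians:
        b = base_counts.get(phys, 0)
        need = config.required_reduction(b)
        per_cp: dict[dt.date, tuple[int, bool]] = {}
        for snap, counts in zip(checkpoints, cp_counts):
            c = counts.get(phys, 0)
            per_cp[snap.snapshot_date] = (c, goal_met(b, need, c))
        final_count = cp_counts[-1].get(phys, 0)
        if b == 0:
            variation, pct = final_count, (0 if final_count == 0 else None)
        else:
            variation, pct = compute_variation(b, final_count)
        results.append(
            IndicatorResult(
                physician_id=phys,
                baseline_count=b,
                per_checkpoint=per_cp,
                final_variation=variation,
                final_pct=pct,
            )
        )
    return results


def indicator_aggregate(
    per_category_resolved: dict[str, int],
    baseline_linked_total: Optional[int] = None,
) -> tuple[int, Optional[int]]:
    """Pooled resolution count over the three indicator categories, and —
    when the baseline total of linked problems is known — the pooled
    resolution percentage (integer, rounded half away from zero)."""
    if set(per_category_resolved) != INDICATOR_CATEGORY_KEYS:
        raise ValueError(
            f"expected exactly the categories {sorted(INDICATOR_CATEGORY_KEYS)}, "
            f"got {sorted(per_category_resolved)}"
        )
    total = sum(per_category_resolved.values())
    if baseline_linked_total is None:
        return total, None
    if baseline_linked_total <= 0:
        raise ValueError("baseline_linked_total must be positive")
    from fractions import Fraction

    pct = round_half_away_from_zero(Fraction(100 * total, baseline_linked_total))
    return total, pct


def results_to_frame(results: Sequence[IndicatorResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict = {"physician_id": r.physician_id, "baseline": r.baseline_count}
        for date, (count, met) in sorted(r.per_checkpoint.items()):
            row[f"count_{date.isoformat()}"] = count
            row[f"goal_met_{date.isoformat()}"] = met
        row["final_variation"] = r.final_variation
        row["final_pct"] = r.final_pct
        rows.append(row)
    return pd.DataFrame(rows)
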