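"""Evaluate the incentive-based safety indicator per physician.

Counts indicator-linked problems (relevant duplications, regulatory
alerts, elderly polymedication) per physician at the April baseline, then
checks at the September and December extractions whether each physician
reduced their count by the yearly goal.
"""

import datetime as dt

from selfaudit import (
    GeneratorConfig,
    IndicatorConfig,
    builtin_catalog,
    evaluate_indicator,
    generate_cohort,
    run_snapshot,
)

D = dt.date
catalog = builtin_catalog("2016")
cohort, truth = generate_cohort(GeneratorConfig(n_patients=1500, n_physicians=8, seed=9), catalog)

baseline = run_snapshot(cohort, catalog, D(2016, 4, 1))
checkpoints = [run_snapshot(cohort, catalog, d) for d in (D(2016, 9, 1), D(2016, 12, 1))]
config = IndicatorConfig(
    year_label="2016",
    checkpoint_dates=(D(2016, 9, 1), D(2016, 12, 1)),
    goal_reduction=2,  # each physician must shed two linked problems
)

results = evaluate_indicator(baseline, checkpoints, config)
print("physician  baseline  sept(met)  dec(met)  final pct")
for r in results:
    sept, sept_met = r.per_checkpoint[D(2016, 9, 1)]
    dec, dec_met = r.per_checkpoint[D(2016, 12, 1)]
    pct = f"{r.final_pct:+d}%" if r.final_pct is not None else "n/a"
    print(f"{r.physician_id:>9}  {r.baseline_count:>8}  {sept:>4}({'y' if sept_met else 'n'})"
          f"  {dec:>4}({'y' if dec_met else 'n'})  {pct:>8}")
met = sum(r.per_checkpoint[D(2016, 12, 1)][1] for r in results)
print(f"\n{met}/{len(results)} physicians met the goal at the December evaluation")
# 'met' requires the December count to be at least goal_reduction below April.
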