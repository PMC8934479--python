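# selfaudit

A medication-safety rule engine for active-prescription snapshots,
modelled on the prescription self-audit system used in Catalan primary
care. It is aimed at pharmacoepidemiologists and clinical-decision-support
engineers who need a transparent, testable implementation of
medication-related-problem (MRP) detection, longitudinal resolution
tracking and pay-for-performance indicator computation — exercisable end
to end on synthetic cohorts, since the original clinical data were never
deposited.

## What it computes

**Detection.** Given one extraction date, every patient is reduced to a
*state* (age, active prescriptions under the half-open `[start, end)`
convention, active diagnoses, latest clinical values) and evaluated
against a year-versioned, declarative rule catalog covering:

- **therapeutic duplications** — two or more active drugs sharing an
  active principle (alone or in combination) or a pharmacological-action
  group, with "dose-adjustment" combinations (e.g. insulins)
  distinguished from clinically relevant ones;
- **regulatory (AEMPS) safety alerts** — 13 drug blocks including dose
  ceilings (citalopram > 40 mg/day, > 20 mg/day over age 65 or with liver
  dysfunction), contraindicated comorbidities, risky co-prescriptions
  (ivabradine + verapamil, cilostazol + two antiplatelets) and the *Triple
  Whammy* (NSAID + RAS inhibitor + diuretic at age ≥ 75 or under
  antidiabetic treatment);
- **clinical-variable contraindications** (eGFR < 30 mL/min under an
  NSAID, potassium > 5.5 mmol/L under a RAS inhibitor);
- **treatment duration** (bisphosphonates ≥ 5 years, double antiplatelet
  therapy ≥ 12 months of overlap);
- **drugs inadvisable in geriatrics**, **anticholinergic combinations**,
  **avoidable medication**; and
- **polymedication** — patients over 65 on ≥ 10 drugs (2016–17) or ≥ 8
  (2018) with a qualifying sub-problem.

Each alert carries a stable identity key `patient | rule | sorted
triggering drugs`.

**Tracking.** Comparing two snapshot dates partitions baseline alerts
into *resolved* (the identity key is gone; the reason is classified as
`drug_dropped` or `diagnosis_resolved`), *persisting*, and *new*, and
computes the per-category variation `Δ = final − baseline` with integer
percentages rounded half away from zero.

**Indicator.** The incentive-based safety indicator counts only
indicator-linked alerts (relevant duplications, regulatory alerts,
polymedication) per physician, fixes an April baseline and a goal — a
specific number of problems below baseline — and evaluates goal
attainment at each checkpoint extraction.

**Synthesis.** A seeded generator plants MRPs disjointly (each planted
patient carries only their target rule's triggers plus inert background
drugs), plans resolutions and new problems between the April and December
dates, and records a ground truth against which recall, precision and
longitudinal recovery are exactly measurable.

## Worked example

```python
import datetime as dt
from selfaudit import builtin_catalog, build_patient_state, evaluate_patient
```

Running `python examples/01_detect_problems.py` (an 81-year-old on
ibuprofen + enalapril + furosemide; a 56-year-old on 60 mg/day citalopram
plus two anti-inflammatories) prints:

```
P1 (age 81, 3 active drugs):
  [aemps_alert] triple_whammy: drugs=C03CA01,C09AA02,M01AE01 dx=- (indicator-linked)

P2 (age 56, 3 active drugs):
  [aemps_alert] citalopram_dose: drugs=N06AB04 dx=- (indicator-linked)
  [duplicate_therapy] duplications: drugs=M01AE01,M01AE02 dx=- (indicator-linked)
```

P1 meets the Triple Whammy criterion (all three renal-risk groups, age
≥ 75); P2 exceeds the citalopram dose ceiling and duplicates the
anti-inflammatory group. All three alerts count toward the safety
indicator.

`python examples/05_published_arithmetic.py` recomputes the published
2016–2018 deployment figures from their printed counts:

```
74/74 published figures reproduced exactly

  table2_2016_total              expected (-21547, -9)  computed (-21547, -9)
  indicator_total_2016           expected 17358  computed 17358
  indicator_pct_2016             expected 41  computed 41
```

i.e. of 232,463 problems detected in April 2016, 21,547 (9%) were
resolved by December, and the three indicator-linked categories alone
account for 17,358 resolutions (41% of their April baseline).

The other examples cover simulation + ground-truth audit (`02`),
resolution tracking (`03`) and the per-physician indicator (`04`).
A thin CLI wraps the same functions:

```bash
selfaudit simulate --catalog 2016 --seed 7 --out cohort/
selfaudit snapshot --cohort cohort/ --catalog 2016 --date 2016-04-01 --out snap/
selfaudit compare --cohort cohort/ --catalog 2016 \
    --baseline-date 2016-04-01 --final-date 2016-12-01 --out cmp/
selfaudit verify-reference
```

## Layout

- `src/selfaudit/` — library (`models`, `io`, `catalog`, `engine`,
  `tracking`, `indicator`, `simulate`, `reference`, `cli`);
- `src/selfaudit/data/` — built-in year catalogs
  (`selfaudit-2016/17/18.yaml`), the illustrative drug catalog and the
  printed-count fixture;
- `docs/methods.md` — model, conventions, parameter choices and known
  limitations;
- `examples/`, `tests/`, `scripts/acceptance.py`.
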