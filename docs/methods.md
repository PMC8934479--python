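# Methods

## The problem being modelled

Primary-care prescription audits screen every patient's *active*
medication list on a fixed extraction date for medication-related
problems (MRPs): duplicated therapy, regulator-flagged risk situations,
contraindications, excessive treatment durations, drugs inadvisable in
the elderly, and heavy polymedication. The audit is longitudinal: the
April extraction fixes a baseline (clinical content is revised each
spring), the December extraction closes the year, and the difference
measures net resolution. A pay-for-performance indicator follows the
three most clinically relevant categories per physician. This package
implements that whole pipeline as a library with a versioned, data-driven
rule catalog, so the same engine reproduces any year's content.

## Data model and conventions

- **Activity.** A prescription or diagnosis is active on date *d* under
  the half-open interval `[start, end)`: `start ≤ d` and (no end, or
  `end > d`). An absent end date means ongoing. A record starting on the
  snapshot date is therefore included; one ending on it is not.
- **Age** is completed years at the snapshot date (floor).
- **Drug coding** is ATC level 5; the drug catalog maps each code to its
  active principles (several for combination products) and
  pharmacological group tags. **Diagnoses** are ICD-10 codes matched by
  prefix against named concept sets held in the catalog (e.g. heart
  failure = `I50*`), because the clinical sources name concepts, not code
  lists.
- **Dose** is a single daily amount in mg/day taken from the extract; the
  engine does not parse dosing regimens. A dose-threshold rule never
  fires on a prescription with an unknown dose — it skips it and logs a
  warning, since alerting on an unknown dose would be a fabricated
  finding.
- **Clinical variables** (potassium in mmol/L, eGFR in mL/min/1.73 m²)
  enter rules through the latest measurement on or before the snapshot.
- The extract is assumed pre-filtered to publicly financed prescriptions;
  that filter is upstream of this engine.

## Detection semantics

Rules are data (YAML), validated against per-kind parameter schemas, with
comparators always explicit because the source criteria mix strict and
inclusive bounds (citalopram's elderly dose tier applies *over* 65; the
agomelatine restriction *at or over* 75). Alert counting follows "one
problem, one alert": one alert per distinct triggering drug-set, and for
combination rules (co-prescription, Triple Whammy) the triggering set is
the lexicographically smallest assignment of distinct active drugs that
fills every slot, making output deterministic and at most one alert per
patient per such rule.

Duplication detection has two bases: a shared active principle across ≥ 2
active prescriptions (always clinically relevant), and a shared
duplication-group tag across ≥ 2 distinct principles (relevance taken
from the group; "dose-adjustment" groups such as insulins are detected at
low relevance and never indicator-linked). When both bases produce the
same drug set, the principle basis wins and one alert is emitted. Whether
a production system counts one alert per pair or per basis is not
externally specified; per-basis counting is this package's choice.

Duration thresholds are calendar-safe integers: 5 years = 1826 days,
12 months = 365 days. Double antiplatelet therapy uses the *overlap*
duration — the minimum of the two longest per-drug durations — because
the clinical concept is concurrent therapy length; per-drug duration was
the alternative reading and is documented here as a deliberate choice.

Polymedication fires for patients strictly over 65 whose distinct active
drug count reaches the year's threshold (≥ 10 in 2016–17, ≥ 8 in 2018;
the comparator is a catalog field since the source wording wavers between
"more than 10" and "10 or more") *and* who carry a qualifying
sub-problem: long double antiplatelet therapy, an anticholinergic
combination, or avoidable medication. Its triggering drugs are those of
the qualifying sub-alerts, so its identity tracks the clinical cause, not
the drug count.

Year catalogs differ the way the audit's content evolved: the 2018
catalog drops the citalopram/escitalopram dose rules (QT-co-prescription
only), swaps strontium ranelate for canagliflozin, and lowers the
polymedication threshold; clinical-variable contraindications enter in
2017. The packaged ICD-10 sets and the geriatric-inadvisable/avoidable
drug lists are **illustrative, editable defaults** — plausible
placeholders, not curated clinical authority.

## Longitudinal tracking

Alerts are matched between dates by identity key (patient, rule, sorted
triggering drugs). A baseline alert absent at the final date is resolved;
the reason is `diagnosis_resolved` when every triggering diagnosis is
registered as resolved by the final date (checked first, as the more
specific event), otherwise `drug_dropped` when at least one triggering
drug is no longer active; a resolution matching neither channel defaults
to `drug_dropped` and is flagged unattributed. Comparing snapshots from
different catalog years is an error: content changes make cross-year
counts incommensurable, so multi-year chaining is out of scope.

Percentages are integers rounded **half away from zero**; this is the
rounding that reproduces every reconcilable printed cell of the published
deployment tables (−65.64 → −66, −32.5 → −33, 2.59 → 3). Prevalence (MRPs
per active prescription) is reported to one decimal the same way. A zero
baseline with a non-zero change has no defined percentage: the library
function raises, and the comparison report shows `None`.

## Safety indicator

Per physician, the indicator counts only indicator-linked alerts —
high-relevance duplications, regulatory alerts, polymedication. The goal
is "a specific number of problems below the April baseline"; both an
absolute count (default) and a fraction of baseline are supported, since
the administrative definition is stated only qualitatively. Goal
attainment at a checkpoint is `count ≤ baseline − goal`. Patients
reassigned between physicians during the year stay attributed to their
baseline physician, keeping denominators stable. The aggregate resolution
percentage is the pooled-count form (total resolved over total baseline
of the three categories); an unweighted mean of per-category percentages
is expressible from the same outputs but pooled counting is the default
because it is what the published sums reconcile with.

## Synthetic cohorts

The generator emulates the study conditions: an April baseline and a
December final extraction of one audit year, with problems planted at
configurable per-rule prevalence, resolving with probability
`resolution_probability` (split 80/20 between the drug-withdrawal and
diagnosis-closure channels where a diagnosis channel exists), and new
problems arising among unplanted patients at `new_mrp_rate`. Defaults —
2,000 patients, 20 physicians, 30% elderly, a Poisson(3) inert background
regimen per patient, 0.8% prevalence per plantable rule, 25% resolution,
2% new-problem rate — are fixed choices representing a plausible
primary-care panel (overall MRP prevalence of a few percent of
prescriptions, most problems persisting within a year).

Disjointness is the design invariant: each planted patient receives only
the drugs/diagnoses/values their target rule needs, ages are pinned to
ranges that cannot co-trigger age-gated rules, background drugs are
untagged with unique principles, and the few genuinely coupled plants
(aliskiren + ACE inhibitor is also a RAS duplication; polymedication owns
its qualifying anticholinergic combination) declare *all* their alerts in
the ground truth. `audit_ground_truth` re-runs the engine and reconciles
exactly. Because durations cannot accrue 12+ months between April and
December, duration rules are excluded from *new*-problem planting.

What passing tests on these cohorts show — and do not show: recall = 1.0
and zero false positives demonstrate that the engine implements the
declared criteria exactly, not that the criteria have clinical
sensitivity/specificity on real data, where co-occurring problems,
messy coding, missing doses and demographic structure all differ.
Realistic co-occurrence is deliberately not generated by default.

## Numerical and degenerate-input choices

- Percentage rounding uses exact rational arithmetic (`fractions`), never
  binary floats, so printed-table reproduction is exact.
- Deterministic ordering everywhere: alerts sorted by (rule id, identity
  key); serialized cohorts sorted by natural keys; the generator draws
  from a single seeded NumPy generator and produces byte-identical files
  per seed.
- Empty cohorts, empty snapshots and rules that cannot apply all return
  empty results rather than raising; malformed catalogs and extracts
  raise located errors (rule id/field, file/row).
- Records referencing unknown patients are rejected row-wise and reported
  rather than failing the whole load.

## Known limitations

- Rule content (ICD-10 sets, drug lists, the duplication-group roster and
  which groups are "clinically relevant") is illustrative; real
  deployments curate these continuously.
- No dispensing/claims data, no free-text sig parsing, no prescribing-time
  (online) alerting, and no modelling of post-evaluation rebound
  behaviour.
- Identity-key matching tracks problem *instances* between two dates; it
  does not follow patients across years, by design.
- The aggregate published figure of 41,492 resolved cases across
  2016-2018 is not derivable from the printed per-year tables (their net
  reductions sum to 39,863); only its indicator-linked share (33,148,
  80%) reconciles and only that is recomputed.
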