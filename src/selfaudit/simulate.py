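"""Seeded synthetic primary-care cohorts with known, audited MRP content.

The generator emulates the population structure the audit assumes:
monthly active-prescription extracts in which medication-related problems
arise and resolve between an April baseline and a December final date.
Each planted patient receives *only* the drugs, diagnoses and clinical
values needed to trigger one target rule, plus inert background drugs
carrying no catalog tags (each with a unique active principle), so that
detection recall and precision are exactly measurable: the engine should
find every planted alert and nothing else.  :func:`audit_ground_truth`
verifies that disjointness with the engine itself.

Longitudinal dynamics are planted per alert: with a configurable
probability a baseline problem resolves before the final date, through
either of the two administrative channels (the causing drug is dropped,
or the diagnosis is registered as resolved); unplanted patients may gain
a *new* problem whose records start after the baseline date.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .catalog import RuleCatalog
from .engine import make_identity_key, run_snapshot
from .io import Cohort, write_cohort
from .models import (
    ClinicalVariableRecord,
    DiagnosisRecord,
    PatientRecord,
    PrescriptionRecord,
)

DEFAULT_BASELINE = dt.date(2016, 4, 1)
DEFAULT_FINAL = dt.date(2016, 12, 1)

# untagged catalog drugs usable as inert background prescriptions
INERT_POOL = (
    "H03AA01", "A11CC05", "B03BA01", "B03AA07", "M04AA01", "C10AA05",
    "C10AA01", "J01CA04", "C07AB02", "C08CA01", "N03AX12", "N06AB06",
    "R06AX13", "R03AC02", "N02BB02",
)


class InfeasiblePrevalenceError(ValueError):
    """Requested prevalences cannot be planted disjointly."""


@dataclass(frozen=True)
class Dynamics:
    """Between-snapshot transition rates for planted problems."""

    resolution_probability: float = 0.25
    drug_dropped_fraction: float = 0.8
    diagnosis_resolved_fraction: float = 0.2
    new_mrp_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("resolution_probability", "drug_dropped_fraction",
                     "diagnosis_resolved_fraction", "new_mrp_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(self.drug_dropped_fraction + self.diagnosis_resolved_fraction - 1) > 1e-9:
            raise ValueError("drug_dropped_fraction + diagnosis_resolved_fraction must equal 1")


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 2000
    n_physicians: int = 20
    seed: int = 0
    elderly_fraction: float = 0.3  # share of background patients aged 66-90
    background_rx_rate: float = 3.0  # mean inert prescriptions per patient
    per_rule_prevalence: Optional[dict[str, float]] = None  # None -> defaults
    dynamics: Dynamics = field(default_factory=Dynamics)


@dataclass(frozen=True)
class ExpectedAlert:
    rule_id: str
    triggering_drugs: tuple[str, ...]
    triggering_diagnoses: tuple[str, ...] = ()


@dataclass(frozen=True)
class PlantRecipe:
    """Everything needed to make one patient trigger exactly one target
    rule (possibly via several coupled alerts, e.g. polymedication plus
    its qualifying sub-problem)."""

    recipe_id: str
    rule_id: str
    age_range: tuple[int, int]
    drugs: tuple[tuple[str, Optional[float], int], ...]  # (code, dose mg/day, start offset days)
    diagnoses: tuple[tuple[str, int], ...] = ()  # (icd10, onset offset days)
    clinical: tuple[tuple[str, float, int], ...] = ()  # (variable, value, offset days)
    expected: tuple[ExpectedAlert, ...] = ()
    drop_for_resolution: tuple[str, ...] = ()
    resolve_diagnoses: tuple[str, ...] = ()  # diagnosis-channel alternative, if any
    duration_sensitive: bool = False  # cannot be planted as a *new* problem


def _recipes_for(catalog: RuleCatalog) -> dict[str, PlantRecipe]:
    """Build the recipe registry for one catalog year (content differs
    between years, e.g. the polymedication threshold and which alerts
    exist)."""
    t = catalog.polymedication_threshold
    poly_inert = INERT_POOL[: t - 2]
    r: list[PlantRecipe] = [
        PlantRecipe(
            "citalopram_dose", "citalopram_dose", (40, 60),
            drugs=(("N06AB04", 60.0, -120),),
            expected=(ExpectedAlert("citalopram_dose", ("N06AB04",)),),
            drop_for_resolution=("N06AB04",),
        ),
        PlantRecipe(
            "citalopram_qt", "citalopram_qt", (40, 64),
            drugs=(("N06AB04", 20.0, -120), ("C01BD01", 200.0, -90)),
            expected=(ExpectedAlert("citalopram_qt", ("C01BD01", "N06AB04")),),
            drop_for_resolution=("C01BD01",),
        ),
        PlantRecipe(
            "escitalopram_dose", "escitalopram_dose", (67, 85),
            drugs=(("N06AB10", 20.0, -120),),
            expected=(ExpectedAlert("escitalopram_dose", ("N06AB10",)),),
            drop_for_resolution=("N06AB10",),
        ),
        PlantRecipe(
            "escitalopram_qt", "escitalopram_qt", (40, 64),
            drugs=(("N06AB10", 10.0, -100), ("C07AA07", 160.0, -80)),
            expected=(ExpectedAlert("escitalopram_qt", ("C07AA07", "N06AB10")),),
            drop_for_resolution=("C07AA07",),
        ),
        PlantRecipe(
            "aliskiren_diabetes", "aliskiren_diabetes", (45, 64),
            drugs=(("C09XA02", 150.0, -150),),
            diagnoses=(("E11.9", -400),),
            expected=(ExpectedAlert("aliskiren_diabetes", ("C09XA02",), ("E11.9",)),),
            drop_for_resolution=("C09XA02",),
            resolve_diagnoses=("E11.9",),
        ),
        PlantRecipe(
            # aliskiren + an ACE inhibitor also constitutes a RAS-inhibitor
            # duplication, so this plant legitimately owns two alerts
            "aliskiren_ace", "aliskiren_ace", (45, 64),
            drugs=(("C09XA02", 150.0, -150), ("C09AA02", 20.0, -100)),
            expected=(
                ExpectedAlert("aliskiren_ace", ("C09AA02", "C09XA02")),
                ExpectedAlert("duplications", ("C09AA02", "C09XA02")),
            ),
            drop_for_resolution=("C09XA02",),
        ),
        PlantRecipe(
            "cilostazol_contra", "cilostazol_contra", (50, 64),
            drugs=(("B01AC23", 200.0, -120),),
            diagnoses=(("I50.9", -300),),
            expected=(ExpectedAlert("cilostazol_contra", ("B01AC23",), ("I50.9",)),),
            drop_for_resolution=("B01AC23",),
            resolve_diagnoses=("I50.9",),
        ),
        PlantRecipe(
            "cilostazol_two_antiplatelets", "cilostazol_two_antiplatelets", (50, 64),
            drugs=(("B01AC23", 200.0, -60), ("B01AC06", 100.0, -100), ("B01AC04", 75.0, -90)),
            expected=(
                ExpectedAlert("cilostazol_two_antiplatelets", ("B01AC04", "B01AC06", "B01AC23")),
            ),
            drop_for_resolution=("B01AC23",),
        ),
        PlantRecipe(
            "cilostazol_antiplatelet_anticoagulant", "cilostazol_antiplatelet_anticoagulant",
            (50, 64),
            drugs=(("B01AC23", 200.0, -60), ("B01AC06", 100.0, -80), ("B01AA07", 3.0, -70)),
            expected=(
                ExpectedAlert(
                    "cilostazol_antiplatelet_anticoagulant",
                    ("B01AA07", "B01AC06", "B01AC23"),
                ),
            ),
            drop_for_resolution=("B01AC23",),
        ),
        PlantRecipe(
            "trimetazidine_movement", "trimetazidine_movement", (45, 64),
            drugs=(("C01EB15", 60.0, -150),),
            diagnoses=(("G20", -500),),
            expected=(ExpectedAlert("trimetazidine_movement", ("C01EB15",), ("G20",)),),
            drop_for_resolution=("C01EB15",),
            resolve_diagnoses=("G20",),
        ),
        PlantRecipe(
            "raloxifene_contra", "raloxifene_contra", (55, 64),
            drugs=(("G03XC01", 60.0, -200),),
            diagnoses=(("I80.2", -250),),
            expected=(ExpectedAlert("raloxifene_contra", ("G03XC01",), ("I80.2",)),),
            drop_for_resolution=("G03XC01",),
            resolve_diagnoses=("I80.2",),
        ),
        PlantRecipe(
            "coxib_contra", "coxib_contra", (45, 64),
            drugs=(("M01AH01", 200.0, -100),),
            diagnoses=(("I25.1", -600),),
            expected=(ExpectedAlert("coxib_contra", ("M01AH01",), ("I25.1",)),),
            drop_for_resolution=("M01AH01",),
            resolve_diagnoses=("I25.1",),
        ),
        PlantRecipe(
            "diclofenac_contra", "diclofenac_contra", (45, 64),
            drugs=(("M01AB05", 100.0, -100),),
            diagnoses=(("I63.9", -600),),
            expected=(ExpectedAlert("diclofenac_contra", ("M01AB05",), ("I63.9",)),),
            drop_for_resolution=("M01AB05",),
            resolve_diagnoses=("I63.9",),
        ),
        PlantRecipe(
            "aceclofenac_contra", "aceclofenac_contra", (45, 64),
            drugs=(("M01AB16", 200.0, -100),),
            diagnoses=(("I20.0", -600),),
            expected=(ExpectedAlert("aceclofenac_contra", ("M01AB16",), ("I20.0",)),),
            drop_for_resolution=("M01AB16",),
            resolve_diagnoses=("I20.0",),
        ),
        PlantRecipe(
            "agomelatine_age", "agomelatine_age", (75, 88),
            drugs=(("N06AX22", 25.0, -150),),
            expected=(ExpectedAlert("agomelatine_age", ("N06AX22",)),),
            drop_for_resolution=("N06AX22",),
        ),
        PlantRecipe(
            "ivabradine_verapamil", "ivabradine_verapamil", (50, 64),
            drugs=(("C01EB17", 10.0, -120), ("C08DA01", 240.0, -100)),
            expected=(ExpectedAlert("ivabradine_verapamil", ("C01EB17", "C08DA01")),),
            drop_for_resolution=("C08DA01",),
        ),
        PlantRecipe(
            "triple_whammy", "triple_whammy", (75, 88),
            drugs=(("M01AE01", 1200.0, -60), ("C09AA02", 20.0, -400), ("C03CA01", 40.0, -300)),
            expected=(ExpectedAlert("triple_whammy", ("C03CA01", "C09AA02", "M01AE01")),),
            drop_for_resolution=("M01AE01",),
        ),
        PlantRecipe(
            "verapamil_heart_failure", "verapamil_heart_failure", (55, 64),
            drugs=(("C08DA01", 240.0, -200),),
            diagnoses=(("I50.1", -350),),
            expected=(ExpectedAlert("verapamil_heart_failure", ("C08DA01",), ("I50.1",)),),
            drop_for_resolution=("C08DA01",),
            resolve_diagnoses=("I50.1",),
        ),
        PlantRecipe(
            "nsaid_low_egfr", "nsaid_low_egfr", (55, 64),
            drugs=(("M01AE02", 1000.0, -90),),
            clinical=(("egfr", 24.0, -15),),
            expected=(ExpectedAlert("nsaid_low_egfr", ("M01AE02",)),),
            drop_for_resolution=("M01AE02",),
        ),
        PlantRecipe(
            "bisphosphonate_5y", "bisphosphonate_5y", (58, 64),
            drugs=(("M05BA04", 70.0, -2000),),
            expected=(ExpectedAlert("bisphosphonate_5y", ("M05BA04",)),),
            drop_for_resolution=("M05BA04",),
            duration_sensitive=True,
        ),
        PlantRecipe(
            "dapt_12m", "dapt_12m", (50, 64),
            drugs=(("B01AC06", 100.0, -400), ("B01AC04", 75.0, -380)),
            expected=(ExpectedAlert("dapt_12m", ("B01AC04", "B01AC06")),),
            drop_for_resolution=("B01AC04",),
            duration_sensitive=True,
        ),
        PlantRecipe(
            "geriatric_list", "geriatric_list", (67, 85),
            drugs=(("N05BA01", 10.0, -150),),
            expected=(ExpectedAlert("geriatric_list", ("N05BA01",)),),
            drop_for_resolution=("N05BA01",),
        ),
        PlantRecipe(
            "anticholinergic_combo", "anticholinergic_combo", (40, 64),
            drugs=(("N05BB01", 50.0, -120), ("N04AA01", 6.0, -100)),
            expected=(ExpectedAlert("anticholinergic_combo", ("N04AA01", "N05BB01")),),
            drop_for_resolution=("N04AA01",),
        ),
        PlantRecipe(
            "avoidable_meds", "avoidable_meds", (40, 64),
            drugs=(("N06BX06", 1000.0, -150),),
            expected=(ExpectedAlert("avoidable_meds", ("N06BX06",)),),
            drop_for_resolution=("N06BX06",),
        ),
        PlantRecipe(
            # group-action basis: two distinct anti-inflammatory principles
            "duplications", "duplications", (35, 64),
            drugs=(("M01AE01", 1200.0, -150), ("M01AE02", 1000.0, -100)),
            expected=(ExpectedAlert("duplications", ("M01AE01", "M01AE02")),),
            drop_for_resolution=("M01AE02",),
        ),
        PlantRecipe(
            # active-principle basis: plain paracetamol + a combination
            # product containing it
            "duplications_principle", "duplications", (35, 64),
            drugs=(("N02BE01", 2000.0, -150), ("N02BE51", 2000.0, -100)),
            expected=(ExpectedAlert("duplications", ("N02BE01", "N02BE51")),),
            drop_for_resolution=("N02BE51",),
        ),
        PlantRecipe(
            "polymedication", "polymedication", (67, 85),
            drugs=(
                ("N05BB01", 50.0, -200),
                ("N04AA01", 6.0, -180),
                *((code, 1.0, -250) for code in poly_inert),
            ),
            expected=(
                ExpectedAlert("anticholinergic_combo", ("N04AA01", "N05BB01")),
                ExpectedAlert("polymedication", ("N04AA01", "N05BB01")),
            ),
            drop_for_resolution=("N04AA01",),
        ),
    ]
    available = {rule.rule_id for rule in catalog.rules}
    return {rec.recipe_id: rec for rec in r if rec.rule_id in available}


def default_prevalence(catalog: RuleCatalog, per_rule: float = 0.008) -> dict[str, float]:
    """Uniform plantable prevalences over every recipe the year's catalog
    supports."""
    return {rid: per_rule for rid in sorted(_recipes_for(catalog))}


@dataclass(frozen=True)
class PlannedAlert:
    patient_id: str
    rule_id: str
    triggering_drugs: tuple[str, ...]
    triggering_diagnoses: tuple[str, ...]
    phase: str  # "baseline" | "new"
    transition: Optional[str] = None  # "resolved" | "persisting" (baseline only)
    reason: Optional[str] = None  # "drug_dropped" | "diagnosis_resolved"

    @property
    def identity_key(self) -> str:
        return make_identity_key(self.patient_id, self.rule_id, self.triggering_drugs)


@dataclass
class GroundTruth:
    baseline_date: dt.date
    final_date: dt.date
    planted: list[PlannedAlert]

    def baseline_keys(self) -> set[str]:
        return {p.identity_key for p in self.planted if p.phase == "baseline"}

    def final_keys(self) -> set[str]:
        return {
            p.identity_key
            for p in self.planted
            if (p.phase == "baseline" and p.transition == "persisting") or p.phase == "new"
        }

    def resolved(self) -> dict[str, str]:
        """identity_key -> planted resolution reason."""
        return {
            p.identity_key: p.reason
            for p in self.planted
            if p.phase == "baseline" and p.transition == "resolved"
        }

    def new_keys(self) -> set[str]:
        return {p.identity_key for p in self.planted if p.phase == "new"}

    def to_json_dict(self) -> dict:
        return {
            "baseline_date": self.baseline_date.isoformat(),
            "final_date": self.final_date.isoformat(),
            "planted": [
                {
                    "patient_id": p.patient_id,
                    "rule_id": p.rule_id,
                    "triggering_drugs": list(p.triggering_drugs),
                    "triggering_diagnoses": list(p.triggering_diagnoses),
                    "identity_key": p.identity_key,
                    "phase": p.phase,
                    "transition": p.transition,
                    "reason": p.reason,
                }
                for p in self.planted
            ],
        }


def _birth_date_for_age(age: int, baseline: dt.date) -> dt.date:
    # January-1 birthday: age is constant from the April baseline through
    # the December final snapshot
    return dt.date(baseline.year - age, 1, 1)


def generate_cohort(
    config: GeneratorConfig,
    catalog: RuleCatalog,
    baseline_date: dt.date = DEFAULT_BASELINE,
    final_date: dt.date = DEFAULT_FINAL,
) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort with planted MRPs and planned dynamics.

    Fully reproducible from ``config.seed``.  Raises
    :class:`InfeasiblePrevalenceError` when the requested prevalences sum
    above 1 (each patient can host at most one disjoint plant).
    """
    if final_date <= baseline_date:
        raise ValueError("final_date must follow baseline_date")
    recipes = _recipes_for(catalog)
    prevalence = (
        dict(config.per_rule_prevalence)
        if config.per_rule_prevalence is not None
        else default_prevalence(catalog)
    )
    unknown = sorted(set(prevalence) - set(recipes))
    if unknown:
        raise ValueError(f"no plant recipe for: {unknown} (year {catalog.year_label})")
    total_p = sum(prevalence.values())
    if total_p > 1:
        raise InfeasiblePrevalenceError(
            f"requested prevalences sum to {total_p:.3f} > 1; disjoint planting "
            f"assigns at most one problem per patient — lower the prevalences"
        )
    dyn = config.dynamics
    new_eligible = [
        rid for rid in sorted(prevalence) if not recipes[rid].duration_sensitive
    ]

    rng = np.random.default_rng(config.seed)
    recipe_ids = sorted(prevalence)
    cum = np.cumsum([prevalence[rid] for rid in recipe_ids])

    patients: dict[str, PatientRecord] = {}
    prescriptions: list[PrescriptionRecord] = []
    diagnoses: list[DiagnosisRecord] = []
    clinical: list[ClinicalVariableRecord] = []
    planted: list[PlannedAlert] = []

    width = max(5, len(str(config.n_patients)))
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        physician = f"D{int(rng.integers(config.n_physicians)):04d}"

        u = rng.random()
        idx = int(np.searchsorted(cum, u, side="right"))
        recipe: Optional[PlantRecipe] = None
        phase = "baseline"
        if idx < len(recipe_ids):
            recipe = recipes[recipe_ids[idx]]
        elif new_eligible and rng.random() < dyn.new_mrp_rate:
            recipe = recipes[new_eligible[int(rng.integers(len(new_eligible)))]]
            phase = "new"

        if recipe is not None:
            age = int(rng.integers(recipe.age_range[0], recipe.age_range[1] + 1))
        elif rng.random() < config.elderly_fraction:
            age = int(rng.integers(66, 91))
        else:
            age = int(rng.integers(18, 66))
        patients[pid] = PatientRecord(
            patient_id=pid, physician_id=physician,
            birth_date=_birth_date_for_age(age, baseline_date),
            sex="female" if rng.random() < 0.5 else "male",
        )

        used_codes: set[str] = set()
        transition = reason = None
        drop_codes: set[str] = set()
        resolve_dx: set[str] = set()
        if recipe is not None:
            if phase == "baseline":
                anchor = baseline_date
                if rng.random() < dyn.resolution_probability:
                    transition = "resolved"
                    if recipe.resolve_diagnoses and rng.random() < dyn.diagnosis_resolved_fraction:
                        reason = "diagnosis_resolved"
                        resolve_dx = set(recipe.resolve_diagnoses)
                    else:
                        reason = "drug_dropped"
                        drop_codes = set(recipe.drop_for_resolution)
                else:
                    transition = "persisting"
            else:
                # new problem: every planted record starts after baseline
                span = (final_date - baseline_date).days
                anchor = baseline_date + dt.timedelta(days=int(rng.integers(30, max(31, span - 30))))

            event_day = anchor + dt.timedelta(days=int(rng.integers(30, 121)))
            for code, dose, offset in recipe.drugs:
                start = anchor + dt.timedelta(days=offset if phase == "baseline" else int(rng.integers(0, 5)))
                end = event_day if code in drop_codes else None
                prescriptions.append(
                    PrescriptionRecord(
                        patient_id=pid, drug_code=code, daily_dose_mg=dose,
                        start_date=start, end_date=end,
                    )
                )
                used_codes.add(code)
            for icd, offset in recipe.diagnoses:
                onset = anchor + dt.timedelta(days=offset if phase == "baseline" else 0)
                resolved = event_day if icd in resolve_dx else None
                diagnoses.append(
                    DiagnosisRecord(
                        patient_id=pid, icd10_code=icd,
                        onset_date=onset, resolved_date=resolved,
                    )
                )
            for var, value, offset in recipe.clinical:
                clinical.append(
                    ClinicalVariableRecord(
                        patient_id=pid, variable_code=var, value=value,
                        measured_date=anchor + dt.timedelta(days=offset if phase == "baseline" else 0),
                    )
                )
            for exp in recipe.expected:
                planted.append(
                    PlannedAlert(
                        patient_id=pid, rule_id=exp.rule_id,
                        triggering_drugs=exp.triggering_drugs,
                        triggering_diagnoses=exp.triggering_diagnoses,
                        phase=phase, transition=transition, reason=reason,
                    )
                )

        # inert background prescriptions (no tags, unique principles)
        n_bg = min(int(rng.poisson(config.background_rx_rate)), 7)
        pool = [c for c in INERT_POOL if c not in used_codes]
        if n_bg > 0 and pool:
            picks = rng.choice(len(pool), size=min(n_bg, len(pool)), replace=False)
            for k in sorted(int(x) for x in picks):
                start = baseline_date - dt.timedelta(days=int(rng.integers(30, 721)))
                prescriptions.append(
                    PrescriptionRecord(
                        patient_id=pid, drug_code=pool[k], daily_dose_mg=1.0,
                        start_date=start, end_date=None,
                    )
                )

    cohort = Cohort(patients=patients, prescriptions=prescriptions,
                    diagnoses=diagnoses, clinical=clinical)
    truth = GroundTruth(baseline_date=baseline_date, final_date=final_date, planted=planted)
    return cohort, truth


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "ground_truth.json"
    path.write_text(json.dumps(truth.to_json_dict(), indent=2, sort_keys=True) + "\n")
    return path


@dataclass
class AuditReport:
    """Engine-versus-ground-truth reconciliation at both snapshot dates."""

    missing_at_baseline: list[str]
    unplanned_at_baseline: list[str]
    missing_at_final: list[str]
    unplanned_at_final: list[str]

    @property
    def n_discrepancies(self) -> int:
        return (
            len(self.missing_at_baseline) + len(self.unplanned_at_baseline)
            + len(self.missing_at_final) + len(self.unplanned_at_final)
        )

    @property
    def ok(self) -> bool:
        return self.n_discrepancies == 0


def audit_ground_truth(cohort: Cohort, catalog: RuleCatalog, truth: GroundTruth) -> AuditReport:
    """Run the detection engine on a generated cohort and reconcile the
    alerts it finds with the planted ground truth at both dates.
    Discrepancies (leakage) are report content, never exceptions."""
    base_snap = run_snapshot(cohort, catalog, truth.baseline_date)
    final_snap = run_snapshot(cohort, catalog, truth.final_date)
    found_base = base_snap.identity_keys()
    found_final = final_snap.identity_keys()
    want_base = truth.baseline_keys()
    want_final = truth.final_keys()
    return AuditReport(
        missing_at_baseline=sorted(want_base - found_base),
        unplanned_at_baseline=sorted(found_base - want_base),
        missing_at_final=sorted(want_final - found_final),
        unplanned_at_final=sorted(found_final - want_final),
    )
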