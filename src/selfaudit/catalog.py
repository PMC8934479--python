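"""Declarative catalog of medication-related-problem (MRP) rules.

The clinical content of the audit — which drug/dose/diagnosis situations
count as an MRP — is reviewed yearly and therefore lives in data (YAML),
not code.  A :class:`RuleCatalog` bundles one year's rules, duplication
groups, named ICD-10 concept sets and the year's polymedication
threshold, together with the drug catalog that resolves ATC codes to
active principles and pharmacological group tags.

Comparators are explicit everywhere because the source criteria mix
strict and inclusive bounds (``> 65`` years for the citalopram dose tier
versus ``>= 75`` years for agomelatine).
"""

from __future__ import annotations

import enum
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .io import load_drug_catalog
from .models import DrugCatalogEntry

BUILTIN_YEARS = ("2016", "2017", "2018")


class CatalogError(ValueError):
    """Catalog file fails schema or cross-reference validation."""


class Category(str, enum.Enum):
    duplicate_therapy = "duplicate_therapy"
    aemps_alert = "aemps_alert"
    contraindication_clinical = "contraindication_clinical"
    treatment_duration = "treatment_duration"
    geriatric_inadvisable = "geriatric_inadvisable"
    anticholinergic_combination = "anticholinergic_combination"
    avoidable_medication = "avoidable_medication"
    polymedication = "polymedication"


class Relevance(str, enum.Enum):
    high = "high"
    low = "low"


class RuleKind(str, enum.Enum):
    dose_threshold = "dose_threshold"
    age_restriction = "age_restriction"
    comorbidity_contraindication = "comorbidity_contraindication"
    co_prescription = "co_prescription"
    clinical_variable = "clinical_variable"
    list_membership = "list_membership"
    composite_triple_whammy = "composite_triple_whammy"
    duration = "duration"
    duplication_group = "duplication_group"
    polymedication = "polymedication"


INDICATOR_CATEGORIES = {
    Category.duplicate_therapy,
    Category.aemps_alert,
    Category.polymedication,
}


class DrugSelector(BaseModel):
    """Selects drugs either by pharmacological group tag or explicit codes."""

    model_config = {"frozen": True, "extra": "forbid"}

    tag: Optional[str] = None
    codes: Optional[tuple[str, ...]] = None

    @model_validator(mode="after")
    def _one_of(self) -> "DrugSelector":
        if (self.tag is None) == (self.codes is None):
            raise ValueError("selector needs exactly one of 'tag' or 'codes'")
        return self

    def matches(self, entry: DrugCatalogEntry) -> bool:
        if self.tag is not None:
            return self.tag in entry.group_tags
        return entry.drug_code in self.codes


class DoseTier(BaseModel):
    """One dose limit, optionally qualified by age or a comorbidity set.

    The limit fires on doses *strictly above* ``threshold_mg_per_day``.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    threshold_mg_per_day: float = Field(gt=0)
    age_gt: Optional[int] = None
    comorbidity_set: Optional[str] = None


class DoseThresholdParams(BaseModel):
    model_config = {"frozen": True, "extra": "forbid"}

    drug: DrugSelector
    tiers: tuple[DoseTier, ...] = Field(min_length=1)


class AgeRestrictionParams(BaseModel):
    model_config = {"frozen": True, "extra": "forbid"}

    drug: DrugSelector
    age_threshold: int
    comparator: Literal["gte", "gt"] = "gte"


class ComorbidityParams(BaseModel):
    """Drug contraindicated by an active diagnosis (ICD-10 prefix match).

    ``or_drug_group`` admits an alternative drug-treatment qualifier
    (e.g. aliskiren is flagged for a type-2-diabetes diagnosis *or* for
    ongoing antidiabetic treatment).
    """

    model_config = {"frozen": True, "extra": "forbid"}

    drug: DrugSelector
    concept_sets: tuple[str, ...] = Field(min_length=1)
    or_drug_group: Optional[DrugSelector] = None


class CoPrescriptionSlot(BaseModel):
    model_config = {"frozen": True, "extra": "forbid"}

    drug: DrugSelector
    min_count: int = Field(default=1, ge=1)


class CoPrescriptionParams(BaseModel):
    """Fires when every slot can be filled with distinct active drugs."""

    model_config = {"frozen": True, "extra": "forbid"}

    groups: tuple[CoPrescriptionSlot, ...] = Field(min_length=1)


class ClinicalVariableParams(BaseModel):
    model_config = {"frozen": True, "extra": "forbid"}

    drug: DrugSelector
    variable: str
    comparator: Literal["lt", "lte", "gt", "gte"]
    threshold: float


class ListMembershipParams(BaseModel):
    model_config = {"frozen": True, "extra": "forbid"}

    drug: DrugSelector
    age_gt: Optional[int] = None


class TripleWhammyParams(BaseModel):
    """NSAID + RAS inhibitor + diuretic, in patients aged >= ``age_gte``
    or under antidiabetic treatment (acute-kidney-injury risk triple)."""

    model_config = {"frozen": True, "extra": "forbid"}

    nsaid: DrugSelector = DrugSelector(tag="nsaid")
    ras_inhibitor: DrugSelector = DrugSelector(tag="ras_inhibitor")
    diuretic: DrugSelector = DrugSelector(tag="diuretic")
    antidiabetic: DrugSelector = DrugSelector(tag="antidiabetic")
    age_gte: int = 75


class DurationParams(BaseModel):
    """Treatment-length rule.

    ``per_drug``: each matching drug active for at least ``min_days``.
    ``overlap``: at least ``min_count`` matching drugs whose concurrent
    duration (minimum of the individual durations) is >= ``min_days``.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    mode: Literal["per_drug", "overlap"]
    drug: DrugSelector
    min_days: int = Field(ge=1)
    min_count: int = Field(default=2, ge=2)


class DuplicationParams(BaseModel):
    model_config = {"frozen": True, "extra": "forbid"}


class PolymedicationParams(BaseModel):
    """Age-gated medication-count rule requiring a qualifying sub-MRP."""

    model_config = {"frozen": True, "extra": "forbid"}

    age_gt: int = 65
    qualifying_rules: tuple[str, ...] = Field(min_length=1)


_PARAM_MODELS: dict[RuleKind, type[BaseModel]] = {
    RuleKind.dose_threshold: DoseThresholdParams,
    RuleKind.age_restriction: AgeRestrictionParams,
    RuleKind.comorbidity_contraindication: ComorbidityParams,
    RuleKind.co_prescription: CoPrescriptionParams,
    RuleKind.clinical_variable: ClinicalVariableParams,
    RuleKind.list_membership: ListMembershipParams,
    RuleKind.composite_triple_whammy: TripleWhammyParams,
    RuleKind.duration: DurationParams,
    RuleKind.duplication_group: DuplicationParams,
    RuleKind.polymedication: PolymedicationParams,
}

AnyParams = Union[
    DoseThresholdParams,
    AgeRestrictionParams,
    ComorbidityParams,
    CoPrescriptionParams,
    ClinicalVariableParams,
    ListMembershipParams,
    TripleWhammyParams,
    DurationParams,
    DuplicationParams,
    PolymedicationParams,
]


class MrpRule(BaseModel):
    model_config = {"frozen": True}

    rule_id: str
    category: Category
    relevance: Relevance
    indicator_linked: bool
    kind: RuleKind
    parameters: AnyParams
    drug_block: Optional[str] = None
    recommendation_text: str = ""

    @model_validator(mode="before")
    @classmethod
    def _coerce_params(cls, data):
        # the right parameter schema is dictated by `kind`, not guessed
        # from the union
        if isinstance(data, dict) and isinstance(data.get("parameters"), dict):
            try:
                kind = RuleKind(data.get("kind"))
            except ValueError:
                return data  # let the field validator report the bad kind
            model = _PARAM_MODELS[kind]
            try:
                data = {**data, "parameters": model(**data["parameters"])}
            except ValidationError as exc:
                raise ValueError(
                    f"rule {data.get('rule_id')!r}: invalid parameters for kind "
                    f"{kind.value}: {exc}"
                ) from exc
        return data

    @model_validator(mode="after")
    def _checks(self) -> "MrpRule":
        expected = _PARAM_MODELS[self.kind]
        if type(self.parameters) is not expected:
            raise ValueError(
                f"rule {self.rule_id!r}: parameters for kind {self.kind.value} "
                f"must be {expected.__name__}, got {type(self.parameters).__name__}"
            )
        if self.indicator_linked and self.category not in INDICATOR_CATEGORIES:
            raise ValueError(
                f"rule {self.rule_id!r}: indicator_linked is only allowed for "
                f"duplicate therapy, AEMPS alerts and polymedication"
            )
        if self.indicator_linked and self.category is Category.duplicate_therapy and self.relevance is not Relevance.high:
            raise ValueError(
                f"rule {self.rule_id!r}: indicator-linked duplications must be high relevance"
            )
        return self


class DuplicationGroup(BaseModel):
    """A pharmacological-action duplication group.

    ``clinically_relevant = False`` marks a "duplication of dose
    adjustment" (a combination sought deliberately, e.g. insulins): it is
    still detected, but at low relevance and never indicator-linked.
    """

    model_config = {"frozen": True}

    group_id: str
    member_tag: str
    clinically_relevant: bool = True


class RuleCatalog(BaseModel):
    year_label: str
    rules: tuple[MrpRule, ...]
    duplication_groups: tuple[DuplicationGroup, ...] = ()
    icd10_concept_sets: dict[str, tuple[str, ...]] = {}
    polymedication_threshold: int = Field(ge=1)
    polymedication_comparator: Literal["gte", "gt"] = "gte"
    drug_catalog: dict[str, DrugCatalogEntry] = {}

    # -- lookup helpers ------------------------------------------------
    def rule(self, rule_id: str) -> MrpRule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)

    def tag_vocabulary(self) -> set[str]:
        vocab: set[str] = set()
        for entry in self.drug_catalog.values():
            vocab |= entry.group_tags
        return vocab

    def drugs_with_tag(self, tag: str) -> set[str]:
        return {c for c, e in self.drug_catalog.items() if tag in e.group_tags}

    def entry(self, drug_code: str) -> Optional[DrugCatalogEntry]:
        return self.drug_catalog.get(drug_code)

    def concept_prefixes(self, concept: str) -> tuple[str, ...]:
        return self.icd10_concept_sets[concept]

    def icd10_in_concept(self, icd10_code: str, concept: str) -> bool:
        return any(icd10_code.startswith(p) for p in self.icd10_concept_sets[concept])


def _iter_selectors(rule: MrpRule):
    p = rule.parameters
    if isinstance(p, (DoseThresholdParams, AgeRestrictionParams, ClinicalVariableParams, ListMembershipParams, DurationParams)):
        yield p.drug
    elif isinstance(p, ComorbidityParams):
        yield p.drug
        if p.or_drug_group is not None:
            yield p.or_drug_group
    elif isinstance(p, CoPrescriptionParams):
        for slot in p.groups:
            yield slot.drug
    elif isinstance(p, TripleWhammyParams):
        yield p.nsaid
        yield p.ras_inhibitor
        yield p.diuretic
        yield p.antidiabetic


def validate_catalog(catalog: RuleCatalog) -> None:
    """Cross-reference validation: every tag, code, concept set and
    sub-rule a rule mentions must exist.  Raises :class:`CatalogError`
    naming the offending rule and field."""
    vocab = catalog.tag_vocabulary()

    seen: set[str] = set()
    for rule in catalog.rules:
        if rule.rule_id in seen:
            raise CatalogError(f"duplicate rule_id {rule.rule_id!r}")
        seen.add(rule.rule_id)

        for sel in _iter_selectors(rule):
            if sel.tag is not None and sel.tag not in vocab:
                raise CatalogError(
                    f"rule {rule.rule_id!r}: unknown group tag {sel.tag!r}"
                )
            if sel.codes is not None:
                for code in sel.codes:
                    if code not in catalog.drug_catalog:
                        raise CatalogError(
                            f"rule {rule.rule_id!r}: drug code {code!r} not in drug catalog"
                        )
        p = rule.parameters
        concepts: list[str] = []
        if isinstance(p, ComorbidityParams):
            concepts.extend(p.concept_sets)
        if isinstance(p, DoseThresholdParams):
            concepts.extend(t.comorbidity_set for t in p.tiers if t.comorbidity_set)
        for c in concepts:
            if c not in catalog.icd10_concept_sets:
                raise CatalogError(
                    f"rule {rule.rule_id!r}: unknown ICD-10 concept set {c!r}"
                )
        if isinstance(p, PolymedicationParams):
            for sub in p.qualifying_rules:
                if sub not in seen and sub not in {r.rule_id for r in catalog.rules}:
                    raise CatalogError(
                        f"rule {rule.rule_id!r}: qualifying rule {sub!r} not in catalog"
                    )

    group_ids: set[str] = set()
    for g in catalog.duplication_groups:
        if g.group_id in group_ids:
            raise CatalogError(f"duplicate duplication group {g.group_id!r}")
        group_ids.add(g.group_id)
        if g.member_tag not in vocab:
            raise CatalogError(
                f"duplication group {g.group_id!r}: member tag {g.member_tag!r} "
                f"carried by no drug in the catalog"
            )


def _builtin_drug_catalog_path() -> Path:
    return Path(resources.files("selfaudit").joinpath("data/drug_catalog.csv"))


def builtin_drug_catalog() -> dict[str, DrugCatalogEntry]:
    """The packaged illustrative drug catalog (ATC codes, tags)."""
    return load_drug_catalog(_builtin_drug_catalog_path())


def catalog_from_dict(
    raw: dict,
    drug_catalog: Optional[dict[str, DrugCatalogEntry]] = None,
) -> RuleCatalog:
    if drug_catalog is None:
        drug_catalog = builtin_drug_catalog()
    try:
        catalog = RuleCatalog(drug_catalog=drug_catalog, **raw)
    except ValidationError as exc:
        raise CatalogError(str(exc)) from exc
    validate_catalog(catalog)
    return catalog


def load_rule_catalog(
    path: str | Path,
    drug_catalog: Optional[dict[str, DrugCatalogEntry]] = None,
) -> RuleCatalog:
    """Load and validate a YAML rule-catalog file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CatalogError(f"{path}: catalog file must contain a mapping")
    return catalog_from_dict(raw, drug_catalog)


def builtin_catalog(year_label: str | int) -> RuleCatalog:
    """The packaged rule catalog for one audit year (2016, 2017 or 2018).

    Yearly differences mirror how the audit's clinical content evolved:
    the polymedication threshold drops from 10 to 8 drugs in 2018, the
    citalopram/escitalopram alerts become QT-co-prescription-only in
    2018, strontium ranelate leaves after 2017 and canagliflozin enters
    in 2018, and clinical-variable contraindications (potassium, eGFR)
    appear from 2017.
    """
    year = str(year_label)
    if year not in BUILTIN_YEARS:
        raise CatalogError(f"no built-in catalog for year {year!r}; choose one of {BUILTIN_YEARS}")
    path = resources.files("selfaudit").joinpath(f"data/selfaudit-{year}.yaml")
    return load_rule_catalog(Path(path))
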