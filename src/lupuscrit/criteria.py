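"""Declarative rule-based classification criteria and their scoring engines.

Three rule kinds cover the four SLE criteria sets:

``weighted_sum_threshold``
    SLERPI: score = sum of item weights for satisfied items; classify when
    the score exceeds (strictly, for SLERPI) a threshold.  An optional
    logistic transform maps the score to a lupus probability percentage,
    binned into the ordinal categories definite / likely / possible /
    unlikely.
``count_threshold``
    ACR-1997 and SLICC-2012: score = number of satisfied items; SLICC
    additionally requires at least one clinical and one immunologic item
    and grants classification outright through a standalone
    biopsy-proven-nephritis rule.
``domain_weighted_threshold``
    EULAR/ACR-2019: ANA entry criterion, then within each domain only the
    highest-weighted satisfied item contributes; classify at >= 10 points.

Item predicates are boolean expressions (``and`` / ``or`` / ``not`` /
parentheses) over vocabulary feature names, parsed with Python's ``ast``
restricted to those node types.
"""

from __future__ import annotations

import ast
import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from .records import VOCABULARY, PatientRecord

DATA_DIR = Path(__file__).parent / "data"

#: Ordinal probability categories and their lower bounds (percent).  The
#: published ranges (0-14, 15-43, 44-86, 87-100) are implemented half-open
#: so that every percentage maps to exactly one category.
CATEGORY_CUTPOINTS: tuple[float, float, float] = (15.0, 44.0, 87.0)


class Category(str, enum.Enum):
    definite = "definite"
    likely = "likely"
    possible = "possible"
    unlikely = "unlikely"


class RuleKind(str, enum.Enum):
    weighted_sum_threshold = "weighted_sum_threshold"
    count_threshold = "count_threshold"
    domain_weighted_threshold = "domain_weighted_threshold"


class ItemCategory(str, enum.Enum):
    clinical = "clinical"
    immunologic = "immunologic"
    none = "none"


class DefinitionError(ValueError):
    """A criteria definition violates the schema or its invariants."""


class PredicateError(ValueError):
    """A predicate references an undeclared feature or uses bad syntax."""


# ---------------------------------------------------------------------------
# predicates


def parse_predicate(expression: str) -> ast.expr:
    """Parse a boolean feature expression, rejecting anything but
    and/or/not over declared vocabulary names."""
    try:
        tree = ast.parse(expression, mode="eval").body
    except SyntaxError as exc:
        raise PredicateError(f"cannot parse predicate {expression!r}: {exc}") from exc
    for node in ast.walk(tree):
        if isinstance(node, ast.BoolOp):
            if not isinstance(node.op, (ast.And, ast.Or)):
                raise PredicateError(f"unsupported operator in {expression!r}")
        elif isinstance(node, ast.UnaryOp):
            if not isinstance(node.op, ast.Not):
                raise PredicateError(f"unsupported operator in {expression!r}")
        elif isinstance(node, ast.Name):
            if node.id not in VOCABULARY:
                raise PredicateError(
                    f"predicate {expression!r} references undeclared feature {node.id!r}"
                )
        elif isinstance(node, (ast.And, ast.Or, ast.Not, ast.Load)):
            pass
        else:
            raise PredicateError(
                f"unsupported syntax {type(node).__name__} in predicate {expression!r}"
            )
    return tree


def _eval_node(node: ast.expr, record: PatientRecord) -> int:
    if isinstance(node, ast.Name):
        return record.feature(node.id)
    if isinstance(node, ast.UnaryOp):
        return 1 - _eval_node(node.operand, record)
    if isinstance(node, ast.BoolOp):
        vals = (_eval_node(v, record) for v in node.values)
        if isinstance(node.op, ast.And):
            return int(all(vals))
        return int(any(vals))
    raise PredicateError(f"unsupported node {type(node).__name__}")  # pragma: no cover


def evaluate_predicate(predicate: Union[str, ast.expr], record: PatientRecord) -> int:
    """Evaluate a boolean feature expression on a record (absent feature = 0)."""
    node = parse_predicate(predicate) if isinstance(predicate, str) else predicate
    return _eval_node(node, record)


# ---------------------------------------------------------------------------
# definitions


class ProbabilityTransform(BaseModel):
    """Inverse-logit map from satisfied items to a probability percentage."""

    intercept: float
    coefficients: dict[str, float]

    model_config = {"frozen": True}


class CriterionItem(BaseModel):
    item_id: str
    predicate: str
    weight: float = 1.0
    domain: Optional[str] = None
    category: ItemCategory = ItemCategory.none

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _validate(self) -> "CriterionItem":
        if not math.isfinite(self.weight):
            raise DefinitionError(f"item {self.item_id!r}: weight must be finite")
        try:
            parse_predicate(self.predicate)
        except PredicateError as exc:
            raise DefinitionError(f"item {self.item_id!r}: {exc}") from exc
        return self


class CriteriaSet(BaseModel):
    name: str
    rule_kind: RuleKind
    items: list[CriterionItem]
    threshold: float
    threshold_is_strict: bool = False
    entry: Optional[str] = None
    min_clinical: int = 0
    min_immunologic: int = 0
    standalone: list[str] = Field(default_factory=list)
    probability_transform: Optional[ProbabilityTransform] = None
    category_cutpoints: tuple[float, float, float] = CATEGORY_CUTPOINTS

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _validate(self) -> "CriteriaSet":
        if not self.items:
            raise DefinitionError(f"{self.name}: items must be nonempty")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise DefinitionError(f"{self.name}: duplicate item_id")
        for expr in ([self.entry] if self.entry else []) + list(self.standalone):
            try:
                parse_predicate(expr)
            except PredicateError as exc:
                raise DefinitionError(f"{self.name}: {exc}") from exc
        if self.rule_kind is RuleKind.domain_weighted_threshold:
            missing = [it.item_id for it in self.items if it.domain is None]
            if missing:
                raise DefinitionError(
                    f"{self.name}: domain required for items {missing}"
                )
        if self.probability_transform is not None:
            unknown = set(self.probability_transform.coefficients) - set(ids)
            if unknown:
                raise DefinitionError(
                    f"{self.name}: probability_transform references unknown items {sorted(unknown)}"
                )
        if self.name == "SLERPI":
            pos = sum(it.weight for it in self.items if it.weight > 0)
            if abs(pos - 30.5) > 1e-9:
                raise DefinitionError(
                    f"SLERPI positive weights must sum to 30.5, got {pos}"
                )
            neg = [it for it in self.items if it.weight < 0]
            if len(neg) != 1 or neg[0].weight != -1.0:
                raise DefinitionError(
                    "SLERPI must carry exactly one negative weight of -1"
                )
        return self


def load_criteria_set(source: Union[str, Path, dict]) -> CriteriaSet:
    """Load and validate a criteria definition from YAML/JSON file or mapping.

    Raises :class:`DefinitionError` naming the offending field when the
    document violates the schema, references undeclared features, or
    breaks a set-specific invariant (e.g. the SLERPI weight-sum anchor).
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = source
    if not isinstance(doc, dict):
        raise DefinitionError("criteria definition must be a mapping")
    try:
        return CriteriaSet.model_validate(doc)
    except DefinitionError:
        raise
    except Exception as exc:  # pydantic ValidationError -> DefinitionError
        raise DefinitionError(str(exc)) from exc


def bundled_criteria_path(name: str) -> Path:
    """Path of a bundled definition: slerpi, acr1997, slicc2012, eular_acr2019."""
    path = DATA_DIR / f"{name}.yaml"
    if not path.exists():
        raise DefinitionError(f"no bundled criteria definition named {name!r}")
    return path


def load_bundled(name: str) -> CriteriaSet:
    return load_criteria_set(bundled_criteria_path(name))


def load_all_bundled() -> list[CriteriaSet]:
    """The four bundled sets in reporting order: ACR-1997, SLICC-2012,
    EULAR/ACR-2019, SLERPI."""
    return [load_bundled(n) for n in ("acr1997", "slicc2012", "eular_acr2019", "slerpi")]


# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class ClassificationResult:
    patient_id: str
    criteria_name: str
    score: float
    classified: int
    probability_pct: Optional[float] = None
    category: Optional[Category] = None
    entry_failed: int = 0


def probability_category(
    probability_pct: float,
    cutpoints: Sequence[float] = CATEGORY_CUTPOINTS,
) -> Category:
    """Ordinal category for a lupus probability percentage.

    Half-open bins [0, c1), [c1, c2), [c2, c3), [c3, 100] with default
    cutpoints (15, 44, 87) so every value in [0, 100] maps to exactly one
    of unlikely / possible / likely / definite.
    """
    if not 0.0 <= probability_pct <= 100.0:
        raise ValueError(f"probability_pct must be in [0, 100], got {probability_pct}")
    c1, c2, c3 = cutpoints
    if probability_pct < c1:
        return Category.unlikely
    if probability_pct < c2:
        return Category.possible
    if probability_pct < c3:
        return Category.likely
    return Category.definite


def _classified(score: float, criteria: CriteriaSet) -> int:
    if criteria.threshold_is_strict:
        return int(score > criteria.threshold)
    return int(score >= criteria.threshold)


def score_weighted_sum(record: PatientRecord, criteria: CriteriaSet) -> ClassificationResult:
    """Weighted-sum rule (SLERPI): score = sum of weights of satisfied items."""
    assert criteria.rule_kind is RuleKind.weighted_sum_threshold
    satisfied = {
        it.item_id: evaluate_predicate(it.predicate, record) for it in criteria.items
    }
    score = sum(it.weight * satisfied[it.item_id] for it in criteria.items)
    prob = cat = None
    if criteria.probability_transform is not None:
        pt = criteria.probability_transform
        logit = pt.intercept + sum(
            coef * satisfied.get(item_id, 0) for item_id, coef in pt.coefficients.items()
        )
        prob = 100.0 / (1.0 + math.exp(-logit))
        cat = probability_category(prob, criteria.category_cutpoints)
    return ClassificationResult(
        patient_id=record.id,
        criteria_name=criteria.name,
        score=score,
        classified=_classified(score, criteria),
        probability_pct=prob,
        category=cat,
    )


def score_count_threshold(record: PatientRecord, criteria: CriteriaSet) -> ClassificationResult:
    """Count rule (ACR-1997, SLICC-2012): score = number of satisfied items,
    with optional clinical/immunologic minima and standalone rules."""
    assert criteria.rule_kind is RuleKind.count_threshold
    n_clinical = n_immunologic = 0
    score = 0
    for it in criteria.items:
        if evaluate_predicate(it.predicate, record):
            score += 1
            if it.category is ItemCategory.clinical:
                n_clinical += 1
            elif it.category is ItemCategory.immunologic:
                n_immunologic += 1
    classified = (
        _classified(score, criteria)
        and n_clinical >= criteria.min_clinical
        and n_immunologic >= criteria.min_immunologic
    )
    if not classified:
        classified = any(
            evaluate_predicate(rule, record) for rule in criteria.standalone
        )
    return ClassificationResult(
        patient_id=record.id,
        criteria_name=criteria.name,
        score=float(score),
        classified=int(classified),
    )


def score_domain_weighted(record: PatientRecord, criteria: CriteriaSet) -> ClassificationResult:
    """Domain-weighted rule (EULAR/ACR-2019): entry criterion, then per
    domain only the highest-weighted satisfied item contributes."""
    assert criteria.rule_kind is RuleKind.domain_weighted_threshold
    if criteria.entry is not None and not evaluate_predicate(criteria.entry, record):
        return ClassificationResult(
            patient_id=record.id,
            criteria_name=criteria.name,
            score=0.0,
            classified=0,
            entry_failed=1,
        )
    best: dict[str, float] = {}
    for it in criteria.items:
        if evaluate_predicate(it.predicate, record):
            dom = it.domain or it.item_id
            best[dom] = max(best.get(dom, float("-inf")), it.weight)
    score = float(sum(best.values()))
    return ClassificationResult(
        patient_id=record.id,
        criteria_name=criteria.name,
        score=score,
        classified=_classified(score, criteria),
    )


_DISPATCH = {
    RuleKind.weighted_sum_threshold: score_weighted_sum,
    RuleKind.count_threshold: score_count_threshold,
    RuleKind.domain_weighted_threshold: score_domain_weighted,
}


def score_record(record: PatientRecord, criteria: CriteriaSet) -> ClassificationResult:
    """Score one record under a criteria set, dispatching on rule kind."""
    return _DISPATCH[criteria.rule_kind](record, criteria)


def apply_criteria(
    cohort: Sequence[PatientRecord], criteria: CriteriaSet
) -> list[ClassificationResult]:
    """One result per record, order preserved; errors carry the patient id."""
    out = []
    for rec in cohort:
        try:
            out.append(score_record(rec, criteria))
        except (PredicateError, KeyError) as exc:
            raise PredicateError(f"patient {rec.id!r}: {exc}") from exc
    return out
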