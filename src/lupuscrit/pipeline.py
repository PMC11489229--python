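"""End-to-end orchestration: cohort -> four criteria sets -> performance
report (overall, by polyautoimmunity stratum, by subphenotype), ordinal
category distribution, ROC/AUC and feature regression, assembled into a
deterministic JSON-serializable report."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .cohort import CohortSpec, CohortTable, default_spec, generate_cohort
from .criteria import (
    Category,
    ClassificationResult,
    CriteriaSet,
    apply_criteria,
    load_all_bundled,
    load_criteria_set,
)
from .evaluation import (
    PerformanceEstimate,
    delong_auc_ci,
    roc_curve,
    round_half_away,
    stratified_performance,
)
from .records import Group, Subphenotype
from .stats import format_p, ols_regression

_SUBPHENOTYPE_STRATA = tuple(s.value for s in Subphenotype)


class RunConfig(BaseModel):
    cohort_source: str = "generate"  # generate | file
    cohort_path: Optional[str] = None
    cohort_spec: Optional[CohortSpec] = None
    criteria_paths: list[str] = Field(default_factory=list)  # empty -> bundled four
    strata: list[str] = Field(
        default_factory=lambda: ["polyA", *_SUBPHENOTYPE_STRATA]
    )
    conf_level: float = 0.95
    seed: int = 0
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _validate(self) -> "RunConfig":
        if self.cohort_source not in ("generate", "file"):
            raise ValueError("cohort_source must be generate|file")
        if self.cohort_source == "file" and not self.cohort_path:
            raise ValueError("cohort_path required when cohort_source=file")
        if not 0.0 < self.conf_level < 1.0:
            raise ValueError("conf_level must be in (0,1)")
        bad = [s for s in self.strata if s != "polyA" and s not in _SUBPHENOTYPE_STRATA]
        if bad:
            raise ValueError(f"unknown strata {bad}")
        return self


def _estimate_block(est: dict[str, PerformanceEstimate]) -> dict:
    return {
        m: {
            "point_pct": round_half_away(e.point_pct, 1),
            "ci_low_pct": round_half_away(e.ci_low_pct, 1),
            "ci_high_pct": round_half_away(e.ci_high_pct, 1),
            "numerator": e.numerator,
            "denominator": e.denominator,
        }
        for m, e in est.items()
    }


def _category_distribution(results: list[ClassificationResult]) -> dict:
    counts = {c.value: 0 for c in Category}
    for r in results:
        if r.category is not None:
            counts[r.category.value] += 1
    total = sum(counts.values())
    return {
        "counts": counts,
        "pct": {
            c: (round_half_away(100.0 * k / total, 2) if total else None)
            for c, k in counts.items()
        },
    }


def _load_criteria(config: RunConfig) -> list[CriteriaSet]:
    if not config.criteria_paths:
        return load_all_bundled()
    return [load_criteria_set(p) for p in config.criteria_paths]


def evaluate_criteria_on_cohort(
    cohort: CohortTable,
    criteria: CriteriaSet,
    strata: list[str],
    conf_level: float = 0.95,
) -> dict:
    """Performance blocks for one criteria set: overall plus each
    requested stratum (polyA splits cases by flag; subphenotype strata
    keep flagged cases).  ROC uses the probability when the set defines
    one, the raw score otherwise."""
    results = apply_criteria(cohort.records, criteria)
    blocks = {
        "overall": _estimate_block(
            stratified_performance(cohort, results, lambda r: True, conf_level)
        )
    }
    for stratum in strata:
        if stratum == "polyA":
            for flag in (0, 1):
                blocks[f"polyA={flag}"] = _estimate_block(
                    stratified_performance(
                        cohort, results, lambda r, f=flag: r.polyA == f, conf_level
                    )
                )
        else:
            sub = Subphenotype(stratum)
            blocks[stratum] = _estimate_block(
                stratified_performance(
                    cohort, results, lambda r, s=sub: s in r.subphenotypes, conf_level
                )
            )

    by_id = {r.patient_id: r for r in results}
    truth = [int(rec.group is Group.case) for rec in cohort.records]
    has_prob = all(r.probability_pct is not None for r in results)
    scores = [
        by_id[rec.id].probability_pct if has_prob else by_id[rec.id].score
        for rec in cohort.records
    ]
    roc = roc_curve(scores, truth)
    auc, auc_ci = delong_auc_ci(scores, truth, conf_level)
    out = {
        "criteria": criteria.name,
        "metrics": blocks,
        "roc": {
            "auc": round(roc.auc, 4),
            "auc_ci": [round(auc_ci[0], 4), round(auc_ci[1], 4)],
            "score_scale": "probability_pct" if has_prob else "score",
            "operating_point": "probability > 50%" if has_prob else f"threshold {criteria.threshold}",
        },
        "n_classified": int(sum(r.classified for r in results)),
        "n_entry_failed": int(sum(r.entry_failed for r in results)),
    }
    if has_prob:
        case_ids = {rec.id for rec in cohort.cases()}
        out["category_distribution"] = {
            "cases": _category_distribution([r for r in results if r.patient_id in case_ids]),
            "controls": _category_distribution([r for r in results if r.patient_id not in case_ids]),
        }
    return out


def regression_block(cohort: CohortTable, outcome: str = "slerpi_probability") -> dict:
    """OLS of the SLERPI probability percentage (or raw score) on the
    14-feature panel, pooled over cases and controls.  Structurally
    constant features are dropped with a warning and listed."""
    from .criteria import load_bundled
    from .records import SLERPI_FEATURES

    slerpi = load_bundled("slerpi")
    results = apply_criteria(cohort.records, slerpi)
    y = [
        r.probability_pct if outcome == "slerpi_probability" else r.score
        for r in results
    ]
    X = pd.DataFrame(
        {f: [rec.feature(f) for rec in cohort.records] for f in SLERPI_FEATURES}
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = ols_regression(y, X)
    return {
        "outcome": outcome,
        "n": fit.n,
        "r_squared": round(fit.r_squared, 4),
        "dropped_columns": list(fit.dropped_columns),
        "warnings": [str(w.message) for w in caught],
        "coefficients": {
            name: {
                "beta": round(c.beta, 2),
                "se": round(c.se, 2),
                "t": round(c.t, 2),
                "p": format_p(c.p),
            }
            for name, c in fit.coefficients.items()
        },
        "intercept": round(fit.intercept, 2),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Full pipeline; deterministic given config (including seed)."""
    criteria_sets = _load_criteria(config)
    if config.cohort_source == "generate":
        spec = config.cohort_spec or default_spec(config.seed)
        cohort = generate_cohort(spec, seed=config.seed)
    else:
        from .io import read_cohort_csv

        cohort = read_cohort_csv(config.cohort_path)

    report = {
        "provenance": {
            "package": "lupuscrit",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                config.model_dump_json(exclude={"output_dir"}).encode()
            ).hexdigest(),
        },
        "cohort": {
            "n_case": len(cohort.cases()),
            "n_control": len(cohort.controls()),
            "strata": config.strata,
        },
        "criteria": [
            evaluate_criteria_on_cohort(cohort, cs, config.strata, config.conf_level)
            for cs in criteria_sets
        ],
        "regression": regression_block(cohort),
    }
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return report
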