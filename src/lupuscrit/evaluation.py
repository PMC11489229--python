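"""Diagnostic-performance evaluation.

Confusion matrices against the clinical-diagnosis gold standard,
sensitivity/specificity/accuracy with exact (Clopper-Pearson) binomial
confidence intervals, ROC/AUC with midrank tie handling (so the AUC
equals the scaled Mann-Whitney U statistic), subgroup analyses that
restrict the case set while retaining the full control group, and the
integer-count reconstruction used to audit published percentage tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .cohort import CohortTable
from .criteria import ClassificationResult
from .records import Group, PatientRecord


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed clinical tables;
    Python's ``round`` rounds half to even)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class PerformanceEstimate:
    metric: str
    point_pct: float
    ci_low_pct: float
    ci_high_pct: float
    numerator: int
    denominator: int
    conf_level: float


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_ci: Optional[tuple[float, float]] = None


def confusion_matrix(predicted: Sequence[int], truth: Sequence[int]) -> ConfusionMatrix:
    pred = np.asarray(predicted, dtype=int)
    tru = np.asarray(truth, dtype=int)
    if pred.shape != tru.shape or pred.ndim != 1:
        raise ValueError("predicted and truth must be equal-length 1-D arrays")
    if pred.size == 0:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (tru == 1))),
        fn=int(np.sum((pred == 0) & (tru == 1))),
        fp=int(np.sum((pred == 1) & (tru == 0))),
        tn=int(np.sum((pred == 0) & (tru == 0))),
    )


def clopper_pearson(successes: int, trials: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial interval via beta-distribution quantiles.

    Closed at the boundaries: low = 0 when successes = 0, high = 1 when
    successes = trials.
    """
    if not 0.0 < conf_level < 1.0:
        raise ValueError(f"conf_level must be in (0,1), got {conf_level}")
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    low, high = proportion_confint(successes, trials, alpha=1 - conf_level, method="beta")
    return (0.0 if successes == 0 else float(low), 1.0 if successes == trials else float(high))


def wilson_interval(successes: int, trials: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval, offered as an alternative to the exact one."""
    if not 0.0 < conf_level < 1.0:
        raise ValueError(f"conf_level must be in (0,1), got {conf_level}")
    low, high = proportion_confint(successes, trials, alpha=1 - conf_level, method="wilson")
    return float(low), float(high)


def _estimate(
    metric: str,
    numerator: int,
    denominator: int,
    conf_level: float,
    ci_method: Callable[[int, int, float], tuple[float, float]],
) -> PerformanceEstimate:
    if denominator == 0:
        raise ValueError(f"{metric}: zero denominator")
    low, high = ci_method(numerator, denominator, conf_level)
    return PerformanceEstimate(
        metric=metric,
        point_pct=100.0 * numerator / denominator,
        ci_low_pct=100.0 * low,
        ci_high_pct=100.0 * high,
        numerator=numerator,
        denominator=denominator,
        conf_level=conf_level,
    )


def diagnostic_metrics(
    cm: ConfusionMatrix,
    conf_level: float = 0.95,
    ci_method: str = "clopper-pearson",
) -> dict[str, PerformanceEstimate]:
    """Sensitivity, specificity and accuracy with exact binomial CIs.

    Point estimates are exact fractions (percent); round with
    :func:`round_half_away` for one-decimal table display.
    """
    method = {"clopper-pearson": clopper_pearson, "wilson": wilson_interval}[ci_method]
    return {
        "sensitivity": _estimate("sensitivity", cm.tp, cm.tp + cm.fn, conf_level, method),
        "specificity": _estimate("specificity", cm.tn, cm.fp + cm.tn, conf_level, method),
        "accuracy": _estimate("accuracy", cm.tp + cm.tn, cm.total, conf_level, method),
    }


def roc_curve(scores: Sequence[float], truth: Sequence[int]) -> RocResult:
    """Empirical ROC over all distinct score thresholds; trapezoidal AUC
    with midrank tie handling, hence AUC = U / (n1 * n2)."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=int)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if len(np.unique(t)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(t, s, drop_intermediate=False)
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(roc_auc_score(t, s)))


def delong_auc_ci(
    scores: Sequence[float], truth: Sequence[int], conf_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC with DeLong variance-based confidence interval."""
    from scipy.stats import norm, rankdata

    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=int)
    pos, neg = s[t == 1], s[t == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    # placement values (DeLong's V10 / V01 structural components)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = norm.ppf(0.5 + conf_level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def plot_roc(roc: RocResult, path, label: str = "score", operating_point: Optional[tuple[float, float]] = None) -> None:
    """Save a ROC curve (SVG/PNG by extension); marks the operating point
    when given as (fpr, tpr)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(roc.fpr, roc.tpr, lw=1.5, label=f"{label} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    if operating_point is not None:
        ax.plot(*operating_point, "o", c="crimson", ms=5, label="operating point")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def performance_from_results(
    cohort: CohortTable,
    results: Sequence[ClassificationResult],
    conf_level: float = 0.95,
) -> dict[str, PerformanceEstimate]:
    """Overall metrics: every case is a truth-positive, every control a
    truth-negative."""
    return stratified_performance(cohort, results, lambda r: True, conf_level)


def stratified_performance(
    cohort: CohortTable,
    results: Sequence[ClassificationResult],
    case_filter: Callable[[PatientRecord], bool],
    conf_level: float = 0.95,
) -> dict[str, PerformanceEstimate]:
    """Metrics on a case subgroup: sensitivity over the filtered cases only,
    specificity over the *full* control group (hence identical across
    subgroups), accuracy over their union."""
    by_id = {res.patient_id: res for res in results}
    missing = [r.id for r in cohort.records if r.id not in by_id]
    if missing:
        raise ValueError(f"missing classification results for {missing[:3]}...")
    kept_cases = [r for r in cohort.records if r.group is Group.case and case_filter(r)]
    controls = [r for r in cohort.records if r.group is Group.control]
    if not kept_cases:
        raise ValueError("case_filter selected no cases")
    pred = [by_id[r.id].classified for r in kept_cases + controls]
    tru = [1] * len(kept_cases) + [0] * len(controls)
    return diagnostic_metrics(confusion_matrix(pred, tru), conf_level)


def reconstruct_count(rate_pct: float, denominator: int) -> int:
    """The unique integer k in [0, denominator] whose percentage rounds
    (half away from zero, one decimal) to ``rate_pct``.

    Raises if no such k exists (the printed rate is inconsistent with the
    denominator) or several do (the rate does not pin the count down).
    """
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    hits = [
        k
        for k in range(denominator + 1)
        if abs(round_half_away(100.0 * k / denominator, 1) - rate_pct) < 1e-9
    ]
    if not hits:
        raise ValueError(
            f"no count in 0..{denominator} rounds to {rate_pct}% (inconsistent rate)"
        )
    if len(hits) > 1:
        raise ValueError(
            f"counts {hits} all round to {rate_pct}% of {denominator} (ambiguous rate)"
        )
    return hits[0]
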