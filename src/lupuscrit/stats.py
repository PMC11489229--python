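"""Inferential statistics for cohort comparison and feature attribution.

Multiple linear regression of the lupus-probability outcome on the binary
feature panel, Mann-Whitney U and chi-square bivariate tests for the
Table-style group comparison, and Kolmogorov-Smirnov normality screening
(Lilliefors-corrected by default, since location and scale are estimated
from the sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors


@dataclass(frozen=True)
class CoefficientEstimate:
    beta: float
    se: float
    t: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    coefficients: dict[str, CoefficientEstimate]
    intercept: float
    n: int
    r_squared: float
    dropped_columns: tuple[str, ...] = ()


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int = 0
    extra: Optional[dict] = None


def format_p(p: float) -> str:
    """Report style for p-values: values below 1e-4 print as '<0.0001'."""
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"


def ols_regression(
    outcome: Sequence[float],
    design: pd.DataFrame,
    drop_constant: bool = True,
) -> RegressionResult:
    """Least-squares fit of ``outcome`` on binary predictor columns.

    Constant (zero-variance) columns are dropped with a warning when
    ``drop_constant`` — structurally absent features (e.g. a feature with
    zero prevalence in the pooled sample) otherwise make the design
    rank-deficient.  Remaining collinearity raises an error naming the
    involved columns.
    """
    y = np.asarray(outcome, dtype=float)
    X = design.astype(float).copy()
    if len(y) != len(X):
        raise ValueError("outcome and design lengths differ")
    dropped = tuple(c for c in X.columns if X[c].nunique() <= 1)
    if dropped:
        if not drop_constant:
            raise ValueError(f"constant columns in design: {list(dropped)}")
        warnings.warn(
            f"dropping constant design columns: {list(dropped)}", stacklevel=2
        )
        X = X.drop(columns=list(dropped))
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError(f"design is rank deficient; check columns {list(X.columns)}")
    fit = sm.OLS(y, Xc).fit()
    coefs = {
        c: CoefficientEstimate(
            beta=float(fit.params[c]),
            se=float(fit.bse[c]),
            t=float(fit.tvalues[c]),
            p=float(fit.pvalues[c]),
        )
        for c in X.columns
    }
    return RegressionResult(
        coefficients=coefs,
        intercept=float(fit.params["const"]),
        n=len(y),
        r_squared=float(fit.rsquared),
        dropped_columns=dropped,
    )


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Mann-Whitney U (midrank ties): exact null distribution for small
    untied samples, tie-corrected continuity-corrected normal
    approximation otherwise.  ``statistic`` is U for ``sample_a``."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) < 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="mann_whitney",
        n1=a.size,
        n2=b.size,
        extra={"approximation": method},
    )


def chi_square_independence(table: Sequence[Sequence[int]], yates: bool = True) -> TestResult:
    """Pearson chi-square test of independence on an r x k count table;
    Yates continuity correction applied for 2x2 unless disabled."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D nonnegative count matrix")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("all marginal totals must be positive")
    correction = yates and obs.shape == (2, 2)
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=correction)
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        method="chi_square",
        n1=int(obs.sum()),
        extra={"dof": int(dof), "yates": bool(correction)},
    )


def ks_normality(sample: Sequence[float], lilliefors_correction: bool = True) -> TestResult:
    """One-sample KS distance against a normal with estimated mean/SD.

    With parameters estimated from the data the plain KS p-value is badly
    miscalibrated, so the Lilliefors-corrected p is the default; the
    uncorrected p is reported alongside.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("sample must be non-constant")
    if x.size < 50:
        warnings.warn("KS normality screen intended for n >= 50", stacklevel=2)
    stat_l, p_l = lilliefors(x, dist="norm", pvalmethod="table")
    stat_plain, p_plain = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    stat, p = (stat_l, p_l) if lilliefors_correction else (stat_plain, p_plain)
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        method="ks_normality",
        n1=x.size,
        extra={"p_plain_ks": float(p_plain), "p_lilliefors": float(p_l)},
    )
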