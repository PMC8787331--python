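"""Descriptive and inferential statistics for cohort tables.

Thin, contract-checked wrappers over scipy/statsmodels: Pearson correlations
with t-distribution p-values, one-way ANOVA, chi-square / Fisher exact tests
with the classic expected-count selection rule, and bivariate OLS regressions
of age acceleration on participant characteristics (unstandardised estimate,
SE, 95% CI, p).  Missing data are dropped pairwise for correlations and
listwise within each regression; every result echoes the n actually used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CorrelationResult",
    "RegressionRow",
    "pearson",
    "oneway_anova",
    "contingency_test",
    "bivariate_regression",
    "recode_smoking",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class RegressionRow:
    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-test p-value.

    Pairs with a missing value in either vector are dropped (pairwise-complete).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def oneway_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across >= 2 groups of values."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    if sum(map(len, arrays)) <= len(arrays):
        raise ValueError("need more observations than groups")
    with warnings.catch_warnings():
        # constant data yields F = 0 / NaN warnings we handle below
        warnings.simplefilter("ignore", category=RuntimeWarning)
        f, p = stats.f_oneway(*arrays)
    if np.isnan(f):  # zero within-group variance and zero between: define F = 0
        f, p = 0.0, 1.0
    return float(f), float(p)


def contingency_test(table) -> tuple[float, float, str]:
    """Chi-square or Fisher exact test of independence on a count table.

    Fisher's exact test is used for 2x2 tables whenever any expected count is
    below 5 (the returned statistic is then the sample odds ratio); larger
    tables with small expected counts fall back to chi-square with a warning,
    since no exact RxC test is feasible here.  Otherwise a chi-square test
    without continuity correction is applied.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has an all-zero row or column")
    expected = stats.contingency.expected_freq(t)
    small = (expected < 5).any()
    if small and t.shape == (2, 2):
        odds, p = stats.fisher_exact(t.astype(int))
        return float(odds), float(p), "fisher"
    if small:
        warnings.warn(
            "expected counts < 5 in a table larger than 2x2; "
            "no exact test feasible, using chi-square",
            stacklevel=2,
        )
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p), "chi-square"


def recode_smoking(smoking: pd.Series) -> pd.Series:
    """Collapse the five-level smoking history to yes/no for testing.

    Current, social and past (quit) smokers are "yes"; never smokers are
    "no"; unknown stays missing.
    """
    mapping = {"current": "yes", "social": "yes", "quit": "yes", "past": "yes", "never": "no", "no": "no"}
    return smoking.astype(str).str.lower().map(mapping)


def bivariate_regression(
    accel, covariate, reference: str | None = None
) -> list[RegressionRow]:
    """Simple OLS of acceleration on one covariate (Table-3 style rows).

    A numeric covariate yields one row; a categorical covariate is dummy-coded
    against ``reference`` (default: first level in sorted order) and yields
    one row per non-reference level.  95% CIs use the t quantile.  Missing
    values are dropped listwise; each row echoes the n used.  A perfect fit
    (zero residual variance) reports p as its zero limit with a warning.
    """
    y = pd.Series(accel).reset_index(drop=True)
    x = pd.Series(covariate).reset_index(drop=True)
    keep = y.notna() & x.notna()
    y, x = y[keep].astype(float), x[keep]
    n = len(y)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    if x.nunique() < 2:
        raise ValueError("constant covariate")
    numeric = pd.api.types.is_numeric_dtype(x)
    if numeric:
        X = pd.DataFrame({str(getattr(covariate, "name", "x") or "x"): x.astype(float)})
    else:
        levels = sorted(x.astype(str).unique())
        ref = reference if reference is not None else levels[0]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not among {levels}")
        X = pd.get_dummies(x.astype(str), dtype=float).drop(columns=ref)
        X.columns = [f"{getattr(covariate, 'name', 'x') or 'x'}[{lvl} vs {ref}]" for lvl in X.columns]
    model = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
    if model.ssr <= 1e-12 * max(model.centered_tss, 1.0):
        warnings.warn("perfect fit: residual variance ~ 0; p reported at its zero limit", stacklevel=2)
    ci = model.conf_int(alpha=0.05)
    rows = []
    for j, term in enumerate(X.columns, start=1):
        rows.append(
            RegressionRow(
                term=str(term),
                estimate=float(model.params[j]),
                se=float(model.bse[j]),
                ci_low=float(ci[j][0]),
                ci_high=float(ci[j][1]),
                p=float(model.pvalues[j]) if np.isfinite(model.pvalues[j]) else 0.0,
                n=n,
            )
        )
    return rows
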