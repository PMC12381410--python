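"""Descriptive and auxiliary behavioral statistics.

Scale reliability (Cronbach's alpha), paired t-tests for longitudinal
shifts, and covariate-adjusted partial correlation matrices with the
conventional significance stars (0.05 / 0.01 / 0.001, uncorrected).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cpm import residualize
from .errors import DegenerateDataError, InvalidConfigError


def cronbach_alpha(items: np.ndarray) -> float:
    """Internal consistency: alpha = k/(k-1) * (1 - sum var_i / var_total).

    ``items`` is subjects x items; variances use ddof=1. Invariant under
    adding a constant to any item.
    """
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[1] < 2:
        raise InvalidConfigError("need a subjects x items matrix with >= 2 items")
    if items.shape[0] < 3:
        raise InvalidConfigError("need at least 3 subjects")
    k = items.shape[1]
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("total score has zero variance")
    item_var = items.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def paired_t(t1: np.ndarray, t2: np.ndarray) -> tuple[float, float]:
    """Paired-samples t-test on t1 - t2 (positive t = decrease over time).

    Returns (t, two-tailed p); zero-variance differences are an error.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if t1.shape != t2.shape:
        raise InvalidConfigError("paired samples must have equal length")
    if t1.size < 3:
        raise InvalidConfigError("need at least 3 pairs")
    if np.std(t1 - t2) == 0:
        raise DegenerateDataError("paired differences have zero variance")
    res = stats.ttest_rel(t1, t2)
    return float(res.statistic), float(res.pvalue)


def partial_corr_matrix(
    table: pd.DataFrame,
    variables: list[str],
    covariates: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise partial Pearson correlations controlling for covariates.

    Each variable is residualized against an intercept plus the covariate
    columns; two-tailed p-values use df = n - 2 - k. Returns (r, p)
    DataFrames with unit diagonal / zero-p diagonal.
    """
    covariates = covariates or []
    missing = [c for c in list(variables) + covariates if c not in table.columns]
    if missing:
        raise InvalidConfigError(f"table lacks columns: {missing}")
    n = len(table)
    k = len(covariates)
    df = n - 2 - k
    if df < 1:
        raise InvalidConfigError("too few subjects for the covariate count")
    C = table[covariates].to_numpy(dtype=float) if covariates else None
    resid = np.column_stack(
        [residualize(table[v].to_numpy(dtype=float), C) for v in variables]
    )
    norms = np.linalg.norm(resid, axis=0)
    if (norms == 0).any():
        bad = [v for v, s in zip(variables, norms) if s == 0]
        raise DegenerateDataError(f"zero residual variance for: {bad}")
    r = (resid.T @ resid) / np.outer(norms, norms)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    np.fill_diagonal(p, 0.0)
    idx = pd.Index(variables)
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


def significance_stars(p: float) -> str:
    """Conventional star flags: *** < 0.001, ** < 0.01, * < 0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def describe(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Mean and SD (ddof=1) per variable."""
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise InvalidConfigError(f"table lacks columns: {missing}")
    return pd.DataFrame(
        {
            "mean": [table[v].mean() for v in variables],
            "sd": [table[v].std(ddof=1) for v in variables],
        },
        index=pd.Index(variables, name="variable"),
    )


def starred_matrix(r: pd.DataFrame, p: pd.DataFrame) -> pd.DataFrame:
    """Lower-triangle formatted correlation table with star flags."""
    out = pd.DataFrame("", index=r.index, columns=r.columns, dtype=object)
    vals = r.to_numpy()
    ps = p.to_numpy()
    for i in range(len(r)):
        for j in range(i + 1):
            if i == j:
                out.iat[i, j] = "1"
            else:
                out.iat[i, j] = f"{vals[i, j]:.3f}{significance_stars(ps[i, j])}"
    return out
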