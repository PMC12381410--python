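"""Time-normalized change scores and longitudinal CPM.

Follow-up intervals differ between subjects, so raw t2 - t1 differences
are annualized: ``((t2 - t1) / interval_days) * 365``. The longitudinal
analysis then asks whether the FC network previously identified for a
metacognition subdimension at baseline can predict the annualized change
of an emotional-distress outcome: the CPM pipeline is rerun with the edge
universe restricted to that prior network (selection within folds
re-applied inside the restricted universe by default; a wholesale mode
that uses the prior edges without re-selection is also available).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cpm as _cpm
from .connectome import EdgeTable
from .errors import EmptyMaskError, InvalidConfigError

logger = logging.getLogger(__name__)


def annualize_change(t1, t2, interval_days):
    """Annualized change score: ((t2 - t1) / interval_days) * 365.

    Accepts scalars or aligned arrays; nonpositive intervals are an error.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    interval = np.asarray(interval_days, dtype=float)
    if (interval <= 0).any():
        raise InvalidConfigError("measurement interval must be positive")
    out = (t2 - t1) / interval * 365.0
    return float(out) if out.ndim == 0 else out


def change_table(
    behavior: pd.DataFrame,
    outcomes: tuple[str, ...],
    t2_suffix: str = "_t2",
    interval_col: str = "interval_days",
) -> pd.DataFrame:
    """Annualized change scores for subjects with a second time point.

    Subjects missing any t2 score or the interval are dropped with a
    logged count (e.g. 180 enrolled -> 159 retained).
    """
    needed = [interval_col] + [f"{o}{t2_suffix}" for o in outcomes]
    missing_cols = [c for c in needed if c not in behavior.columns]
    if missing_cols:
        raise InvalidConfigError(f"behavior table lacks columns: {missing_cols}")
    keep = behavior[needed].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "dropping %d of %d subjects without complete follow-up",
            dropped,
            len(behavior),
        )
    sub = behavior.loc[keep]
    out = pd.DataFrame({"subject_id": sub["subject_id"]})
    out["interval_days"] = sub[interval_col].to_numpy()
    for o in outcomes:
        out[f"{o}_change"] = annualize_change(
            sub[o].to_numpy(), sub[f"{o}{t2_suffix}"].to_numpy(), out["interval_days"]
        )
    return out.reset_index(drop=True)


@dataclass
class ChangePredictionResult:
    """Restricted-universe CPM result with masks mapped back to full edges."""

    result: _cpm.CpmResult
    prior_mask: np.ndarray           # the restricting universe (full length)
    consensus_mask_full: np.ndarray  # consensus, in the full edge universe
    full_sample_mask_full: np.ndarray
    p_perm: float | None = None

    @property
    def r(self) -> float:
        return self.result.r


def _expand(mask_small: np.ndarray, prior_idx: np.ndarray, e_total: int) -> np.ndarray:
    full = np.zeros(e_total, dtype=bool)
    full[prior_idx[mask_small]] = True
    return full


def predict_change(
    edges: EdgeTable | np.ndarray,
    prior_mask: np.ndarray,
    change: np.ndarray,
    covariates: np.ndarray | None = None,
    p_threshold: float = 0.01,
    tail: str = "positive",
    cv: str = "loo",
    k: int = 10,
    repeats: int = 1,
    reselect: bool = True,
    n_perm: int = 0,
    seed: int = 0,
) -> ChangePredictionResult:
    """CPM on baseline edges restricted to a previously identified network.

    ``prior_mask`` (full-length boolean) defines the edge universe; with
    ``reselect=True`` (default) edge selection is re-applied within folds
    inside that universe, typically recovering a sparser predictive
    subset. With ``reselect=False`` every prior edge is used wholesale in
    each fold's summed strength. ``prior_mask`` equal to all edges with
    re-selection reduces exactly to unrestricted CPM. When ``n_perm > 0``
    a one-tailed permutation p for the observed r is attached.
    """
    X = _cpm._as_matrix(edges)
    prior_mask = np.asarray(prior_mask, dtype=bool)
    if prior_mask.size != X.shape[1]:
        raise InvalidConfigError("prior mask length does not match edge count")
    if not prior_mask.any():
        raise EmptyMaskError("prior mask is empty")
    change = np.asarray(change, dtype=float)
    prior_idx = np.flatnonzero(prior_mask)
    Xr = X[:, prior_idx]
    e_total = X.shape[1]

    if reselect:
        if cv == "loo":
            res = _cpm.cpm_loocv(Xr, change, covariates, p_threshold, tail)
        elif cv == "kfold":
            res = _cpm.cpm_kfold(
                Xr, change, covariates, p_threshold, tail, k=k, repeats=repeats, seed=seed
            )
        else:
            raise InvalidConfigError("cv must be 'loo' or 'kfold'")
        consensus_full = _expand(res.consensus_mask, prior_idx, e_total)
        full_mask_full = _expand(res.full_sample_mask, prior_idx, e_total)
    else:
        res = _fixed_mask_cv(Xr, change, cv, k, repeats, seed, tail, p_threshold)
        consensus_full = prior_mask.copy()
        full_mask_full = prior_mask.copy()

    p_perm = None
    if n_perm > 0:
        if reselect:
            p_perm = _cpm.permutation_test(
                Xr, change, covariates, p_threshold, tail,
                n_perm=n_perm, seed=seed, cv=cv, k=k, repeats=repeats,
            )
        else:
            p_perm = _cpm.permutation_test(
                Xr, change, covariates, p_threshold, tail, n_perm=n_perm, seed=seed,
                cpm_callable=lambda yy: _fixed_mask_cv(
                    Xr, yy, cv, k, repeats, seed, tail, p_threshold
                ).r,
            )
        res.p_perm = p_perm
    return ChangePredictionResult(
        result=res,
        prior_mask=prior_mask,
        consensus_mask_full=consensus_full,
        full_sample_mask_full=full_mask_full,
        p_perm=p_perm,
    )


def _fixed_mask_cv(
    Xr: np.ndarray,
    y: np.ndarray,
    cv: str,
    k: int,
    repeats: int,
    seed: int,
    tail: str,
    p_threshold: float,
) -> _cpm.CpmResult:
    """Cross-validated strength -> score fit using every restricted edge
    (no per-fold selection); folds only refit the linear map."""
    n, e = Xr.shape
    s = Xr.sum(axis=1)
    y = np.asarray(y, dtype=float)

    def fit_fold(train: np.ndarray, test: np.ndarray) -> np.ndarray:
        var = s[train].var()
        if var == 0:
            return np.full(test.size, np.nan)
        slope = np.cov(s[train], y[train], ddof=0)[0, 1] / var
        intercept = y[train].mean() - slope * s[train].mean()
        return intercept + slope * s[test]

    all_idx = np.arange(n)
    if cv == "loo":
        predicted = np.full(n, np.nan)
        for i in range(n):
            predicted[i] = fit_fold(np.delete(all_idx, i), np.array([i]))[0]
        n_folds = n
    elif cv == "kfold":
        rng = np.random.default_rng(seed)
        per_repeat = np.full((repeats, n), np.nan)
        for rep in range(repeats):
            order = rng.permutation(n)
            for test in np.array_split(order, k):
                train = np.setdiff1d(all_idx, test, assume_unique=True)
                per_repeat[rep, test] = fit_fold(train, test)
        with np.errstate(invalid="ignore"):
            predicted = np.nanmean(per_repeat, axis=0)
        n_folds = k * repeats
    else:
        raise InvalidConfigError("cv must be 'loo' or 'kfold'")
    r, n_missing = _cpm._pearson_valid(predicted, y)
    full_mask = np.ones(e, dtype=bool)
    return _cpm.CpmResult(
        tail=tail,
        predicted=predicted,
        observed=y,
        r=r,
        n_folds=n_folds,
        n_missing=n_missing,
        flagged_unreliable=n_missing > _cpm.UNRELIABLE_FOLD_FRACTION * n,
        consensus_mask=full_mask.copy(),
        full_sample_mask=full_mask,
        n_selected_full=e,
        p_threshold=p_threshold,
        cv=f"{cv}(fixed-mask)",
        seed=seed,
    )
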