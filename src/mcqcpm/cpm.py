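"""Connectome-based predictive modeling (CPM).

The protocol: for a behavioral score, correlate every FC edge with the
score across training subjects (partial correlation controlling for age,
gender and head motion), keep edges with two-tailed p below a threshold
(default 0.01), split them by correlation sign into a positively and a
negatively correlated network, sum each training subject's Fisher-z values
over the selected edges, fit a one-variable linear regression from summed
strength to score, and apply it to the held-out subject(s). Model quality
is the Pearson correlation between observed and predicted scores across
held-out subjects; its significance comes from a one-tailed permutation
test in which the behavior labels are shuffled and the *entire* pipeline
(selection included) is rerun.

Edge selection is performed inside every training fold, so held-out data
never leak into feature selection or model fitting. A separate full-sample
selection is reported as the descriptive network (its edge count is what
anatomical summaries describe), alongside the consensus mask of edges
selected in every fold.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .connectome import EdgeTable
from .errors import DegenerateDataError, EmptyMaskError, InvalidConfigError

#: Fraction of empty-mask folds above which a result is flagged unreliable.
UNRELIABLE_FOLD_FRACTION = 0.2


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept-plus-covariates design matrix; raises on rank deficiency."""
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        return np.ones((n, 1))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    if covariates.shape[0] != n:
        raise InvalidConfigError("covariate rows must match subject count")
    C = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        # name the first column whose addition kills the rank
        for j in range(1, C.shape[1]):
            if np.linalg.matrix_rank(C[:, : j + 1]) < j + 1:
                raise DegenerateDataError(
                    f"covariate column {j - 1} is collinear with the preceding "
                    "columns (plus intercept)"
                )
    return C


def residualize(v: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
    """Residual of ``v`` after OLS on an intercept plus the covariates.

    With no covariates this is simply mean-centering. The result is
    orthogonal to every covariate column and to the intercept.
    """
    v = np.asarray(v, dtype=float)
    C = _design(covariates, v.shape[0])
    beta, *_ = np.linalg.lstsq(C, v, rcond=None)
    return v - C @ beta


# ---------------------------------------------------------------------------
# edge selection
# ---------------------------------------------------------------------------

@dataclass
class EdgeSelectionResult:
    """Per-edge partial correlations with sign-split significance masks."""

    r: np.ndarray
    p: np.ndarray
    pos_mask: np.ndarray
    neg_mask: np.ndarray
    p_threshold: float
    df: int

    @property
    def n_pos(self) -> int:
        return int(self.pos_mask.sum())

    @property
    def n_neg(self) -> int:
        return int(self.neg_mask.sum())


def _as_matrix(edges: EdgeTable | np.ndarray) -> np.ndarray:
    if isinstance(edges, EdgeTable):
        return edges.values
    return np.asarray(edges, dtype=float)


def select_edges(
    edges: EdgeTable | np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | None = None,
    p_threshold: float = 0.01,
) -> EdgeSelectionResult:
    """Correlate every edge with the behavior, controlling for covariates.

    ``r_k`` is the Pearson correlation between the residualized edge and
    the residualized behavior; its two-tailed p-value uses
    ``t = r * sqrt(df / (1 - r^2))`` with ``df = n - 2 - k`` covariates.
    Edges with ``p < p_threshold`` are split by sign into the positively
    and negatively correlated masks.
    """
    X = _as_matrix(edges)
    y = np.asarray(behavior, dtype=float)
    n = y.shape[0]
    if X.shape[0] != n:
        raise InvalidConfigError("edge rows must match behavior length")
    if not (0.0 < p_threshold <= 0.05):
        raise InvalidConfigError("p_threshold must lie in (0, 0.05]")
    if y.std() == 0:
        raise DegenerateDataError("behavior has zero variance")
    C = _design(covariates, n)
    k = C.shape[1] - 1
    df = n - 2 - k
    if df < 1:
        raise InvalidConfigError("too few subjects for the covariate count")
    beta_x, *_ = np.linalg.lstsq(C, X, rcond=None)
    Xr = X - C @ beta_x
    yr = residualize(y, covariates)
    y_norm = np.linalg.norm(yr)
    x_norm = np.linalg.norm(Xr, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xr.T @ yr) / (x_norm * y_norm)
    r = np.where(np.isfinite(r), r, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    t = np.where(np.isfinite(t), t, np.inf * np.sign(r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    sig = p < p_threshold
    return EdgeSelectionResult(
        r=r,
        p=p,
        pos_mask=sig & (r > 0),
        neg_mask=sig & (r < 0),
        p_threshold=p_threshold,
        df=df,
    )


def summed_strength(edge_row: np.ndarray, mask: np.ndarray) -> float:
    """Sum of a subject's Fisher-z values over the masked edges.

    Signs of the individual edges are retained; an empty mask means no
    model can be built and raises :class:`EmptyMaskError` rather than
    returning zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot compute summed strength over an empty mask")
    return float(np.asarray(edge_row, dtype=float)[mask].sum())


# ---------------------------------------------------------------------------
# cross-validated prediction
# ---------------------------------------------------------------------------

@dataclass
class CpmResult:
    """Cross-validated prediction of one behavior from one edge network."""

    tail: str
    predicted: np.ndarray           # per-subject, NaN where no model was built
    observed: np.ndarray
    r: float                        # observed-vs-predicted Pearson r
    n_folds: int
    n_missing: int                  # subjects without a prediction
    flagged_unreliable: bool
    consensus_mask: np.ndarray      # edges selected in every fold
    full_sample_mask: np.ndarray    # descriptive full-sample selection
    n_selected_full: int
    p_threshold: float
    cv: str
    seed: int | None = None
    p_perm: float | None = None
    q: float | None = None
    fold_masks: np.ndarray | None = field(default=None, repr=False)
    fold_coefs: np.ndarray | None = field(default=None, repr=False)


def _pearson_valid(pred: np.ndarray, obs: np.ndarray) -> tuple[float, int]:
    valid = np.isfinite(pred)
    n_missing = int((~valid).sum())
    if valid.sum() < 3:
        return float("nan"), n_missing
    r = float(np.corrcoef(pred[valid], obs[valid])[0, 1])
    return r, n_missing


def _fit_predict_fold(
    X: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    train: np.ndarray,
    test: np.ndarray,
    p_threshold: float,
    tail: str,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Select on the training subjects only, fit strength -> score, predict
    the held-out subjects. Returns (predictions, mask, (slope, intercept))."""
    C_train = covariates[train] if covariates is not None else None
    sel = select_edges(X[train], y[train], C_train, p_threshold)
    mask = sel.pos_mask if tail == "positive" else sel.neg_mask
    nan = np.full(test.shape[0], np.nan)
    if not mask.any():
        return nan, mask, (np.nan, np.nan)
    s_train = X[np.ix_(train, np.flatnonzero(mask))].sum(axis=1)
    var = s_train.var()
    if var == 0:
        return nan, mask, (np.nan, np.nan)
    slope = np.cov(s_train, y[train], ddof=0)[0, 1] / var
    intercept = y[train].mean() - slope * s_train.mean()
    s_test = X[np.ix_(test, np.flatnonzero(mask))].sum(axis=1)
    return intercept + slope * s_test, mask, (float(slope), float(intercept))


def _check_tail(tail: str) -> None:
    if tail not in ("positive", "negative"):
        raise InvalidConfigError("tail must be 'positive' or 'negative'")


def _run_cv(
    X: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    folds: Sequence[np.ndarray],
    p_threshold: float,
    tail: str,
    keep_fold_details: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Run selection + fit + predict over the given test folds.

    Returns (predicted, consensus_mask, fold_masks, fold_coefs).
    """
    n, e = X.shape
    predicted = np.full(n, np.nan)
    consensus = np.ones(e, dtype=bool)
    all_idx = np.arange(n)
    fold_masks = np.zeros((len(folds), e), dtype=bool) if keep_fold_details else None
    fold_coefs = np.zeros((len(folds), 2)) if keep_fold_details else None
    for f, test in enumerate(folds):
        train = np.setdiff1d(all_idx, test, assume_unique=True)
        pred, mask, coefs = _fit_predict_fold(
            X, y, covariates, train, test, p_threshold, tail
        )
        predicted[test] = pred
        consensus &= mask
        if keep_fold_details:
            fold_masks[f] = mask
            fold_coefs[f] = coefs
    return predicted, consensus, fold_masks, fold_coefs


def cpm_loocv(
    edges: EdgeTable | np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | None = None,
    p_threshold: float = 0.01,
    tail: str = "positive",
    keep_fold_details: bool = False,
) -> CpmResult:
    """Leave-one-out cross-validated CPM.

    Each subject is predicted by a model whose edge selection and linear
    fit used only the remaining n-1 subjects. Folds whose selected mask is
    empty yield a missing prediction; the observed-vs-predicted r is
    computed over subjects with predictions, and results with more than
    20% missing folds are flagged unreliable.
    """
    _check_tail(tail)
    X = _as_matrix(edges)
    y = np.asarray(behavior, dtype=float)
    n = y.shape[0]
    if n < 20:
        raise InvalidConfigError("LOOCV requires at least 20 subjects")
    folds = [np.array([i]) for i in range(n)]
    predicted, consensus, fold_masks, fold_coefs = _run_cv(
        X, y, covariates, folds, p_threshold, tail, keep_fold_details
    )
    r, n_missing = _pearson_valid(predicted, y)
    full = select_edges(X, y, covariates, p_threshold)
    full_mask = full.pos_mask if tail == "positive" else full.neg_mask
    return CpmResult(
        tail=tail,
        predicted=predicted,
        observed=y,
        r=r,
        n_folds=n,
        n_missing=n_missing,
        flagged_unreliable=n_missing > UNRELIABLE_FOLD_FRACTION * n,
        consensus_mask=consensus,
        full_sample_mask=full_mask,
        n_selected_full=int(full_mask.sum()),
        p_threshold=p_threshold,
        cv="loo",
        fold_masks=fold_masks,
        fold_coefs=fold_coefs,
    )


def cpm_kfold(
    edges: EdgeTable | np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | None = None,
    p_threshold: float = 0.01,
    tail: str = "positive",
    k: int = 10,
    repeats: int = 100,
    seed: int = 0,
) -> CpmResult:
    """Repeated k-fold CPM with per-subject predictions averaged over repeats.

    Per repeat, subjects are randomly partitioned into ``k`` folds (seeded);
    each subject's predictions are averaged across repeats (ignoring
    missing folds) before the observed-vs-predicted correlation is taken.
    ``k = n`` with ``repeats = 1`` reduces exactly to LOOCV.
    """
    _check_tail(tail)
    X = _as_matrix(edges)
    y = np.asarray(behavior, dtype=float)
    n = y.shape[0]
    if k < 2:
        raise InvalidConfigError("k must be at least 2")
    if k > n:
        raise InvalidConfigError("k cannot exceed the number of subjects")
    if repeats < 1:
        raise InvalidConfigError("repeats must be at least 1")
    rng = np.random.default_rng(seed)
    per_repeat = np.full((repeats, n), np.nan)
    consensus = np.ones(X.shape[1], dtype=bool)
    for rep in range(repeats):
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        predicted, cons, _, _ = _run_cv(X, y, covariates, folds, p_threshold, tail)
        per_repeat[rep] = predicted
        consensus &= cons
    with np.errstate(invalid="ignore"):
        predicted = np.nanmean(per_repeat, axis=0)
    r, n_missing = _pearson_valid(predicted, y)
    full = select_edges(X, y, covariates, p_threshold)
    full_mask = full.pos_mask if tail == "positive" else full.neg_mask
    return CpmResult(
        tail=tail,
        predicted=predicted,
        observed=y,
        r=r,
        n_folds=k * repeats,
        n_missing=n_missing,
        flagged_unreliable=n_missing > UNRELIABLE_FOLD_FRACTION * n,
        consensus_mask=consensus,
        full_sample_mask=full_mask,
        n_selected_full=int(full_mask.sum()),
        p_threshold=p_threshold,
        cv=f"kfold(k={k},repeats={repeats})",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fast LOOCV engine (used by the permutation test)
# ---------------------------------------------------------------------------

class LoocvEngine:
    """Vectorized leave-one-out CPM evaluator.

    Everything that does not depend on the behavior vector — per-fold
    covariate Gram inverses and residualized-edge sums of squares — is
    precomputed once, so evaluating the pipeline for a (permuted) behavior
    costs a handful of BLAS matrix products. Numerically equivalent to
    :func:`cpm_loocv` (unit-tested to ~1e-10); selection thresholds are
    applied as ``|r| > r_crit``, the exact inverse of the t-test p-value.
    """

    def __init__(
        self,
        edges: EdgeTable | np.ndarray,
        covariates: np.ndarray | None,
        p_threshold: float = 0.01,
    ):
        X = _as_matrix(edges)
        n, e = X.shape
        if n < 20:
            raise InvalidConfigError("LOOCV requires at least 20 subjects")
        C = _design(covariates, n)
        p = C.shape[1]
        self.X = X
        self.C = C
        self.n, self.e, self.p = n, e, p
        k = p - 1
        self.df = (n - 1) - 2 - k
        if self.df < 1:
            raise InvalidConfigError("too few subjects for the covariate count")
        t_crit = stats.t.isf(p_threshold / 2.0, self.df)
        self.r_crit = t_crit / np.sqrt(self.df + t_crit ** 2)
        # per-fold Gram inverses G_f = inv(C_f' C_f), batched
        G_full = C.T @ C
        outer_c = C[:, :, None] * C[:, None, :]          # (n, p, p)
        self.G = np.linalg.inv(G_full[None] - outer_c)    # (n, p, p)
        # per-fold residual sum of squares of every edge
        B_full = C.T @ X                                  # (p, e)
        B = B_full[None] - C[:, :, None] * X[:, None, :]  # (n, p, e)
        A = np.einsum("fpq,fqe->fpe", self.G, B)
        q = np.einsum("fpe,fpe->fe", A, B)
        colsum_x2 = (X ** 2).sum(axis=0)
        self.edge_rss = np.maximum(colsum_x2[None] - X ** 2 - q, 0.0)  # (n, e)
        self.B_full = B_full

    def evaluate(self, y: np.ndarray, tail: str = "positive") -> tuple[float, np.ndarray]:
        """Full LOOCV pipeline for one behavior vector.

        Returns (observed-vs-predicted r, per-subject predictions).
        """
        _check_tail(tail)
        X, C, n = self.X, self.C, self.n
        y = np.asarray(y, dtype=float)
        # fold-wise covariate fit of y
        b_full = C.T @ y                                  # (p,)
        b = b_full[None] - C * y[:, None]                 # (n, p)
        beta = np.einsum("fpq,fq->fp", self.G, b)         # (n, p)
        F = C @ beta.T                                    # (n, n): F[j, f]
        U = y[:, None] - F
        np.fill_diagonal(U, 0.0)
        y_rss = (U ** 2).sum(axis=0)                      # (n,)
        num = X.T @ U                                     # (e, n)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num.T / np.sqrt(self.edge_rss * y_rss[:, None])  # (n, e)
        r = np.where(np.isfinite(r), r, 0.0)
        if tail == "positive":
            M = (r > self.r_crit).astype(X.dtype)
        else:
            M = (r < -self.r_crit).astype(X.dtype)
        S = X @ M.T                                       # (n, n): S[j, f]
        diag_s = np.diag(S).copy()
        nt = n - 1
        s_sum = S.sum(axis=0) - diag_s
        s2_sum = (S ** 2).sum(axis=0) - diag_s ** 2
        sy_sum = S.T @ y - diag_s * y
        y_sum = y.sum() - y
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (sy_sum - s_sum * y_sum / nt) / (s2_sum - s_sum ** 2 / nt)
            intercept = y_sum / nt - slope * s_sum / nt
            pred = intercept + slope * diag_s
        empty = M.sum(axis=1) == 0
        pred = np.where(empty | ~np.isfinite(pred), np.nan, pred)
        r_obs, _ = _pearson_valid(pred, y)
        return r_obs, pred


def permutation_test(
    edges: EdgeTable | np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | None = None,
    p_threshold: float = 0.01,
    tail: str = "positive",
    n_perm: int = 1000,
    seed: int = 0,
    cv: str = "loo",
    k: int = 10,
    repeats: int = 1,
    cpm_callable: Callable[[np.ndarray], float] | None = None,
    return_null: bool = False,
):
    """One-tailed permutation significance of the observed-vs-predicted r.

    The behavior labels are permuted ``n_perm`` times (covariate rows stay
    attached to their subjects) and the full pipeline — edge selection
    included — is rerun per permutation. The plus-one estimator
    ``p = (#{r_null >= r_obs} + 1) / (n_perm + 1)`` can never reach 0,
    matching the one-sided "significant positive r" decision rule.

    ``cpm_callable``, if given, maps a behavior vector to an r value and
    overrides the built-in cross-validation (useful for custom schemes).
    """
    if n_perm < 100:
        raise InvalidConfigError("n_perm must be at least 100")
    y = np.asarray(behavior, dtype=float)
    rng = np.random.default_rng(seed)
    if cpm_callable is not None:
        run = cpm_callable
    elif cv == "loo":
        engine = LoocvEngine(edges, covariates, p_threshold)
        run = lambda yy: engine.evaluate(yy, tail)[0]
    elif cv == "kfold":
        run = lambda yy: cpm_kfold(
            edges, yy, covariates, p_threshold, tail, k=k, repeats=repeats, seed=seed
        ).r
    else:
        raise InvalidConfigError("cv must be 'loo' or 'kfold'")
    r_obs = run(y)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = run(rng.permutation(y))
    if np.isnan(r_obs):
        p = float("nan")
    else:
        p = (np.sum(null >= r_obs) + 1.0) / (n_perm + 1.0)
    if return_null:
        return float(p), float(r_obs), null
    return float(p)


# ---------------------------------------------------------------------------
# multiple-testing correction
# ---------------------------------------------------------------------------

def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    Monotone in the input order statistics and never below the raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InvalidConfigError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InvalidConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
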