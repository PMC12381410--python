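"""Covariate-adjusted single-mediator analysis with bootstrap CIs.

Tests whether a metacognition subdimension score (m) mediates the path
from its FC network strength (x, the *mean* of the predictive edges) to an
emotional-distress outcome (y), controlling for age, gender and head
motion. All three focal variables are z-scored on the full sample before
fitting, so the reported paths are standardized coefficients; paths come
from two OLS fits,

    m ~ x + C        ->  a
    y ~ x + m + C    ->  c' (direct), b

with total effect c from ``y ~ x + C``. The OLS identity c = c' + a*b is
exact when the same covariate set appears in every equation. Significance
of the indirect effect a*b is a percentile bootstrap confidence interval
over subject resamples, each refit end-to-end.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, EmptyMaskError, InvalidConfigError

logger = logging.getLogger(__name__)


def mean_strength(edge_row: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of a subject's Fisher-z values over the masked edges.

    The mediation independent variable uses the mean; the CPM prediction
    model uses the sum. ``mean * |mask| == summed_strength``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot compute mean strength over an empty mask")
    return float(np.asarray(edge_row, dtype=float)[mask].mean())


@dataclass
class MediationResult:
    """Standardized paths, effects, and the bootstrap CI for a*b."""

    a: float
    b: float
    c: float            # total effect
    c_prime: float      # direct effect
    indirect: float     # a * b
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n: int
    covariate_names: tuple[str, ...]

    @property
    def significant(self) -> bool:
        """True when the bootstrap CI for the indirect effect excludes 0."""
        return not (self.ci_low <= 0.0 <= self.ci_high)


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("cannot standardize a constant variable")
    return (v - v.mean()) / sd


def _solve_ols(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients via normal equations; raises on collinearity."""
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise DegenerateDataError("collinear design matrix in mediation fit")
    return np.linalg.solve(D.T @ D, D.T @ y)


def _paths(Z: np.ndarray) -> tuple[float, float, float, float]:
    """Standardized a, b, c, c' from the stacked [x, m, y, 1, C...] matrix."""
    x, m, y = Z[:, 0], Z[:, 1], Z[:, 2]
    rest = Z[:, 3:]  # intercept + covariates
    D_a = np.column_stack([x, rest])
    a = _solve_ols(D_a, m)[0]
    D_b = np.column_stack([x, m, rest])
    coef = _solve_ols(D_b, y)
    c_prime, b = coef[0], coef[1]
    c = _solve_ols(D_a, y)[0]
    return float(a), float(b), float(c), float(c_prime)


def _bootstrap_indirect(
    Z: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Indirect-effect estimates over ``n_boot`` subject resamples.

    Vectorized over resamples via batched normal equations; a degenerate
    resample (constant x, m or y) is redrawn and logged. Falls back to a
    per-resample loop if any batched system is singular.
    """
    n = Z.shape[0]
    idx = rng.integers(0, n, (n_boot, n))
    for _ in range(100):
        Zb = Z[idx]
        bad = (Zb[:, :, :3].std(axis=1) == 0).any(axis=1)
        if not bad.any():
            break
        logger.warning("redrew %d degenerate bootstrap resamples", int(bad.sum()))
        idx[bad] = rng.integers(0, n, (int(bad.sum()), n))
    x_b = Zb[:, :, 0:1]
    m_b = Zb[:, :, 1]
    y_b = Zb[:, :, 2]
    rest = Zb[:, :, 3:]  # intercept + covariates
    D_a = np.concatenate([x_b, rest], axis=2)
    D_b = np.concatenate([x_b, Zb[:, :, 1:2], rest], axis=2)
    try:
        coef_a = np.linalg.solve(
            np.einsum("bnp,bnq->bpq", D_a, D_a),
            np.einsum("bnp,bn->bp", D_a, m_b)[..., None],
        )[..., 0]
        coef_b = np.linalg.solve(
            np.einsum("bnp,bnq->bpq", D_b, D_b),
            np.einsum("bnp,bn->bp", D_b, y_b)[..., None],
        )[..., 0]
        return coef_a[:, 0] * coef_b[:, 1]
    except np.linalg.LinAlgError:
        logger.warning("singular batched bootstrap solve; using per-resample lstsq")
        out = np.empty(n_boot)
        for i in range(n_boot):
            a = np.linalg.lstsq(D_a[i], m_b[i], rcond=None)[0][0]
            b = np.linalg.lstsq(D_b[i], y_b[i], rcond=None)[0][1]
            out[i] = a * b
        return out


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: tuple[str, ...] = (),
    n_boot: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Single-mediator model with a seeded percentile bootstrap.

    Standardization happens once on the full sample; bootstrap resamples
    draw standardized rows with replacement and refit both equations. A
    degenerate resample (constant column) is redrawn and logged.
    """
    x, m, y = np.asarray(x, float), np.asarray(m, float), np.asarray(y, float)
    n = x.shape[0]
    if m.shape[0] != n or y.shape[0] != n:
        raise InvalidConfigError("x, m, y must have equal length")
    C = None
    k = 0
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        k = C.shape[1]
    if n <= k + 4:
        raise InvalidConfigError("too few subjects for the covariate count")
    cols = [_zscore(x), _zscore(m), _zscore(y), np.ones(n)]
    if C is not None:
        cols.extend(_zscore(C[:, j]) for j in range(C.shape[1]))
    Z = np.column_stack(cols)
    a, b, c, c_prime = _paths(Z)

    rng = np.random.default_rng(seed)
    boot = _bootstrap_indirect(Z, n_boot, rng)
    alpha = 1.0 - ci_level
    ci_low, ci_high = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    return MediationResult(
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        indirect=a * b,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        seed=seed,
        n=n,
        covariate_names=tuple(covariate_names),
    )
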