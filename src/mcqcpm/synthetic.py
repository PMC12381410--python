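"""Synthetic cohorts with known ground truth.

Emulates a resting-state FC + questionnaire study: ~180 young adults, an
N-node parcellation grouped into functional networks, per-subject FC
matrices with network block structure, behavioral scores linearly coupled
to a planted edge subset, covariate confounding (age, gender, head motion),
single-mediator paths to emotional-distress outcomes, and a second time
point whose change scores are partially driven by baseline network strength.

Generative model (all latent quantities standardized):

* each behavior ``b`` has a latent network factor ``g_b ~ N(0,1)``;
* behavior  ``y_b = alpha * g_b + sum_c gamma_c * c + delta * eps`` with
  ``alpha^2 + sum gamma^2 + delta^2 = 1`` (``alpha`` = latent share);
* a planted edge loads ``lambda = effect_r / alpha`` on ``g_b`` so that the
  population edge-behavior correlation is exactly ``effect_r`` (sign
  flipped for negatively planted edges);
* non-planted edges are network-block means plus independent noise;
* a mediated outcome is ``y = c' * g + b * m + sigma * eps`` with
  ``m`` the mediator behavior (whose latent share is then ``a``);
* time-2 outcome scores are ``t2 = t1 + coupling * s + noise`` where ``s``
  is the standardized mean planted-edge strength of the driver behavior.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import connectome as cx
from .connectome import AtlasDefinition, EdgeTable, POWER14_NETWORKS
from .errors import InvalidConfigError

#: Between-subject SD of a Fisher-z edge (typical resting-state value).
FC_EDGE_SD = 0.15
#: Population mean Fisher-z within / between networks.
FC_WITHIN_MEAN = 0.25
FC_BETWEEN_MEAN = 0.05

#: Affine maps from the standardized latent scale to questionnaire units.
SCALE_MAP: dict[str, tuple[float, float]] = {
    "MCQ30": (65.0, 12.0),
    "CC": (14.0, 3.0),
    "POS": (12.0, 3.5),
    "CSC": (16.0, 3.0),
    "NEG": (13.0, 3.5),
    "NC": (13.0, 3.0),
    "PA": (28.0, 6.0),
    "NA": (18.0, 5.0),
    "BAI": (8.0, 6.0),
    "BDI": (8.0, 6.0),
}

EMOTION_OUTCOMES = ("PA", "NA", "BAI", "BDI")


@dataclass
class CovariateModel:
    """Covariate distributions and their confound loadings on behaviors."""

    age_mean: float = 19.09
    age_sd: float = 0.84
    female_prop: float = 103 / 180
    motion_mean: float = 0.12
    motion_sd: float = 0.05
    #: standardized loading of each covariate on every behavioral score
    confounds: dict[str, float] = field(
        default_factory=lambda: {"age": 0.1, "gender": 0.1, "motion": 0.1}
    )


@dataclass
class MediationPathSpec:
    """Planted single-mediator path: network latent -> mediator -> outcome."""

    mediator: str
    outcome: str
    a: float
    b: float
    c_prime: float

    @property
    def indirect(self) -> float:
        return self.a * self.b


@dataclass
class LongitudinalSpec:
    """Second time point: t2 = t1 + coupling * (planted strength) + noise."""

    change_coupling: float = 0.0
    driver: str | None = None  # behavior whose planted network drives change
    interval_min_days: float = 365.0
    interval_max_days: float = 545.0
    followup_fraction: float = 159 / 180
    outcomes: tuple[str, ...] = EMOTION_OUTCOMES


@dataclass
class CohortConfig:
    """Everything needed to generate one cohort reproducibly."""

    n_subjects: int = 180
    n_nodes: int = 60
    n_networks: int = 14
    n_timepoints_ts: int = 0  # 0 = emit FC edges directly
    planted_pos_edges: Mapping[str, Sequence[int]] = field(default_factory=dict)
    planted_neg_edges: Mapping[str, Sequence[int]] = field(default_factory=dict)
    effect_r: float = 0.5
    behavior_names: tuple[str, ...] = ("MCQ30", "CC", "POS", "CSC", "NEG", "NC")
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    mediation_paths: tuple[MediationPathSpec, ...] = ()
    longitudinal: LongitudinalSpec | None = None
    noise_sd: float = 1.0  # residual SD on standardized scales (t2 coupling)
    latent_share: float = 0.8  # default alpha: behavior loading on its latent
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_subjects < 10:
            raise InvalidConfigError("n_subjects must be at least 10")
        if self.n_networks > self.n_nodes:
            raise InvalidConfigError("n_networks cannot exceed n_nodes")
        if not (0.0 <= self.effect_r < 1.0):
            raise InvalidConfigError("effect_r must lie in [0, 1)")
        if self.n_timepoints_ts < 0:
            raise InvalidConfigError("n_timepoints_ts must be nonnegative")
        e_max = cx.n_edges(self.n_nodes)
        seen: set[int] = set()
        for mapping, sign in ((self.planted_pos_edges, "+"), (self.planted_neg_edges, "-")):
            for name, idx in mapping.items():
                if name not in self.behavior_names:
                    raise InvalidConfigError(f"planted edges for unknown behavior {name!r}")
                idx = np.asarray(list(idx), dtype=int)
                if idx.size and (idx.min() < 0 or idx.max() >= e_max):
                    raise InvalidConfigError(
                        f"planted edge index out of range for {self.n_nodes} nodes"
                    )
                overlap = seen.intersection(idx.tolist())
                if overlap:
                    raise InvalidConfigError(
                        f"planted edge sets overlap (e.g. edge {sorted(overlap)[0]})"
                    )
                seen.update(idx.tolist())
        gamma2 = sum(v * v for v in self.covariate_model.confounds.values())
        for name in self.behavior_names:
            alpha = self._alpha(name)
            if alpha ** 2 + gamma2 > 1.0 + 1e-12:
                raise InvalidConfigError(
                    f"latent share and confound loadings of {name!r} exceed unit variance"
                )
            planted = name in self.planted_pos_edges or name in self.planted_neg_edges
            if planted and self.effect_r > 0 and self.effect_r > alpha:
                raise InvalidConfigError(
                    f"effect_r={self.effect_r} needs edge loading > 1 for behavior "
                    f"{name!r} (latent share {alpha})"
                )
        outcomes_seen = set()
        for path in self.mediation_paths:
            if path.mediator not in self.behavior_names:
                raise InvalidConfigError(f"mediator {path.mediator!r} not a behavior")
            if path.outcome in outcomes_seen:
                raise InvalidConfigError(f"outcome {path.outcome!r} mediated twice")
            outcomes_seen.add(path.outcome)
            resid = 1.0 - (path.b ** 2 + path.c_prime ** 2 + 2 * path.a * path.b * path.c_prime)
            if resid <= 0:
                raise InvalidConfigError(
                    f"mediation path to {path.outcome!r} implies nonpositive residual variance"
                )
        if self.longitudinal and self.longitudinal.change_coupling != 0.0:
            driver = self.longitudinal.driver or self._default_driver()
            if driver is None:
                raise InvalidConfigError(
                    "longitudinal coupling requires a behavior with planted edges"
                )

    def _alpha(self, behavior: str) -> float:
        for path in self.mediation_paths:
            if path.mediator == behavior:
                return path.a
        return self.latent_share

    def _default_driver(self) -> str | None:
        for name in self.behavior_names:
            if name in self.planted_pos_edges or name in self.planted_neg_edges:
                return name
        return None


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery checks downstream."""

    planted_pos: dict[str, np.ndarray]
    planted_neg: dict[str, np.ndarray]
    lambdas: dict[str, float]
    alphas: dict[str, float]
    latents: dict[str, np.ndarray]
    true_indirect: dict[str, float]  # keyed "mediator->outcome"
    driver: str | None
    driver_strength: np.ndarray | None  # standardized mean planted strength
    change_coupling: float
    seed: int

    def mask(self, behavior: str, n_edges_total: int, sign: str = "pos") -> np.ndarray:
        source = self.planted_pos if sign == "pos" else self.planted_neg
        mask = np.zeros(n_edges_total, dtype=bool)
        mask[source.get(behavior, np.empty(0, dtype=int))] = True
        return mask

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_pos": {k: v.tolist() for k, v in self.planted_pos.items()},
            "planted_neg": {k: v.tolist() for k, v in self.planted_neg.items()},
            "lambdas": self.lambdas,
            "alphas": self.alphas,
            "true_indirect": self.true_indirect,
            "driver": self.driver,
            "change_coupling": self.change_coupling,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class CohortData:
    """Bundle returned by :func:`generate_cohort`."""

    atlas: AtlasDefinition
    behavior: pd.DataFrame
    ground_truth: GroundTruth
    edges: EdgeTable | None = None
    timeseries: list[cx.RoiTimeSeries] | None = None


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def generate_atlas(n_nodes: int, n_networks: int, seed: int = 0) -> AtlasDefinition:
    """Random node -> network assignment with pseudo-MNI coordinates.

    Every network receives at least one node. When ``n_networks == 14`` the
    canonical Power-264 network names are used; otherwise labels are
    ``NET01`` .. ``NETxx``.
    """
    if n_networks > n_nodes:
        raise InvalidConfigError("n_networks cannot exceed n_nodes")
    if n_networks < 1:
        raise InvalidConfigError("need at least one network")
    rng = np.random.default_rng(seed)
    if n_networks == 14:
        labels = list(POWER14_NETWORKS)
    else:
        labels = [f"NET{i + 1:02d}" for i in range(n_networks)]
    assignment = np.concatenate(
        [np.arange(n_networks), rng.integers(0, n_networks, n_nodes - n_networks)]
    )
    assignment = rng.permutation(assignment)
    centers = rng.uniform([-60.0, -90.0, -50.0], [60.0, 60.0, 70.0], size=(n_networks, 3))
    coords = centers[assignment] + rng.normal(0.0, 12.0, size=(n_nodes, 3))
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(n_nodes),
            "x": np.round(coords[:, 0], 1),
            "y": np.round(coords[:, 1], 1),
            "z": np.round(coords[:, 2], 1),
            "network": [labels[a] for a in assignment],
        }
    )
    return AtlasDefinition(nodes)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _scale(name: str) -> tuple[float, float]:
    return SCALE_MAP.get(name, (0.0, 1.0))


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate one cohort; identical config + seed is bit-identical."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, n_nodes = config.n_subjects, config.n_nodes
    e_total = cx.n_edges(n_nodes)
    atlas = generate_atlas(n_nodes, config.n_networks, seed=config.seed)

    # --- covariates -----------------------------------------------------
    cov = config.covariate_model
    age = rng.normal(cov.age_mean, cov.age_sd, n)
    gender = (rng.random(n) < cov.female_prop).astype(float)  # 1 = female
    motion = np.abs(rng.normal(cov.motion_mean, cov.motion_sd, n))
    raw_cov = {"age": age, "gender": gender, "motion": motion}
    zc = {k: _zscore(v) for k, v in raw_cov.items()}
    gamma = cov.confounds
    gamma2 = sum(v * v for v in gamma.values())
    confound_term = sum(gamma[k] * zc[k] for k in gamma) if gamma else np.zeros(n)

    # --- behaviors on the standardized scale ----------------------------
    latents: dict[str, np.ndarray] = {}
    behavior_std: dict[str, np.ndarray] = {}
    alphas: dict[str, float] = {}
    lambdas: dict[str, float] = {}
    for name in config.behavior_names:
        g = rng.standard_normal(n)
        alpha = config._alpha(name)
        delta = np.sqrt(max(1.0 - alpha ** 2 - gamma2, 0.0))
        y = alpha * g + confound_term + delta * rng.standard_normal(n)
        latents[name] = g
        behavior_std[name] = y
        alphas[name] = alpha
        lambdas[name] = (config.effect_r / alpha) if config.effect_r > 0 else 0.0

    # --- edges ----------------------------------------------------------
    pairs = cx.edge_pairs(n_nodes)
    net_of = atlas.labels
    within = net_of[pairs[:, 0]] == net_of[pairs[:, 1]]
    mu = np.where(within, FC_WITHIN_MEAN, FC_BETWEEN_MEAN)
    std_part = rng.standard_normal((n, e_total))
    planted_pos = {
        k: np.asarray(sorted(v), dtype=int) for k, v in config.planted_pos_edges.items()
    }
    planted_neg = {
        k: np.asarray(sorted(v), dtype=int) for k, v in config.planted_neg_edges.items()
    }
    for mapping, sign in ((planted_pos, 1.0), (planted_neg, -1.0)):
        for name, idx in mapping.items():
            lam = sign * lambdas[name]
            if lam == 0.0 or idx.size == 0:
                continue
            g = latents[name]
            std_part[:, idx] = (
                lam * g[:, None]
                + np.sqrt(1.0 - lam ** 2) * rng.standard_normal((n, idx.size))
            )
    edge_values = mu[None, :] + FC_EDGE_SD * std_part
    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    edges = EdgeTable(subject_ids, edge_values, n_nodes)

    # --- emotional-distress outcomes ------------------------------------
    mediated = {p.outcome: p for p in config.mediation_paths}
    outcome_std: dict[str, np.ndarray] = {}
    true_indirect: dict[str, float] = {}
    for out in EMOTION_OUTCOMES:
        if out in mediated:
            p = mediated[out]
            g = latents[p.mediator]
            m = behavior_std[p.mediator]
            sigma2 = 1.0 - (p.b ** 2 + p.c_prime ** 2 + 2 * p.a * p.b * p.c_prime)
            y = p.c_prime * g + p.b * m + np.sqrt(max(sigma2, 0.0)) * rng.standard_normal(n)
            true_indirect[f"{p.mediator}->{out}"] = p.indirect
        else:
            delta = np.sqrt(max(1.0 - gamma2, 0.0))
            y = confound_term + delta * rng.standard_normal(n)
        outcome_std[out] = y

    # --- behavioral table (affine-mapped to questionnaire units) --------
    table: dict[str, np.ndarray] = {}
    for name in config.behavior_names:
        m, s = _scale(name)
        table[name] = m + s * behavior_std[name]
    for out in EMOTION_OUTCOMES:
        m, s = _scale(out)
        table[out] = m + s * outcome_std[out]
    table.update(raw_cov)
    behavior_df = pd.DataFrame(table, index=pd.Index(subject_ids, name="subject_id"))
    behavior_df.reset_index(inplace=True)

    # --- second time point ----------------------------------------------
    driver = None
    driver_strength = None
    coupling = 0.0
    if config.longitudinal is not None:
        spec = config.longitudinal
        coupling = spec.change_coupling
        driver = spec.driver or config._default_driver()
        if coupling != 0.0 and driver is not None:
            idx = np.concatenate(
                [
                    planted_pos.get(driver, np.empty(0, dtype=int)),
                    planted_neg.get(driver, np.empty(0, dtype=int)),
                ]
            )
            driver_strength = _zscore(edge_values[:, idx].mean(axis=1))
        else:
            driver_strength = np.zeros(n)
        n_follow = int(round(spec.followup_fraction * n))
        followed = np.zeros(n, dtype=bool)
        followed[rng.choice(n, size=n_follow, replace=False)] = True
        interval = rng.uniform(spec.interval_min_days, spec.interval_max_days, n)
        for out in spec.outcomes:
            m, s = _scale(out)
            t2_std = (
                outcome_std[out]
                + coupling * driver_strength
                + config.noise_sd * rng.standard_normal(n)
            )
            col = np.where(followed, m + s * t2_std, np.nan)
            behavior_df[f"{out}_t2"] = col
        behavior_df["interval_days"] = np.where(followed, interval, np.nan)

    truth = GroundTruth(
        planted_pos=planted_pos,
        planted_neg=planted_neg,
        lambdas=lambdas,
        alphas=alphas,
        latents=latents,
        true_indirect=true_indirect,
        driver=driver,
        driver_strength=driver_strength,
        change_coupling=coupling,
        seed=config.seed,
    )

    if config.n_timepoints_ts > 0:
        ts = _timeseries_from_edges(edges, config.n_timepoints_ts, rng)
        return CohortData(atlas=atlas, behavior=behavior_df, ground_truth=truth,
                          edges=None, timeseries=ts)
    return CohortData(atlas=atlas, behavior=behavior_df, ground_truth=truth, edges=edges)


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _timeseries_from_edges(
    edges: EdgeTable, n_timepoints: int, rng: np.random.Generator
) -> list[cx.RoiTimeSeries]:
    """Sample per-subject multivariate-normal BOLD series whose population
    correlation matrix is tanh of the subject's Fisher-z matrix (nearest
    positive-definite repair by eigenvalue clipping)."""
    out = []
    n_nodes = edges.n_nodes
    for sid, row in zip(edges.subject_ids, edges.values):
        r = np.tanh(cx.devectorize(row, n_nodes, sid).z)
        np.fill_diagonal(r, 1.0)
        w, v = np.linalg.eigh(r)
        w = np.clip(w, 1e-6, None)
        r_pd = (v * w) @ v.T
        d = np.sqrt(np.diag(r_pd))
        r_pd = r_pd / np.outer(d, d)
        chol = np.linalg.cholesky(r_pd)
        series = rng.standard_normal((n_timepoints, n_nodes)) @ chol.T
        out.append(cx.RoiTimeSeries(sid, series))
    return out


# ---------------------------------------------------------------------------
# convenience constructors
# ---------------------------------------------------------------------------

def default_planted_config(
    seed: int = 0,
    n_subjects: int = 180,
    n_nodes: int = 60,
    n_planted: int = 50,
    effect_r: float = 0.5,
    behavior: str = "CSC",
    **kwargs,
) -> CohortConfig:
    """The default planted cohort: one behavior coupled to ``n_planted``
    positively planted edges at population correlation ``effect_r``.

    The planted edge indices are drawn from an independent stream so they
    do not perturb the cohort's own random draws.
    """
    e_total = cx.n_edges(n_nodes)
    design_rng = np.random.default_rng([seed, 7919])
    planted = np.sort(design_rng.choice(e_total, size=n_planted, replace=False))
    kwargs.setdefault("n_networks", min(14, n_nodes))
    return CohortConfig(
        n_subjects=n_subjects,
        n_nodes=n_nodes,
        planted_pos_edges={behavior: planted},
        effect_r=effect_r,
        seed=seed,
        **kwargs,
    )


def null_config(seed: int = 0, n_subjects: int = 120, n_nodes: int = 60) -> CohortConfig:
    """A cohort with no edge-behavior coupling (effect_r = 0)."""
    return CohortConfig(
        n_subjects=n_subjects,
        n_nodes=n_nodes,
        n_networks=min(14, n_nodes),
        effect_r=0.0,
        seed=seed,
    )


def simulate_mediation_triple(
    a: float, b: float, c_prime: float, n_subjects: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directly simulate (x, m, y) with the stated standardized paths.

    ``m = a x + sqrt(1-a^2) e`` and ``y = c' x + b m + sigma e`` with sigma
    chosen so all three variables have unit population variance.
    """
    resid = 1.0 - (b ** 2 + c_prime ** 2 + 2 * a * b * c_prime)
    if resid <= 0:
        raise InvalidConfigError("path coefficients imply nonpositive residual variance")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_subjects)
    m = a * x + np.sqrt(1.0 - a ** 2) * rng.standard_normal(n_subjects)
    y = c_prime * x + b * m + np.sqrt(resid) * rng.standard_normal(n_subjects)
    return x, m, y


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(data: CohortData, outdir: str | Path) -> None:
    """Write atlas TSV, behavioral CSV, edge CSV (or time-series text files)
    and ground-truth JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.atlas.to_tsv(outdir / "atlas.tsv")
    data.behavior.to_csv(outdir / "behavior.csv", index=False)
    data.ground_truth.to_json(outdir / "ground_truth.json")
    if data.edges is not None:
        data.edges.to_csv(outdir / "edges.csv")
    if data.timeseries is not None:
        ts_dir = outdir / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        for ts in data.timeseries:
            np.savetxt(ts_dir / f"{ts.subject_id}.txt", ts.values, fmt="%.6f")
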