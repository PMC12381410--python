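"""End-to-end orchestration: simulate (or load) -> CPM per dimension ->
FDR -> network anatomy -> mediation -> longitudinal change prediction.

Every random draw is traceable to the run seed; identical config + seed
reproduces every number in the bundle bit-for-bit. Results are serialized
as JSON + CSV for diffability.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import anatomy as _anatomy
from . import cpm as _cpm
from . import longitudinal as _longitudinal
from . import mediation as _mediation
from . import synthetic as _synthetic
from .connectome import AtlasDefinition, EdgeTable
from .errors import InvalidConfigError, StageError
from .synthetic import CohortConfig, CohortData, EMOTION_OUTCOMES

logger = logging.getLogger(__name__)

DIMENSIONS = ("MCQ30", "CC", "POS", "CSC", "NEG", "NC")
#: FDR family: the five subdimensions; the total score is reported uncorrected.
FDR_FAMILY = ("CC", "POS", "CSC", "NEG", "NC")
TAILS = ("positive", "negative")


@dataclass
class RunConfig:
    """Configuration of one reproducible end-to-end run."""

    cohort: CohortConfig | None = None
    edges_path: str | None = None      # alternatives to simulation
    behavior_path: str | None = None
    atlas_path: str | None = None
    dimensions: tuple[str, ...] = DIMENSIONS
    tails: tuple[str, ...] = TAILS
    covariates: tuple[str, ...] = ("age", "gender", "motion")
    p_threshold: float = 0.01
    cv: str = "loo"
    k: int = 10
    repeats: int = 100
    n_perm: int = 1000
    n_boot: int = 5000
    alpha: float = 0.05
    fdr_family: tuple[str, ...] = FDR_FAMILY
    outcomes: tuple[str, ...] = EMOTION_OUTCOMES
    run_mediation: bool = True
    run_longitudinal: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.cohort is not None:
            d["cohort"]["planted_pos_edges"] = {
                k: list(map(int, v)) for k, v in self.cohort.planted_pos_edges.items()
            }
            d["cohort"]["planted_neg_edges"] = {
                k: list(map(int, v)) for k, v in self.cohort.planted_neg_edges.items()
            }
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohort = raw.pop("cohort", None)
        if cohort is not None:
            cov = cohort.pop("covariate_model", None)
            med = cohort.pop("mediation_paths", None)
            lon = cohort.pop("longitudinal", None)
            cc = CohortConfig(**cohort)
            if cov:
                cc.covariate_model = _synthetic.CovariateModel(**cov)
            if med:
                cc.mediation_paths = tuple(
                    _synthetic.MediationPathSpec(**m) for m in med
                )
            if lon:
                cc.longitudinal = _synthetic.LongitudinalSpec(**lon)
            raw["cohort"] = cc
        for key in ("dimensions", "tails", "covariates", "fdr_family", "outcomes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def demo_config(seed: int = 0, n_perm: int = 200, n_subjects: int = 120) -> RunConfig:
    """Default demonstration run: 60-node simulated cohort with a planted
    positive CSC network, a CSC -> BAI mediation path and longitudinal
    coupling of emotional change to the planted network."""
    cohort = _synthetic.default_planted_config(
        seed=seed,
        n_subjects=n_subjects,
        n_nodes=60,
        n_planted=50,
        effect_r=0.5,
        behavior="CSC",
        mediation_paths=(
            _synthetic.MediationPathSpec("CSC", "BAI", a=0.5, b=0.5, c_prime=0.0),
        ),
        longitudinal=_synthetic.LongitudinalSpec(change_coupling=0.4, driver="CSC"),
    )
    return RunConfig(cohort=cohort, n_perm=n_perm, seed=seed)


def _stage_seed(seed: int, offset: int) -> int:
    """Deterministic per-stage seed, kept below 2**31."""
    return (seed * 1_000_003 + offset) % (2 ** 31)


@dataclass
class RunBundle:
    """In-memory result bundle; ``write`` serializes it to disk."""

    summary: pd.DataFrame
    manifest: dict
    cohort: CohortData | None
    atlas: AtlasDefinition
    cpm_results: dict = field(default_factory=dict)       # (dim, tail) -> CpmResult
    anatomy: dict = field(default_factory=dict)           # (dim, tail) -> dict
    coincidence: pd.DataFrame | None = None
    mediation: pd.DataFrame | None = None
    longitudinal: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(outdir / "cpm_summary.csv", index=False)
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True)
        )
        for (dim, tail), res in self.cpm_results.items():
            np.savetxt(
                outdir / f"mask_{dim}_{tail}.csv",
                np.column_stack(
                    [res.full_sample_mask.astype(int), res.consensus_mask.astype(int)]
                ),
                fmt="%d",
                delimiter=",",
                header="full_sample,consensus",
                comments="",
            )
        for (dim, tail), rep in self.anatomy.items():
            rep["counts"].counts.to_csv(outdir / f"network_counts_{dim}_{tail}.csv")
            rep["degree"].table.to_csv(
                outdir / f"node_degree_{dim}_{tail}.tsv", sep="\t", index=False
            )
        if self.coincidence is not None:
            self.coincidence.to_csv(outdir / "coincidence.csv", index=False)
        if self.mediation is not None:
            self.mediation.to_csv(outdir / "mediation.csv", index=False)
        if self.longitudinal is not None:
            self.longitudinal.to_csv(outdir / "longitudinal.csv", index=False)


def _load_inputs(config: RunConfig) -> tuple[EdgeTable, pd.DataFrame, AtlasDefinition, CohortData | None]:
    if config.cohort is not None:
        cohort = _synthetic.generate_cohort(config.cohort)
        if cohort.edges is None:
            raise InvalidConfigError(
                "pipeline needs direct FC output (n_timepoints_ts = 0); "
                "compute FC from time series first"
            )
        return cohort.edges, cohort.behavior, cohort.atlas, cohort
    if not (config.edges_path and config.behavior_path and config.atlas_path):
        raise InvalidConfigError("provide either a cohort block or all input paths")
    edges = EdgeTable.from_csv(config.edges_path)
    behavior = pd.read_csv(config.behavior_path)
    atlas = AtlasDefinition.from_tsv(config.atlas_path)
    return edges, behavior, atlas, None


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunBundle:
    """Execute the full analysis; returns (and optionally writes) the bundle.

    Stages: load/simulate, per-dimension CPM (both tails) with permutation
    significance, FDR over the subdimension family per tail, anatomy of
    significant networks, coincidence between them, mediation to the
    emotional-distress outcomes, and longitudinal change prediction.
    Any stage failure raises :class:`StageError` naming the stage; output
    written before the failure is retained.
    """
    t_start = time.time()
    stage = "load"
    try:
        edges, behavior, atlas, cohort = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage '{stage}' failed: {exc}") from exc

    missing = [c for c in config.covariates if c not in behavior.columns]
    if missing:
        raise StageError(f"stage 'load' failed: covariate columns missing: {missing}")
    C = behavior[list(config.covariates)].to_numpy(dtype=float)

    bundle = RunBundle(
        summary=pd.DataFrame(),
        manifest={},
        cohort=cohort,
        atlas=atlas,
    )

    # --- CPM per dimension and tail -------------------------------------
    stage = "cpm"
    rows = []
    try:
        for d_i, dim in enumerate(config.dimensions):
            if dim not in behavior.columns:
                raise InvalidConfigError(f"dimension column {dim!r} missing")
            y = behavior[dim].to_numpy(dtype=float)
            for t_i, tail in enumerate(config.tails):
                if config.cv == "loo":
                    res = _cpm.cpm_loocv(
                        edges, y, C, config.p_threshold, tail
                    )
                else:
                    res = _cpm.cpm_kfold(
                        edges, y, C, config.p_threshold, tail,
                        k=config.k, repeats=config.repeats,
                        seed=_stage_seed(config.seed, 100 + 10 * d_i + t_i),
                    )
                res.p_perm = _cpm.permutation_test(
                    edges, y, C, config.p_threshold, tail,
                    n_perm=config.n_perm,
                    seed=_stage_seed(config.seed, 500 + 10 * d_i + t_i),
                    cv=config.cv, k=config.k, repeats=config.repeats,
                )
                bundle.cpm_results[(dim, tail)] = res
                rows.append(
                    {
                        "dimension": dim,
                        "tail": tail,
                        "r": res.r,
                        "p_perm": res.p_perm,
                        "n_selected_full": res.n_selected_full,
                        "n_consensus": int(res.consensus_mask.sum()),
                        "n_missing_folds": res.n_missing,
                        "flagged_unreliable": res.flagged_unreliable,
                    }
                )
        summary = pd.DataFrame(rows)
        # FDR across the subdimension family, within each tail; dimensions
        # whose pipeline built no model (NaN p) stay uncorrected
        summary["q"] = np.nan
        for tail in config.tails:
            fam = summary.index[
                (summary["tail"] == tail)
                & summary["dimension"].isin(config.fdr_family)
                & summary["p_perm"].notna()
            ]
            if len(fam):
                summary.loc[fam, "q"] = _cpm.fdr_bh(summary.loc[fam, "p_perm"].to_numpy())
        bundle.summary = summary
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage '{stage}' failed: {exc}") from exc

    significant = [
        (row["dimension"], row["tail"])
        for _, row in bundle.summary.iterrows()
        if np.isfinite(row["p_perm"]) and row["p_perm"] < config.alpha
    ]

    # --- anatomy ---------------------------------------------------------
    stage = "anatomy"
    try:
        for dim, tail in significant:
            res = bundle.cpm_results[(dim, tail)]
            bundle.anatomy[(dim, tail)] = {
                "counts": _anatomy.count_by_network(res.full_sample_mask, atlas),
                "degree": _anatomy.node_degree(res.full_sample_mask, atlas),
            }
        pairs = []
        for i in range(len(significant)):
            for j in range(i + 1, len(significant)):
                (d1, t1), (d2, t2) = significant[i], significant[j]
                shared = _anatomy.coincidence(
                    bundle.cpm_results[(d1, t1)].full_sample_mask,
                    bundle.cpm_results[(d2, t2)].full_sample_mask,
                )
                pairs.append(
                    {
                        "network_a": f"{d1}_{t1}",
                        "network_b": f"{d2}_{t2}",
                        "n_shared": int(shared.sum()),
                        "shared_edges": ";".join(
                            f"{i_}-{j_}"
                            for i_, j_ in _anatomy._mask_pairs(shared, atlas.n_nodes)
                        ),
                    }
                )
        bundle.coincidence = pd.DataFrame(
            pairs, columns=["network_a", "network_b", "n_shared", "shared_edges"]
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage '{stage}' failed: {exc}") from exc

    # --- mediation -------------------------------------------------------
    stage = "mediation"
    try:
        if config.run_mediation:
            med_rows = []
            X = edges.values
            for m_i, (dim, tail) in enumerate(significant):
                res = bundle.cpm_results[(dim, tail)]
                if not res.full_sample_mask.any():
                    continue
                x = X[:, res.full_sample_mask].mean(axis=1)
                m = behavior[dim].to_numpy(dtype=float)
                for o_i, outcome in enumerate(config.outcomes):
                    if outcome not in behavior.columns:
                        continue
                    med = _mediation.mediate(
                        x, m, behavior[outcome].to_numpy(dtype=float), C,
                        covariate_names=config.covariates,
                        n_boot=config.n_boot,
                        seed=_stage_seed(config.seed, 2000 + 20 * m_i + o_i),
                    )
                    med_rows.append(
                        {
                            "pathway": f"FC-{dim}-{outcome}",
                            "tail": tail,
                            "total": med.c,
                            "direct": med.c_prime,
                            "indirect": med.indirect,
                            "ci_low": med.ci_low,
                            "ci_high": med.ci_high,
                            "significant": med.significant,
                        }
                    )
            bundle.mediation = pd.DataFrame(
                med_rows,
                columns=[
                    "pathway", "tail", "total", "direct", "indirect",
                    "ci_low", "ci_high", "significant",
                ],
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage '{stage}' failed: {exc}") from exc

    # --- longitudinal ----------------------------------------------------
    stage = "longitudinal"
    try:
        has_t2 = any(f"{o}_t2" in behavior.columns for o in config.outcomes)
        if config.run_longitudinal and has_t2 and significant:
            changes = _longitudinal.change_table(behavior, tuple(config.outcomes))
            retained = behavior["subject_id"].isin(changes["subject_id"]).to_numpy()
            lon_rows = []
            for l_i, (dim, tail) in enumerate(significant):
                res = bundle.cpm_results[(dim, tail)]
                if not res.full_sample_mask.any():
                    continue
                for o_i, outcome in enumerate(config.outcomes):
                    cp = _longitudinal.predict_change(
                        edges.values[retained],
                        res.full_sample_mask,
                        changes[f"{outcome}_change"].to_numpy(),
                        C[retained],
                        p_threshold=config.p_threshold,
                        tail=tail,
                        cv=config.cv,
                        k=config.k,
                        repeats=1 if config.cv == "loo" else config.repeats,
                        n_perm=config.n_perm,
                        seed=_stage_seed(config.seed, 4000 + 20 * l_i + o_i),
                    )
                    lon_rows.append(
                        {
                            "prior_network": f"{dim}_{tail}",
                            "outcome": outcome,
                            "r": cp.r,
                            "p_perm": cp.p_perm,
                            "n_predictive_edges": int(cp.full_sample_mask_full.sum()),
                            "n_subjects": int(retained.sum()),
                        }
                    )
            bundle.longitudinal = pd.DataFrame(
                lon_rows,
                columns=[
                    "prior_network", "outcome", "r", "p_perm",
                    "n_predictive_edges", "n_subjects",
                ],
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage '{stage}' failed: {exc}") from exc

    bundle.manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": int(edges.n_subjects),
        "n_nodes": int(edges.n_nodes),
        "n_edges": int(edges.n_edges),
        "stages": ["load", "cpm", "anatomy", "mediation", "longitudinal"],
        "significant_networks": [f"{d}_{t}" for d, t in significant],
    }
    logger.info("pipeline finished in %.1f s", time.time() - t_start)
    if outdir is not None:
        bundle.write(outdir)
    return bundle
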