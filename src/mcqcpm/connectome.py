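"""Functional-connectome construction and bookkeeping.

Turns ROI mean time series into motion-scrubbed, Fisher-z functional
connectivity (FC) matrices and vectorized edge tables, and manages the
atlas / network-label bookkeeping that every anatomical summary relies on.

Conventions fixed across the package:

* FC edge = Fisher z of the Pearson correlation between two ROIs' mean
  BOLD series; the matrix diagonal is undefined and stored as 0.
* Edge ordering = row-major upper triangle, 0-based node ids, i < j.
  Edge k of an N-node parcellation corresponds to ``edge_pairs(N)[k]``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidConfigError, SubjectExcludedError

#: The 14 canonical functional networks of the Power-264 parcellation.
POWER14_NETWORKS: tuple[str, ...] = (
    "SMH", "SMM", "CON", "AUD", "DMN", "MRN", "VIS",
    "FPN", "SN", "SUB", "VAN", "CN", "DAN", "UNC",
)

#: |r| is capped here before atanh so degenerate correlations stay finite.
R_CAP = 1.0 - 1e-7

#: Symmetry tolerance when vectorizing a connectivity matrix.
SYMMETRY_ATOL = 1e-8


def n_edges(n_nodes: int) -> int:
    """Number of unordered node pairs: N(N-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def edge_pairs(n_nodes: int) -> np.ndarray:
    """(E, 2) array of 0-based node pairs in row-major upper-triangle order."""
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu)


@dataclass
class AtlasDefinition:
    """Node table: id, pseudo-MNI coordinates (mm) and network label."""

    nodes: pd.DataFrame  # columns: node_id, x, y, z, network

    def __post_init__(self) -> None:
        required = {"node_id", "x", "y", "z", "network"}
        missing = required - set(self.nodes.columns)
        if missing:
            raise InvalidConfigError(f"atlas table missing columns: {sorted(missing)}")
        ids = self.nodes["node_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise InvalidConfigError("atlas node ids must be contiguous from 0")
        if self.nodes["network"].isna().any() or (self.nodes["network"] == "").any():
            raise InvalidConfigError("every atlas node must carry a network label")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def networks(self) -> list[str]:
        """Unique network labels in first-appearance order."""
        return list(dict.fromkeys(self.nodes["network"]))

    @property
    def labels(self) -> np.ndarray:
        return self.nodes["network"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.nodes.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AtlasDefinition":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class RoiTimeSeries:
    """One subject's ROI mean BOLD series, frames (rows) x ROIs (columns)."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidConfigError("time series must be a 2-D (time x ROI) array")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class FdTrace:
    """Per-frame framewise displacement (mm), aligned to the time series."""

    subject_id: str
    fd: np.ndarray

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float).ravel()
        if (self.fd < 0).any():
            raise InvalidConfigError("framewise displacement must be nonnegative")


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N Fisher-z FC matrix; the diagonal is stored as 0."""

    subject_id: str
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise InvalidConfigError("connectivity matrix must be square")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class EdgeTable:
    """Subjects x edges matrix of Fisher-z values plus the edge index map.

    Rows follow ``subject_ids``; columns follow ``edge_pairs(n_nodes)``.
    """

    subject_ids: list[str]
    values: np.ndarray
    n_nodes: int
    _pairs: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidConfigError("edge table must be 2-D (subjects x edges)")
        if self.values.shape[0] != len(self.subject_ids):
            raise InvalidConfigError("row count must match number of subject ids")
        if self.values.shape[1] != n_edges(self.n_nodes):
            raise InvalidConfigError(
                f"edge count {self.values.shape[1]} does not equal "
                f"N(N-1)/2 = {n_edges(self.n_nodes)} for N = {self.n_nodes}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    @property
    def pairs(self) -> np.ndarray:
        if self._pairs is None:
            self._pairs = edge_pairs(self.n_nodes)
        return self._pairs

    def row(self, subject_id: str) -> np.ndarray:
        return self.values[self.subject_ids.index(subject_id)]

    def to_csv(self, path: str | Path) -> None:
        cols = [f"e{i}_{j}" for i, j in self.pairs]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "subject_id", self.subject_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EdgeTable":
        df = pd.read_csv(path)
        ids = df["subject_id"].astype(str).tolist()
        values = df.drop(columns="subject_id").to_numpy(dtype=float)
        # invert E = N(N-1)/2
        n = int(round((1 + np.sqrt(1 + 8 * values.shape[1])) / 2))
        return cls(subject_ids=ids, values=values, n_nodes=n)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def scrub(
    ts: RoiTimeSeries,
    fd: FdTrace,
    threshold: float = 0.5,
    min_frames: int = 30,
) -> tuple[RoiTimeSeries, int]:
    """Remove motion-contaminated frames (FD strictly above ``threshold``).

    Returns the scrubbed series and the number of frames removed. Frame
    order is preserved; only flagged frames are dropped (no adjacent-frame
    augmentation). Raises :class:`SubjectExcludedError` when fewer than
    ``min_frames`` frames survive.
    """
    if threshold <= 0:
        raise InvalidConfigError("scrubbing threshold must be positive")
    if len(fd.fd) != ts.n_frames:
        raise InvalidConfigError(
            f"FD trace length {len(fd.fd)} does not match frame count {ts.n_frames}"
        )
    keep = fd.fd <= threshold
    n_removed = int((~keep).sum())
    if keep.sum() < min_frames:
        raise SubjectExcludedError(
            f"subject {ts.subject_id}: only {int(keep.sum())} frames survive "
            f"scrubbing at FD > {threshold} mm (minimum {min_frames})"
        )
    return RoiTimeSeries(ts.subject_id, ts.values[keep]), n_removed


def compute_fc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation of each ROI pair, Fisher z-transformed.

    |r| is capped at 1 - 1e-7 before atanh (with a warning) so duplicated
    or perfectly anticorrelated series yield large finite edges instead of
    +/-inf. Constant ROI series are an error naming the offending ROIs.
    """
    if ts.n_frames < 3:
        raise DegenerateDataError("need at least 3 frames to estimate correlations")
    sd = ts.values.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise DegenerateDataError(
            f"subject {ts.subject_id}: constant time series for ROI(s) "
            f"{constant.tolist()}"
        )
    r = np.corrcoef(ts.values, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    if (np.abs(r[off]) > R_CAP).any():
        warnings.warn(
            f"subject {ts.subject_id}: |r| >= 1 between distinct ROIs; "
            f"capped at {R_CAP}",
            RuntimeWarning,
            stacklevel=2,
        )
    r = np.clip(r, -R_CAP, R_CAP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # enforce exact symmetry against rounding
    return ConnectivityMatrix(ts.subject_id, z)


def vectorize(cm: ConnectivityMatrix, atol: float = SYMMETRY_ATOL) -> np.ndarray:
    """Upper-triangle (row-major, i < j) vector of a symmetric FC matrix."""
    asym = np.abs(cm.z - cm.z.T).max()
    if asym > atol:
        raise InvalidConfigError(
            f"matrix asymmetry {asym:.3e} exceeds tolerance {atol:.0e}"
        )
    iu = np.triu_indices(cm.n_nodes, k=1)
    return cm.z[iu].copy()


def devectorize(row: np.ndarray, n_nodes: int, subject_id: str = "") -> ConnectivityMatrix:
    """Rebuild the symmetric matrix from an edge vector (diagonal set to 0)."""
    row = np.asarray(row, dtype=float).ravel()
    if row.size != n_edges(n_nodes):
        raise InvalidConfigError(
            f"edge vector length {row.size} does not match N(N-1)/2 for N={n_nodes}"
        )
    z = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    z[iu] = row
    z = z + z.T
    return ConnectivityMatrix(subject_id, z)


def edge_table_from_matrices(cms: Sequence[ConnectivityMatrix]) -> EdgeTable:
    """Stack per-subject connectivity matrices into one EdgeTable."""
    if not cms:
        raise InvalidConfigError("no connectivity matrices supplied")
    n = cms[0].n_nodes
    if any(cm.n_nodes != n for cm in cms):
        raise InvalidConfigError("all matrices must share the same node count")
    values = np.vstack([vectorize(cm) for cm in cms])
    return EdgeTable([cm.subject_id for cm in cms], values, n)


# ---------------------------------------------------------------------------
# plain-text readers
# ---------------------------------------------------------------------------

def read_time_series(path: str | Path, subject_id: str | None = None) -> RoiTimeSeries:
    """Read a whitespace- or comma-delimited time x ROI matrix.

    A single non-numeric first row is treated as a header and skipped.
    """
    path = Path(path)
    try:
        values = np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",")
    except ValueError:
        values = np.loadtxt(
            path, delimiter=None if _is_whitespace(path) else ",", skiprows=1
        )
    if values.ndim == 1:
        values = values[:, None]
    return RoiTimeSeries(subject_id or path.stem, values)


def read_fd(path: str | Path, subject_id: str | None = None) -> FdTrace:
    """Read a one-column framewise-displacement trace (mm)."""
    path = Path(path)
    return FdTrace(subject_id or path.stem, np.loadtxt(path).ravel())


def read_fc_matrix(path: str | Path, subject_id: str | None = None) -> ConnectivityMatrix:
    """Read a square FC matrix stored as CSV (no header) or whitespace text."""
    path = Path(path)
    z = np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",")
    return ConnectivityMatrix(subject_id or path.stem, z)


def _is_whitespace(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return "," not in first
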