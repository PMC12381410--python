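"""Anatomical description of selected-edge networks.

Translates an edge mask into network-level edge counts (intra vs inter),
node degrees ranked with atlas labels, and exact pairwise intersections
("coincidence") between the networks of different behavioral dimensions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import AtlasDefinition, edge_pairs
from .errors import InvalidConfigError


@dataclass
class NetworkEdgeCounts:
    """Symmetric networks x networks count matrix for one edge mask.

    The diagonal counts intra-network edges; each off-diagonal cell counts
    the edges between the two networks (stored once in the DataFrame's
    symmetric layout). Percentages are reported to two decimals.
    """

    counts: pd.DataFrame  # symmetric, index/columns = network labels
    n_edges: int

    @property
    def intra_count(self) -> int:
        return int(np.diag(self.counts.to_numpy()).sum())

    @property
    def inter_count(self) -> int:
        m = self.counts.to_numpy()
        return int(np.triu(m, k=1).sum())

    @property
    def intra_pct(self) -> float:
        return round(100.0 * self.intra_count / self.n_edges, 2) if self.n_edges else 0.0

    @property
    def inter_pct(self) -> float:
        return round(100.0 * self.inter_count / self.n_edges, 2) if self.n_edges else 0.0


@dataclass
class NodeDegreeReport:
    """Per-node degree within a mask, ranked (ties broken by node id)."""

    table: pd.DataFrame  # columns: node_id, x, y, z, network, degree; sorted

    @property
    def degrees(self) -> np.ndarray:
        return (
            self.table.sort_values("node_id")["degree"].to_numpy()
        )


def _mask_pairs(mask: np.ndarray, n_nodes: int) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    pairs = edge_pairs(n_nodes)
    if mask.size != pairs.shape[0]:
        raise InvalidConfigError(
            f"mask length {mask.size} does not match edge count for {n_nodes} nodes"
        )
    return pairs[mask]


def count_by_network(mask: np.ndarray, atlas: AtlasDefinition) -> NetworkEdgeCounts:
    """Attribute each masked edge to the unordered network pair of its
    endpoints; both (i,j) and (j,i) cells carry the count, the diagonal
    counts intra-network edges once."""
    selected = _mask_pairs(mask, atlas.n_nodes)
    networks = atlas.networks
    idx = {name: i for i, name in enumerate(networks)}
    labels = atlas.labels
    m = np.zeros((len(networks), len(networks)), dtype=int)
    for i, j in selected:
        a, b = idx[labels[i]], idx[labels[j]]
        if a == b:
            m[a, a] += 1
        else:
            m[a, b] += 1
            m[b, a] += 1
    counts = pd.DataFrame(m, index=networks, columns=networks)
    return NetworkEdgeCounts(counts=counts, n_edges=int(np.asarray(mask, bool).sum()))


def node_degree(mask: np.ndarray, atlas: AtlasDefinition) -> NodeDegreeReport:
    """Degree = number of masked edges incident to each node.

    The handshake identity holds: degrees sum to twice the mask size.
    """
    selected = _mask_pairs(mask, atlas.n_nodes)
    degree = np.bincount(selected.ravel(), minlength=atlas.n_nodes)
    table = atlas.nodes.copy()
    table["degree"] = degree
    table = table.sort_values(
        ["degree", "node_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return NodeDegreeReport(table=table)


def coincidence(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Exact intersection of two edge masks over the same edge universe.

    Returns the boolean AND; symmetric, idempotent and monotone under
    union of either argument.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise InvalidConfigError("masks live in different edge universes")
    return a & b


def coincidence_table(
    mask_a: np.ndarray, mask_b: np.ndarray, atlas: AtlasDefinition
) -> pd.DataFrame:
    """Shared edges as a node-pair table with network labels."""
    shared = coincidence(mask_a, mask_b)
    pairs = _mask_pairs(shared, atlas.n_nodes)
    labels = atlas.labels
    return pd.DataFrame(
        {
            "node_i": pairs[:, 0],
            "node_j": pairs[:, 1],
            "network_i": labels[pairs[:, 0]],
            "network_j": labels[pairs[:, 1]],
        }
    )


def plot_network_heatmap(counts: NetworkEdgeCounts, path=None):
    """Optional heatmap of the network-pair count matrix (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    m = counts.counts.to_numpy()
    im = ax.imshow(m, cmap="Reds")
    ax.set_xticks(range(len(counts.counts)), counts.counts.columns, rotation=90)
    ax.set_yticks(range(len(counts.counts)), counts.counts.index)
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            if m[i, j]:
                ax.text(j, i, str(m[i, j]), ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="edges")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
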