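"""Weighted graph measures: global/nodal efficiency, characteristic path
length, and degree centrality (strength).

Edge weights are mapped to lengths by reciprocal (l = 1/w, the weighted
convention of standard brain-connectivity toolboxes); shortest paths use
Dijkstra.  Disconnected pairs contribute 0 to efficiencies and are
excluded (and counted) in the characteristic path length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "DistanceMatrix",
    "GraphMetricsReport",
    "weight_to_length",
    "shortest_path_distances",
    "global_efficiency",
    "characteristic_path_length",
    "nodal_efficiency",
    "degree_centrality",
    "compute_metrics",
]


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(W < 0):
        raise ValueError("weights must be non-negative")
    if np.any(np.diag(W) != 0):
        raise ValueError("weight matrix diagonal must be zero")
    return W


@dataclass
class DistanceMatrix:
    """Shortest-path lengths; +inf marks disconnected pairs, 0 diagonal."""

    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.D.shape[0]

    def n_infinite_pairs(self) -> int:
        """Count of ordered off-diagonal pairs with infinite distance."""
        off = ~np.eye(self.n_nodes, dtype=bool)
        return int(np.isinf(self.D[off]).sum())


def weight_to_length(W: np.ndarray) -> np.ndarray:
    """l = 1/w for positive weights, +inf for absent edges, 0 diagonal."""
    W = _check_weights(W)
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def shortest_path_distances(lengths: np.ndarray) -> DistanceMatrix:
    """All-pairs shortest paths (Dijkstra per source) on a length matrix."""
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths[np.isfinite(lengths)] < 0):
        raise ValueError("lengths must be non-negative")
    if np.any(np.diag(lengths) != 0):
        raise ValueError("length matrix diagonal must be zero")
    D = shortest_path(lengths, method="D", directed=False)
    return DistanceMatrix(D=D)


def global_efficiency(dist: DistanceMatrix) -> float:
    """Mean inverse distance over ordered node pairs; 1/inf counts as 0."""
    D = dist.D
    n = dist.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(D[off] > 0, 1.0 / D[off], np.inf)
    inv[np.isinf(D[off])] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def characteristic_path_length(dist: DistanceMatrix) -> float:
    """Mean distance over finite ordered pairs (infinite pairs excluded).

    The excluded-pair count is available via
    :meth:`DistanceMatrix.n_infinite_pairs`; :func:`compute_metrics`
    surfaces it in the report.
    """
    D = dist.D
    off = ~np.eye(dist.n_nodes, dtype=bool)
    finite = np.isfinite(D[off])
    if not finite.any():
        raise ValueError("no finite off-diagonal distance: graph fully disconnected")
    return float(D[off][finite].mean())


def nodal_efficiency(dist: DistanceMatrix, i: int | None = None):
    """Mean inverse distance from node i to all others (vector if i is None)."""
    D = dist.D
    n = dist.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(D)] = 0.0
    np.fill_diagonal(inv, 0.0)
    eff = inv.sum(axis=1) / (n - 1)
    return eff if i is None else float(eff[i])


def degree_centrality(W: np.ndarray, i: int | None = None):
    """Weighted degree (strength): sum of incident edge weights."""
    W = _check_weights(W)
    s = W.sum(axis=1)
    return s if i is None else float(s[i])


@dataclass
class GraphMetricsReport:
    """Global and per-node metrics for one weighted network."""

    global_efficiency: float
    characteristic_path_length: float
    n_infinite_pairs: int
    nodal_efficiency: np.ndarray
    degree_centrality: np.ndarray
    node_names: tuple[str, ...] = ()
    weight_mode: str = "positive"
    length_mapping: str = "reciprocal"

    def to_dict(self) -> dict:
        return {
            "global": {
                "global_efficiency": self.global_efficiency,
                "characteristic_path_length": self.characteristic_path_length,
                "n_infinite_pairs": self.n_infinite_pairs,
            },
            "nodal": {
                name: {
                    "nodal_efficiency": float(self.nodal_efficiency[i]),
                    "degree_centrality": float(self.degree_centrality[i]),
                }
                for i, name in enumerate(
                    self.node_names or [str(i) for i in range(len(self.nodal_efficiency))]
                )
            },
            "provenance": {
                "weight_mode": self.weight_mode,
                "length_mapping": self.length_mapping,
            },
        }


def compute_metrics(
    W: np.ndarray,
    node_names: tuple[str, ...] = (),
    weight_mode: str = "positive",
) -> GraphMetricsReport:
    """All four measures from one non-negative weight matrix."""
    W = _check_weights(W)
    dist = shortest_path_distances(weight_to_length(W))
    return GraphMetricsReport(
        global_efficiency=global_efficiency(dist),
        characteristic_path_length=characteristic_path_length(dist),
        n_infinite_pairs=dist.n_infinite_pairs(),
        nodal_efficiency=nodal_efficiency(dist),
        degree_centrality=degree_centrality(W),
        node_names=tuple(node_names),
        weight_mode=weight_mode,
    )
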