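"""Weighted graph construction and metrics: proportional density thresholding,
node strength, Onnela weighted clustering, and global efficiency.

Conventions follow the weighted variants standard in brain-connectivity
work: the adjacency is thresholded proportionally (keep the strongest
fraction ``density`` of the N(N-1)/2 possible edges, weights preserved),
strength is the weighted degree s_i = sum_j W_ij, the clustering coefficient
uses geometric-mean triangle intensity on max-normalized weights

    t_i = 1/2 sum_{j,h} (w_ij w_jh w_ih)^(1/3),  CC_i = 2 t_i / (k_i (k_i-1)),

and global efficiency is the mean inverse shortest weighted path over
ordered pairs with edge lengths 1/w (Dijkstra), computed on max-normalized
weights so GE lies in [0, 1]; unreachable pairs contribute zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra


@dataclass
class WeightedGraph:
    """Symmetric non-negative weighted adjacency with zero diagonal."""

    W: np.ndarray
    density: float = 1.0

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")
        if W.min() < 0:
            raise ValueError("weights must be non-negative")
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        self.W = W

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return (self.W > 0).sum(axis=1)


@dataclass
class GraphMetrics:
    """Per-node strength and clustering plus scalar global efficiency at one density."""

    strength: np.ndarray
    clustering: np.ndarray
    global_efficiency: float
    density: float
    labels: tuple[str, ...] | None = None


def threshold_proportional(W: np.ndarray, density: float) -> WeightedGraph:
    """Keep the strongest ``round(density * N(N-1)/2)`` edges, weights intact.

    Rounding is half-away-from-zero (the dominant convention in
    brain-connectivity toolboxes). Ties at the cut are broken by ascending
    (row, column) index among equal weights — stable and deterministic. If
    fewer nonzero entries exist than requested, all nonzero entries are kept
    with a warning.
    """
    W = np.asarray(W, dtype=float)
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    n = W.shape[0]
    n_possible = n * (n - 1) // 2
    n_keep = int(np.floor(density * n_possible + 0.5))  # round half away from zero
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    nz = w > 0
    if n_keep > nz.sum():
        warnings.warn(
            f"requested {n_keep} edges but only {int(nz.sum())} nonzero weights; keeping all",
            stacklevel=2,
        )
        n_keep = int(nz.sum())
    # sort by weight descending, then by (i, j) ascending for ties
    order = np.lexsort((ju, iu, -w))
    keep = order[:n_keep]
    out = np.zeros_like(W)
    out[iu[keep], ju[keep]] = w[keep]
    out = out + out.T
    return WeightedGraph(W=out, density=density)


def node_strength(g: WeightedGraph) -> np.ndarray:
    """Weighted degree s_i = sum_j W_ij."""
    return g.W.sum(axis=1)


def weighted_clustering(g: WeightedGraph, normalize: bool = True) -> np.ndarray:
    """Onnela per-node weighted clustering coefficient.

    Weights are divided by the matrix maximum first (so CC is in [0, 1] and
    scale-invariant); nodes with degree < 2 get CC = 0.
    """
    W = g.W
    wmax = W.max()
    if wmax == 0:
        return np.zeros(g.n_nodes)
    Wn = W / wmax if normalize else W.copy()
    C = np.cbrt(Wn)
    t = np.diag(C @ C @ C) / 2.0  # geometric-mean triangle intensity
    k = g.degrees.astype(float)
    denom = k * (k - 1)
    cc = np.zeros(g.n_nodes)
    ok = denom > 0
    cc[ok] = 2.0 * t[ok] / denom[ok]
    return cc


def mean_clustering(g: WeightedGraph) -> float:
    """Network-average weighted clustering coefficient."""
    return float(np.mean(weighted_clustering(g)))


def global_efficiency(g: WeightedGraph, normalize: bool = True) -> float:
    """Mean inverse shortest weighted path length over ordered node pairs.

    Edge length is 1/weight; shortest paths by Dijkstra; disconnected pairs
    contribute zero. With ``normalize`` the weights are first divided by the
    matrix maximum, making the result scale-invariant and in [0, 1].
    """
    n = g.n_nodes
    if n < 2:
        return 0.0
    W = g.W
    wmax = W.max()
    if wmax == 0:
        return 0.0
    Wn = W / wmax if normalize else W
    with np.errstate(divide="ignore"):
        L = np.where(Wn > 0, 1.0 / Wn, 0.0)
    D = dijkstra(L, directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def graph_metrics(
    g: WeightedGraph, labels: tuple[str, ...] | None = None
) -> GraphMetrics:
    return GraphMetrics(
        strength=node_strength(g),
        clustering=weighted_clustering(g),
        global_efficiency=global_efficiency(g),
        density=g.density,
        labels=labels,
    )


DEFAULT_DENSITY_GRID: tuple[float, ...] = tuple(
    float(d) for d in np.round(np.arange(0.01, 0.501, 0.01), 2)
)
FEATURE_DENSITY = 0.08


def metrics_over_density_sweep(
    W: np.ndarray,
    densities=DEFAULT_DENSITY_GRID,
    labels: tuple[str, ...] | None = None,
) -> dict[float, GraphMetrics]:
    """Threshold ``W`` at each density and compute metrics.

    Densities not achievable (more edges requested than nonzero weights
    available) are still computed on all surviving edges, with the warning
    raised by :func:`threshold_proportional`.
    """
    out: dict[float, GraphMetrics] = {}
    for d in densities:
        g = threshold_proportional(W, float(d))
        out[float(d)] = graph_metrics(g, labels=labels)
    return out
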