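"""Benchmark node-similarity indices for weighted graphs.

Seven indices commonly used as link-prediction baselines:

* CN / WCN   — (weighted) common-neighbor counts.
* AA / WAA   — (weighted) Adamic-Adar, discounting high-degree neighbors.
* LRW        — local random walk, t-step transition densities.
* RE-LRW     — relative entropy of t-step walk distributions restricted
               to the top-d nodes by degree centrality.
* LRE        — relative entropy of closed-neighborhood degree histograms.

Diagonal conventions: the CN family and LRW use 0 (self-similarity is
never consulted by the evaluation protocols); the entropy family uses 1.
"""

from __future__ import annotations

import numpy as np

from .graph import WeightedGraph
from .redd import (
    DEFAULT_D,
    SimilarityMatrix,
    pairwise_difference_matrix,
    redd_similarity_matrix,
)

__all__ = [
    "cn_index",
    "wcn_index",
    "aa_index",
    "waa_index",
    "lrw_index",
    "re_lrw_index",
    "lre_index",
    "compute_index",
    "INDEX_NAMES",
]

DEFAULT_T = 3


def cn_index(graph: WeightedGraph) -> SimilarityMatrix:
    """Common neighbors: s_xy = |N(x) ∩ N(y)|."""
    a = graph.adjacency
    scores = a @ a
    np.fill_diagonal(scores, 0.0)
    return SimilarityMatrix(scores, "cn", graph.node_labels)


def wcn_index(graph: WeightedGraph) -> SimilarityMatrix:
    """Weighted common neighbors: s_xy = sum_z (w_xz + w_yz) over z in N(x) ∩ N(y)."""
    a = graph.adjacency
    w = graph.weights
    half = w @ a  # sum over z in N(x) ∩ N(y) of w_xz
    scores = half + half.T
    np.fill_diagonal(scores, 0.0)
    return SimilarityMatrix(scores, "wcn", graph.node_labels)


def aa_index(graph: WeightedGraph, log_base: float | None = None) -> SimilarityMatrix:
    """Adamic-Adar: s_xy = sum_z 1 / log(k_z) over common neighbors z.

    Natural log by default.  Common neighbors always have k_z >= 2, so
    the term is finite and positive.
    """
    a = graph.adjacency
    k = graph.degrees
    inv = np.zeros_like(k)
    nz = k > 1
    logs = np.log(k[nz]) if log_base is None else np.log(k[nz]) / np.log(log_base)
    inv[nz] = 1.0 / logs
    scores = (a * inv) @ a
    np.fill_diagonal(scores, 0.0)
    return SimilarityMatrix(scores, "aa", graph.node_labels)


def waa_index(graph: WeightedGraph, log_base: float | None = None) -> SimilarityMatrix:
    """Weighted Adamic-Adar: s_xy = sum_z (w_xz + w_yz) / log(1 + s_z).

    The 1 + s_z argument keeps the denominator positive even when a
    common neighbor's strength is below 1.
    """
    a = graph.adjacency
    w = graph.weights
    s = graph.strengths
    logs = np.log1p(s) if log_base is None else np.log1p(s) / np.log(log_base)
    inv = np.where(logs > 0, 1.0 / np.where(logs > 0, logs, 1.0), 0.0)
    half = (w * inv) @ a  # sum_z w_xz / log(1+s_z) * a_yz
    scores = half + half.T
    np.fill_diagonal(scores, 0.0)
    return SimilarityMatrix(scores, "waa", graph.node_labels)


def _transition_matrix(graph: WeightedGraph, weighted: bool = False) -> np.ndarray:
    """Row-stochastic walk matrix; isolated nodes get a self-loop row."""
    base = graph.weights if weighted else graph.adjacency
    row = base.sum(axis=1)
    p = np.divide(base, np.where(row == 0, 1.0, row)[:, None])
    iso = np.nonzero(row == 0)[0]
    p[iso, iso] = 1.0
    return p


def _walk_densities(graph: WeightedGraph, t: int, weighted: bool = False) -> np.ndarray:
    """pi[x] after t steps from the indicator of x: rows of P^t."""
    if t < 1:
        raise ValueError("walk length t must be >= 1")
    p = _transition_matrix(graph, weighted=weighted)
    return np.linalg.matrix_power(p, t)


def lrw_index(
    graph: WeightedGraph, t: int = DEFAULT_T, weighted_walk: bool = False
) -> SimilarityMatrix:
    """Local random walk: s_xy = k_x/(2m) pi_xy(t) + k_y/(2m) pi_yx(t)."""
    pi = _walk_densities(graph, t, weighted=weighted_walk)
    k = graph.degrees
    two_m = 2.0 * graph.m
    half = (k[:, None] / two_m) * pi
    scores = half + half.T
    np.fill_diagonal(scores, 0.0)
    return SimilarityMatrix(scores, "lrw", graph.node_labels)


def re_lrw_index(
    graph: WeightedGraph,
    d: int = DEFAULT_D,
    t: int = DEFAULT_T,
    weighted_walk: bool = False,
) -> SimilarityMatrix:
    """Relative entropy of local-random-walk distributions.

    Each node's t-step transition distribution is restricted to the d
    nodes of largest degree centrality (ties: ascending index) and
    renormalized (uniform fallback on zero mass); pairwise symmetrized
    KL differences are mapped to similarity via 1 - d_xy / d_max.
    """
    n = graph.n
    if not 1 <= d <= n:
        raise ValueError(f"d must be in 1..{n}, got {d}")
    pi = _walk_densities(graph, t, weighted=weighted_walk)
    k = graph.degrees
    order = np.lexsort((np.arange(n), -k))
    members = order[:d]
    r = pi[:, members]
    mass = r.sum(axis=1)
    uniform = np.full(members.shape[0], 1.0 / members.shape[0])
    r = np.where(mass[:, None] > 0, r / np.where(mass == 0, 1.0, mass)[:, None], uniform)
    return _difference_to_similarity(r, "re-lrw", graph.node_labels)


def lre_index(graph: WeightedGraph) -> SimilarityMatrix:
    """Local relative entropy over closed-neighborhood degree histograms.

    Each node's local structure is summarized as the distribution of
    degrees within {x} ∪ N(x), aligned on the union of degrees observed
    in the graph; symmetrized KL differences map to 1 - d_xy / d_max.
    """
    a = graph.adjacency
    k = graph.degrees.astype(int)
    observed = np.unique(k)
    pos = {deg: i for i, deg in enumerate(observed)}
    n = graph.n
    hist = np.zeros((n, observed.shape[0]))
    closed = a + np.eye(n)
    for x in range(n):
        members = np.nonzero(closed[x])[0]
        for y in members:
            hist[x, pos[k[y]]] += 1.0
        hist[x] /= members.shape[0]
    return _difference_to_similarity(hist, "lre", graph.node_labels)


def _difference_to_similarity(
    rows: np.ndarray, name: str, labels: tuple[str | int, ...]
) -> SimilarityMatrix:
    diff = pairwise_difference_matrix(rows)
    d_max = diff.max()
    scores = np.ones_like(diff) if d_max == 0 else 1.0 - diff / d_max
    np.fill_diagonal(scores, 1.0)
    return SimilarityMatrix(scores, name, labels)


INDEX_NAMES = ("cn", "wcn", "aa", "waa", "lrw", "re-lrw", "lre", "redd")


def compute_index(
    graph: WeightedGraph,
    name: str,
    d: int = DEFAULT_D,
    t: int = DEFAULT_T,
) -> SimilarityMatrix:
    """Compute any of the eight similarity indices by name."""
    name = name.lower()
    if name == "cn":
        return cn_index(graph)
    if name == "wcn":
        return wcn_index(graph)
    if name == "aa":
        return aa_index(graph)
    if name == "waa":
        return waa_index(graph)
    if name == "lrw":
        return lrw_index(graph, t=t)
    if name in ("re-lrw", "re_lrw", "relrw"):
        return re_lrw_index(graph, d=d, t=t)
    if name == "lre":
        return lre_index(graph)
    if name == "redd":
        return redd_similarity_matrix(graph, d=d)
    raise ValueError(f"unknown index {name!r}; choose from {INDEX_NAMES}")
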