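"""REDD: relative entropy of distance distributions as node similarity.

Pipeline, for a weighted graph with n nodes and a dimension parameter d:

1. Each node is mapped to its structural weight triple (uw, dw, sw).
2. Pairwise Euclidean distances between triples give each node a
   distance distribution over all n nodes.
3. Normalizing yields a probability distribution
   p(x, y) = 1 - d(x, y) / sum_y d(x, y), so that close nodes receive
   high probability; the full vector sums to n - 1 with unit self-entry.
4. Distributions are restricted to the d nodes of largest unit weight
   (the top-d important nodes) and renormalized to sum 1.
5. The difference between two nodes is the symmetrized Kullback-Leibler
   divergence (base 2, per-term zero convention) of their reduced
   distributions, and similarity is 1 - d_xy / d_max.

The resulting matrix is symmetric with unit diagonal and entries in
[0, 1]; structurally indistinguishable nodes score exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .graph import WeightedGraph
from .structural import StructuralWeightSet, structural_weight_set

logger = logging.getLogger(__name__)

__all__ = [
    "NodeProbabilityDistribution",
    "TopDSet",
    "SimilarityMatrix",
    "node_distance",
    "distance_distribution",
    "probability_distribution",
    "top_d_nodes",
    "reduced_distribution",
    "relative_entropy",
    "pairwise_difference",
    "symmetrized_kl",
    "redd_similarity_matrix",
]

DEFAULT_D = 5


@dataclass(frozen=True)
class NodeProbabilityDistribution:
    """Probability vector of one node over a set of target nodes.

    In the full form the support is all n nodes, the self-entry is 1 and
    the entries sum to n - 1.  In the reduced form the support is the
    top-d set and the entries sum to 1.
    """

    owner: int
    support: tuple[int, ...]
    probabilities: np.ndarray
    reduced: bool = False


@dataclass(frozen=True)
class TopDSet:
    """The d nodes of largest unit weight (ties: ascending node index)."""

    d: int
    members: tuple[int, ...]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric n x n node-similarity scores from a named index."""

    scores: np.ndarray
    index_name: str
    node_labels: tuple[str | int, ...]

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def to_csv(self, dest: IO[str]) -> None:
        header = "," + ",".join(str(l) for l in self.node_labels)
        dest.write(header + "\n")
        for lab, row in zip(self.node_labels, self.scores):
            dest.write(str(lab) + "," + ",".join(repr(v) for v in row) + "\n")

    def to_long_tsv(self, dest: IO[str]) -> None:
        labs = self.node_labels
        for x in range(self.n):
            for y in range(x + 1, self.n):
                dest.write(f"{labs[x]}\t{labs[y]}\t{self.scores[x, y]!r}\n")


# -- elementary operations -------------------------------------------------


def node_distance(sw_set: StructuralWeightSet, x: int, y: int) -> float:
    """Euclidean distance between the structural triples of x and y."""
    t = sw_set.triples()
    return float(np.linalg.norm(t[x] - t[y]))


def distance_distribution(sw_set: StructuralWeightSet, x: int) -> np.ndarray:
    """Distances from node x's triple to every node's triple (self = 0)."""
    t = sw_set.triples()
    return np.linalg.norm(t - t[x], axis=1)


def probability_distribution(
    dd: np.ndarray, owner: int = 0
) -> NodeProbabilityDistribution:
    """Full probability distribution 1 - d(x, y) / sum_y d(x, y).

    If every distance is zero (all triples identical) the ratio is taken
    as 0 by convention, giving the all-ones vector.
    """
    dd = np.asarray(dd, dtype=float)
    total = dd.sum()
    if total == 0.0:
        logger.warning("degenerate distance distribution (all zero); using all-ones")
        p = np.ones_like(dd)
    else:
        p = 1.0 - dd / total
    return NodeProbabilityDistribution(
        owner=owner, support=tuple(range(dd.shape[0])), probabilities=p, reduced=False
    )


def top_d_nodes(sw_set: StructuralWeightSet, d: int) -> TopDSet:
    """The d nodes of largest unit weight, ties broken by ascending index.

    Isolated nodes are excluded, so the member count is
    min(d, number of non-isolated nodes).
    """
    n = sw_set.n
    if not 1 <= d <= n:
        raise ValueError(f"d must be in 1..{n}, got {d}")
    candidates = np.nonzero(~sw_set.isolated)[0]
    order = candidates[np.lexsort((candidates, -sw_set.unit[candidates]))]
    return TopDSet(d=d, members=tuple(int(i) for i in order[:d]))


def reduced_distribution(
    pd: NodeProbabilityDistribution, top: TopDSet
) -> NodeProbabilityDistribution:
    """Restrict a full distribution to the top-d set and renormalize.

    A zero restricted mass falls back to the uniform vector 1/d.
    """
    if pd.reduced:
        raise ValueError("expected a full distribution")
    members = np.array(top.members, dtype=int)
    v = pd.probabilities[members]
    total = v.sum()
    if total == 0.0:
        v = np.full(members.shape[0], 1.0 / members.shape[0])
    else:
        v = v / total
    return NodeProbabilityDistribution(
        owner=pd.owner, support=top.members, probabilities=v, reduced=True
    )


def relative_entropy(
    p: NodeProbabilityDistribution | np.ndarray,
    q: NodeProbabilityDistribution | np.ndarray,
) -> float:
    """Directed KL divergence sum_z p_z log2(p_z / q_z).

    Any term where p_z = 0 or q_z = 0 contributes 0 (the zero
    convention), which keeps the value finite on restricted supports.
    """
    pv, ps = _unwrap(p)
    qv, qs = _unwrap(q)
    if ps is not None and qs is not None and ps != qs:
        raise ValueError("distributions must share the same support")
    if pv.shape != qv.shape:
        raise ValueError("distributions must have equal length")
    mask = (pv > 0) & (qv > 0)
    return float(np.sum(pv[mask] * np.log2(pv[mask] / qv[mask])))


def _unwrap(
    p: NodeProbabilityDistribution | np.ndarray,
) -> tuple[np.ndarray, tuple[int, ...] | None]:
    if isinstance(p, NodeProbabilityDistribution):
        return np.asarray(p.probabilities, dtype=float), p.support
    return np.asarray(p, dtype=float), None


def pairwise_difference(
    p: NodeProbabilityDistribution | np.ndarray,
    q: NodeProbabilityDistribution | np.ndarray,
) -> float:
    """Symmetric difference (RE(p, q) + RE(q, p)) / 2 between two nodes."""
    return (relative_entropy(p, q) + relative_entropy(q, p)) / 2.0


def symmetrized_kl(
    p: NodeProbabilityDistribution | np.ndarray,
    q: NodeProbabilityDistribution | np.ndarray,
) -> float:
    """Symmetrized KL divergence (D(p||q) + D(q||p)) / 2, base 2.

    Equals the single-sum form sum_z (p_z - q_z) log2(p_z / q_z) / 2 on
    coordinates where both are positive; swap-invariant by construction.
    """
    return pairwise_difference(p, q)


# -- the similarity matrix -------------------------------------------------


def _reduced_matrix(graph: WeightedGraph, d: int) -> tuple[np.ndarray, TopDSet]:
    """Rows: each node's reduced top-d probability distribution."""
    sws = structural_weight_set(graph)
    t = sws.triples()
    dist = cdist(t, t)
    row_sums = dist.sum(axis=1)
    with np.errstate(invalid="ignore"):
        full = np.where(row_sums[:, None] > 0, 1.0 - dist / row_sums[:, None], 1.0)
    top = top_d_nodes(sws, d)
    members = np.array(top.members, dtype=int)
    r = full[:, members]
    mass = r.sum(axis=1)
    uniform = np.full(members.shape[0], 1.0 / members.shape[0])
    r = np.where(mass[:, None] > 0, r / np.where(mass == 0, 1.0, mass)[:, None], uniform)
    return r, top


def pairwise_difference_matrix(reduced: np.ndarray) -> np.ndarray:
    """Symmetrized per-term-zero-convention KL between all row pairs."""
    n, d = reduced.shape
    logs = np.where(reduced > 0, np.log2(np.where(reduced > 0, reduced, 1.0)), 0.0)
    pos = reduced > 0
    kl = np.zeros((n, n))
    for z in range(d):
        both = pos[:, z][:, None] & pos[:, z][None, :]
        kl += np.where(both, reduced[:, z][:, None] * (logs[:, z][:, None] - logs[:, z][None, :]), 0.0)
    diff = (kl + kl.T) / 2.0
    np.fill_diagonal(diff, 0.0)
    return diff


def redd_similarity_matrix(graph: WeightedGraph, d: int = DEFAULT_D) -> SimilarityMatrix:
    """The REDD similarity matrix s_xy = 1 - d_xy / d_max.

    d_max is the largest pairwise difference; when it is 0 (all nodes
    structurally identical) every similarity is 1.
    """
    if graph.n < 2:
        raise ValueError("similarity requires n >= 2")
    if graph.m == 0:
        # all triples are (0,0,0): every node is structurally identical
        scores = np.ones((graph.n, graph.n))
        return SimilarityMatrix(scores=scores, index_name="redd", node_labels=graph.node_labels)
    reduced, _ = _reduced_matrix(graph, d)
    diff = pairwise_difference_matrix(reduced)
    d_max = diff.max()
    if d_max == 0.0:
        scores = np.ones_like(diff)
    else:
        scores = 1.0 - diff / d_max
    np.fill_diagonal(scores, 1.0)
    return SimilarityMatrix(scores=scores, index_name="redd", node_labels=graph.node_labels)
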