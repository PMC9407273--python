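"""Structural weights of nodes in a weighted graph.

Each node x carries three scalar summaries built from its degree k_x
(ability to diffuse information) and strength s_x (ability to collect
information):

* unit weight      uw(x) = s_x / k_x            (mean incident weight)
* degree weight    dw(x) = k_x^2 / (sum_y k_y) * 1/s_x
* strength weight  sw(x) = s_x^2 / (sum_y s_y) * 1/k_x

The triple (uw, dw, sw) is the node's structural weight set, treated as
a point in 3-space by the similarity machinery.  Isolated nodes (k = 0)
receive the all-zero triple by convention and are excluded from top-d
rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO

import numpy as np

from .graph import WeightedGraph

__all__ = [
    "StructuralWeightSet",
    "unit_weight",
    "degree_weight",
    "strength_weight",
    "structural_weight_set",
    "write_structural_weights_csv",
]


@dataclass(frozen=True)
class StructuralWeightSet:
    """Per-node (uw, dw, sw) triples for one graph."""

    unit: np.ndarray
    degree: np.ndarray
    strength: np.ndarray
    isolated: np.ndarray  # boolean mask of k_x == 0 nodes

    @property
    def n(self) -> int:
        return self.unit.shape[0]

    def triples(self) -> np.ndarray:
        """Stack into an (n, 3) array of points in 3-space."""
        return np.column_stack([self.unit, self.degree, self.strength])


def structural_weight_set(graph: WeightedGraph) -> StructuralWeightSet:
    """Compute all three structural weights for every node in one pass."""
    k = graph.degrees
    s = graph.strengths
    sum_k = k.sum()  # equals 2m (handshake identity)
    sum_s = s.sum()
    isolated = k == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        uw = np.where(isolated, 0.0, s / np.where(isolated, 1.0, k))
        dw = np.where(isolated, 0.0, k**2 / sum_k / np.where(s == 0, 1.0, s))
        sw = np.where(isolated, 0.0, s**2 / sum_s / np.where(isolated, 1.0, k))
    if np.any((s == 0) & ~isolated):
        raise ValueError("node with edges but zero strength violates positive weights")
    return StructuralWeightSet(unit=uw, degree=dw, strength=sw, isolated=isolated)


def unit_weight(graph: WeightedGraph, node: int) -> float:
    """Mean incident edge weight s_x / k_x (0 for isolated nodes)."""
    return float(structural_weight_set(graph).unit[node])


def degree_weight(graph: WeightedGraph, node: int) -> float:
    """Degree weight k_x^2 / (sum k) / s_x (0 for isolated nodes)."""
    return float(structural_weight_set(graph).degree[node])


def strength_weight(graph: WeightedGraph, node: int) -> float:
    """Strength weight s_x^2 / (sum s) / k_x (0 for isolated nodes)."""
    return float(structural_weight_set(graph).strength[node])


def write_structural_weights_csv(graph: WeightedGraph, dest: IO[str]) -> None:
    sw = structural_weight_set(graph)
    dest.write("label,uw,dw,sw\n")
    for i, lab in enumerate(graph.node_labels):
        dest.write(f"{lab},{sw.unit[i]!r},{sw.degree[i]!r},{sw.strength[i]!r}\n")
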