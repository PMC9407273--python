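"""Weighted-graph container, file formats, and topology statistics.

The central object is :class:`WeightedGraph`: an undirected simple graph
with strictly positive edge weights, stored as a dense symmetric weight
matrix alongside the external node labels.  All similarity indices and
evaluation protocols in this package operate on this container.

Supported on-disk formats are the ones weighted network datasets are
commonly distributed in: whitespace-separated weighted edge lists,
Pajek ``.net`` files, and square adjacency-matrix CSV files.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedGraph",
    "TopologyStats",
    "GraphFormatError",
    "read_weighted_edge_list",
    "write_weighted_edge_list",
    "read_pajek",
    "write_pajek",
    "read_adjacency_csv",
    "topology_stats",
]


class GraphFormatError(ValueError):
    """Raised when an input file cannot be parsed as a weighted graph."""


Label = str | int


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected simple graph with nonnegative edge weights.

    Parameters
    ----------
    node_labels
        External labels in internal index order.  All reported node
        references use these labels; internally nodes are dense 0-based
        indices into the weight matrix.
    weights
        Symmetric ``(n, n)`` array of edge weights with zero diagonal;
        ``weights[x, y] > 0`` iff the edge ``{x, y}`` exists.
    """

    node_labels: tuple[Label, ...]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        n = len(self.node_labels)
        if w.shape != (n, n):
            raise ValueError(f"weight matrix shape {w.shape} does not match {n} labels")
        if not np.allclose(w, w.T, rtol=0.0, atol=0.0):
            raise ValueError("weight matrix must be exactly symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("self-loops are not allowed (diagonal must be zero)")
        if np.any(w < 0.0):
            raise ValueError("edge weights must be nonnegative")
        if len(set(self.node_labels)) != n:
            raise ValueError("node labels must be unique")

    # -- basic quantities -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of nodes."""
        return len(self.node_labels)

    @property
    def adjacency(self) -> np.ndarray:
        """Binary adjacency indicator a_xy = [w_xy > 0]."""
        return (self.weights > 0.0).astype(float)

    @property
    def m(self) -> int:
        """Number of edges."""
        return int(np.count_nonzero(self.weights) // 2)

    @property
    def degrees(self) -> np.ndarray:
        """Degree k_x: the number of incident edges of each node."""
        return (self.weights > 0.0).sum(axis=1).astype(float)

    @property
    def strengths(self) -> np.ndarray:
        """Strength s_x: the total weight incident to each node."""
        return self.weights.sum(axis=1)

    def index_of(self, label: Label) -> int:
        return self.node_labels.index(label)

    def edges(self) -> Iterator[tuple[int, int, float]]:
        """Yield edges as (x, y, w) with x < y in internal indices."""
        xs, ys = np.nonzero(np.triu(self.weights, k=1))
        for x, y in zip(xs.tolist(), ys.tolist()):
            yield x, y, float(self.weights[x, y])

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Label, Label, float]],
        node_labels: Sequence[Label] | None = None,
    ) -> "WeightedGraph":
        """Build a graph from (u, v, w) triples.

        Duplicate unordered pairs collapse to a single edge, keeping the
        last weight seen; self-loops are dropped with a warning.
        """
        edges = list(edges)
        if node_labels is None:
            seen: dict[Label, None] = {}
            for u, v, _ in edges:
                seen.setdefault(u)
                seen.setdefault(v)
            node_labels = list(seen)
        index = {lab: i for i, lab in enumerate(node_labels)}
        n = len(node_labels)
        w = np.zeros((n, n))
        for u, v, weight in edges:
            if u == v:
                logger.warning("dropping self-loop at node %r", u)
                continue
            if weight < 0:
                raise ValueError(f"negative weight {weight} on edge ({u}, {v})")
            i, j = index[u], index[v]
            w[i, j] = w[j, i] = weight
        return cls(tuple(node_labels), w)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        for x, y, w in self.edges():
            g.add_edge(self.node_labels[x], self.node_labels[y], weight=w)
        return g


@dataclass(frozen=True)
class TopologyStats:
    """The standard summary row for a weighted network.

    ``mean_weighted_clustering`` depends on the chosen variant (Barrat or
    Onnela); there is no single field-wide convention.
    """

    n: int
    m: int
    mean_degree: float
    mean_strength: float
    mean_clustering: float
    mean_weighted_clustering: float
    density: float


# -- readers / writers ----------------------------------------------------


def _as_stream(source: str | IO[str]) -> IO[str]:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def _parse_label(token: str) -> Label:
    """Integers stay integers so labels sort and print naturally."""
    try:
        return int(token)
    except ValueError:
        return token


def read_weighted_edge_list(
    source: str | IO[str],
    comment_prefix: str = "#",
    default_weight: float = 1.0,
) -> WeightedGraph:
    """Parse a whitespace-separated ``u v [w]`` edge list.

    Two-token lines receive ``default_weight``, degenerating to the
    unweighted case.  Duplicate unordered pairs keep the last weight seen.
    """
    if default_weight <= 0:
        raise ValueError("default_weight must be positive")
    edges: list[tuple[Label, Label, float]] = []
    for lineno, raw in enumerate(_as_stream(source), start=1):
        line = raw.strip()
        if not line or line.startswith(comment_prefix):
            continue
        tokens = line.split()
        if len(tokens) not in (2, 3):
            raise GraphFormatError(
                f"line {lineno}: expected 2 or 3 tokens, got {len(tokens)}: {line!r}"
            )
        u, v = _parse_label(tokens[0]), _parse_label(tokens[1])
        if len(tokens) == 3:
            try:
                w = float(tokens[2])
            except ValueError as exc:
                raise GraphFormatError(f"line {lineno}: bad weight {tokens[2]!r}") from exc
            if not math.isfinite(w):
                raise GraphFormatError(f"line {lineno}: non-finite weight {w}")
            if w < 0:
                raise ValueError(f"line {lineno}: negative weight {w}")
        else:
            w = default_weight
        edges.append((u, v, w))
    return WeightedGraph.from_edges(edges)


def write_weighted_edge_list(graph: WeightedGraph, dest: IO[str]) -> None:
    """Write ``u v w`` lines with full-precision weights (round-trip safe)."""
    for x, y, w in graph.edges():
        dest.write(f"{graph.node_labels[x]} {graph.node_labels[y]} {w!r}\n")


def read_pajek(source: str | IO[str]) -> WeightedGraph:
    """Parse a Pajek ``.net`` file (``*Vertices`` then ``*Edges``/``*Arcs``).

    Arcs are symmetrized into undirected edges; vertex labels come from
    the vertices section (quoted names, or the 1-based index when absent).
    """
    stream = _as_stream(source)
    lines = [ln.strip() for ln in stream]
    i = 0
    n = None
    while i < len(lines):
        line = lines[i]
        if line.lower().startswith("*vertices"):
            parts = line.split()
            if len(parts) < 2:
                raise GraphFormatError("*Vertices header missing a count")
            n = int(parts[1])
            i += 1
            break
        if line and not line.startswith("%"):
            raise GraphFormatError("expected *Vertices header before content")
        i += 1
    if n is None:
        raise GraphFormatError("missing *Vertices section")

    labels: list[Label] = [k + 1 for k in range(n)]
    while i < len(lines) and not lines[i].lower().startswith("*"):
        line = lines[i]
        i += 1
        if not line or line.startswith("%"):
            continue
        parts = line.split(maxsplit=1)
        idx = int(parts[0])
        if not 1 <= idx <= n:
            raise ValueError(f"vertex index {idx} out of range 1..{n}")
        if len(parts) > 1:
            name = parts[1].strip()
            if name.startswith('"'):
                name = name[1 : name.index('"', 1)]
            else:
                name = name.split()[0]
            labels[idx - 1] = name

    edges: list[tuple[Label, Label, float]] = []
    in_edge_section = False
    for line in lines[i:]:
        if line.lower().startswith(("*edges", "*arcs")):
            in_edge_section = True
            continue
        if line.startswith("*"):
            in_edge_section = False
            continue
        if not in_edge_section or not line or line.startswith("%"):
            continue
        parts = line.split()
        u, v = int(parts[0]), int(parts[1])
        for idx in (u, v):
            if not 1 <= idx <= n:
                raise ValueError(f"edge endpoint {idx} out of range 1..{n}")
        w = float(parts[2]) if len(parts) > 2 else 1.0
        edges.append((labels[u - 1], labels[v - 1], w))
    return WeightedGraph.from_edges(edges, node_labels=labels)


def write_pajek(graph: WeightedGraph, dest: IO[str]) -> None:
    dest.write(f"*Vertices {graph.n}\n")
    for i, lab in enumerate(graph.node_labels, start=1):
        dest.write(f'{i} "{lab}"\n')
    dest.write("*Edges\n")
    for x, y, w in graph.edges():
        dest.write(f"{x + 1} {y + 1} {w!r}\n")


def read_adjacency_csv(source: str | IO[str]) -> WeightedGraph:
    """Parse a square weighted adjacency matrix CSV.

    An optional header row supplies node labels; otherwise labels are
    1-based integers.  The matrix must be symmetric with zero diagonal.
    """
    import pandas as pd

    stream = _as_stream(source)
    first = stream.readline()
    stream.seek(0)
    has_header = any(
        not _token_is_number(tok) for tok in first.strip().split(",") if tok.strip()
    )
    df = pd.read_csv(stream, header=0 if has_header else None)
    labels: list[Label]
    if has_header:
        labels = [_parse_label(str(c)) for c in df.columns]
    else:
        labels = list(range(1, len(df.columns) + 1))
    w = df.to_numpy(dtype=float)
    if w.shape[0] != w.shape[1]:
        raise GraphFormatError(f"adjacency matrix is not square: {w.shape}")
    w = (w + w.T) / 2.0 if np.allclose(w, w.T) else w
    return WeightedGraph(tuple(labels), w)


def _token_is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# -- topology statistics ---------------------------------------------------


def _barrat_weighted_clustering(graph: WeightedGraph) -> np.ndarray:
    """Barrat et al. local weighted clustering coefficient per node.

    c_w(x) = 1/(s_x (k_x - 1)) * sum over ordered neighbor pairs (y, z)
    closing a triangle of (w_xy + w_xz)/2; reduces to the unweighted
    clustering coefficient when all weights are 1.  Nodes with k < 2
    contribute 0.
    """
    w = graph.weights
    a = graph.adjacency
    k = graph.degrees
    s = graph.strengths
    n = graph.n
    out = np.zeros(n)
    for x in range(n):
        if k[x] < 2:
            continue
        nbrs = np.nonzero(a[x])[0]
        total = 0.0
        for ii, y in enumerate(nbrs):
            for z in nbrs[ii + 1 :]:
                if a[y, z] > 0:
                    # ordered pairs (y,z) and (z,y) each contribute (w_xy+w_xz)/2
                    total += w[x, y] + w[x, z]
        out[x] = total / (s[x] * (k[x] - 1))
    return out


def topology_stats(
    graph: WeightedGraph, weighted_cc_variant: str = "barrat"
) -> TopologyStats:
    """Compute the standard topology summary of a weighted graph.

    ``weighted_cc_variant`` selects how the mean weighted clustering
    coefficient is computed: ``"barrat"`` (strength-normalized triangle
    weights) or ``"onnela"`` (geometric mean of normalized triangle
    weights, as implemented by networkx).
    """
    if graph.n < 2:
        raise ValueError("topology statistics require n >= 2")
    g = graph.to_networkx()
    cc = nx.clustering(g)
    mean_cc = float(np.mean([cc[lab] for lab in graph.node_labels]))
    if weighted_cc_variant == "barrat":
        mean_wcc = float(_barrat_weighted_clustering(graph).mean())
    elif weighted_cc_variant == "onnela":
        wcc = nx.clustering(g, weight="weight")
        mean_wcc = float(np.mean([wcc[lab] for lab in graph.node_labels]))
    else:
        raise ValueError(f"unknown weighted clustering variant {weighted_cc_variant!r}")
    n, m = graph.n, graph.m
    return TopologyStats(
        n=n,
        m=m,
        mean_degree=2.0 * m / n,
        mean_strength=float(graph.strengths.mean()),
        mean_clustering=mean_cc,
        mean_weighted_clustering=mean_wcc,
        density=2.0 * m / (n * (n - 1)),
    )
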