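"""Newman-Watts small-world generator with configurable edge weights.

The NW model starts from a ring lattice on n nodes in which every node
is connected to its M nearest neighbors on each side (base degree 2M,
n*M edges) and then *adds* a shortcut between each non-adjacent pair
independently with probability P — no rewiring, so the lattice is
always intact.  M tunes the average degree and P the amount of
long-range disorder.

Weights are assigned afterwards by a pluggable weight model.  The
default, ``degree_product``, draws w_xy = u * k_x * k_y with u uniform
on (1, 3): the mean edge weight then scales with the square of the mean
degree, which matches how mean strength grows with density in weighted
small-world benchmark suites; an i.i.d. ``uniform_int`` model and a
``constant`` model are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .graph import TopologyStats, WeightedGraph, topology_stats

__all__ = [
    "NWParams",
    "nw_small_world",
    "assign_weights",
    "table_suite",
    "SUITE_PARAMS",
]


@dataclass(frozen=True)
class NWParams:
    """Parameters of a weighted NW small-world network."""

    n: int = 100
    M: int = 2
    P: float = 0.01
    weight_model: str = "degree_product"
    weight_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("P must lie in [0, 1]")


def nw_small_world(params: NWParams) -> WeightedGraph:
    """NW topology with unit weights (ring lattice plus random shortcuts).

    With per-side neighborhoods the lattice alone has n*M edges and
    every node degree 2M; each of the n(n-1)/2 - nM non-lattice pairs
    then becomes a shortcut independently with probability P.
    """
    n, M, P = params.n, params.M, params.P
    if M >= n / 2:
        raise ValueError(f"M={M} would make the ring lattice complete at n={n}")
    w = np.zeros((n, n))
    for j in range(1, M + 1):
        idx = np.arange(n)
        w[idx, (idx + j) % n] = 1.0
        w[(idx + j) % n, idx] = 1.0
    rng = np.random.default_rng(params.seed)
    iu = np.triu_indices(n, k=1)
    non_lattice = w[iu] == 0.0
    draws = rng.random(iu[0].shape[0])
    add = non_lattice & (draws < P)
    w[iu[0][add], iu[1][add]] = 1.0
    w[iu[1][add], iu[0][add]] = 1.0
    return WeightedGraph(tuple(range(1, n + 1)), w)


def assign_weights(
    graph: WeightedGraph,
    weight_model: str = "degree_product",
    seed: int = 0,
    **weight_params,
) -> WeightedGraph:
    """Replace unit weights with i.i.d. draws from the chosen model.

    Models:

    * ``constant``        — every edge gets ``value`` (default 1).
    * ``uniform_int``     — integers uniform on [1, ``w_max``] (default 165).
    * ``degree_product``  — w_xy = u * k_x * k_y with u ~ Uniform(``u_low``,
      ``u_high``) (defaults 1 and 3), tying strong ties to well-connected
      endpoints.
    """
    rng = np.random.default_rng(seed)
    w = graph.weights.copy()
    iu = np.triu_indices(graph.n, k=1)
    mask = w[iu] > 0.0
    n_edges = int(mask.sum())
    if weight_model == "constant":
        values = np.full(n_edges, float(weight_params.get("value", 1.0)))
    elif weight_model == "uniform_int":
        w_max = int(weight_params.get("w_max", 165))
        if w_max < 1:
            raise ValueError("w_max must be >= 1")
        values = rng.integers(1, w_max + 1, size=n_edges).astype(float)
    elif weight_model == "degree_product":
        u_low = float(weight_params.get("u_low", 1.0))
        u_high = float(weight_params.get("u_high", 3.0))
        if u_low <= 0 or u_high <= u_low:
            raise ValueError("need 0 < u_low < u_high")
        k = graph.degrees
        xs, ys = iu[0][mask], iu[1][mask]
        values = rng.uniform(u_low, u_high, size=n_edges) * k[xs] * k[ys]
    else:
        raise ValueError(f"unknown weight model {weight_model!r}")
    if np.any(values <= 0):
        raise ValueError("weight model produced a nonpositive weight")
    out = np.zeros_like(w)
    out[iu[0][mask], iu[1][mask]] = values
    out = out + out.T
    return WeightedGraph(graph.node_labels, out)


def generate(params: NWParams) -> WeightedGraph:
    """Topology plus weights in one call, both driven by ``params.seed``."""
    topo = nw_small_world(params)
    return assign_weights(
        topo, params.weight_model, seed=params.seed + 1, **params.weight_params
    )


#: The nine (M, P) combinations of the standard simulated benchmark suite.
SUITE_PARAMS: tuple[tuple[int, float], ...] = (
    (2, 0.01), (2, 0.05), (2, 0.10),
    (3, 0.01), (3, 0.05), (3, 0.10),
    (4, 0.01), (4, 0.05), (4, 0.10),
)


def table_suite(
    seed: int = 0,
    n: int = 100,
    weight_model: str = "degree_product",
    **weight_params,
) -> Iterator[tuple[str, NWParams, WeightedGraph, TopologyStats]]:
    """Generate the nine-network simulated suite (net1..net9, n=100).

    Yields (name, params, graph, stats) with per-network derived seeds.
    """
    for i, (M, P) in enumerate(SUITE_PARAMS):
        params = NWParams(
            n=n, M=M, P=P, weight_model=weight_model,
            weight_params=weight_params, seed=seed + 101 * i,
        )
        g = generate(params)
        yield f"net{i + 1}", params, g, topology_stats(g)
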