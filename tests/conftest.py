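from __future__ import annotations

import numpy as np
import pytest

from reddsim import WeightedGraph


def random_weighted_graph(
    rng: np.random.Generator,
    n: int,
    p_edge: float = 0.4,
    unit_weights: bool = False,
) -> WeightedGraph:
    """Erdos-Renyi topology with uniform positive weights; at least one edge."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(iu[0].shape[0]) < p_edge
    if not mask.any():
        mask[rng.integers(0, mask.shape[0])] = True
    values = np.ones(int(mask.sum())) if unit_weights else rng.uniform(0.5, 5.0, int(mask.sum()))
    w[iu[0][mask], iu[1][mask]] = values
    w = w + w.T
    return WeightedGraph(tuple(range(1, n + 1)), w)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)


@pytest.fixture
def triangle() -> WeightedGraph:
    return WeightedGraph.from_edges([(1, 2, 1.0), (2, 3, 1.0), (1, 3, 1.0)])


@pytest.fixture
def p4() -> WeightedGraph:
    """Path 1-2-3-4 with weights 1, 2, 3 (hand-computable triples)."""
    return WeightedGraph.from_edges([(1, 2, 1.0), (2, 3, 2.0), (3, 4, 3.0)])
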