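"""Evaluation protocols: mutual-most-similar-node mining and link prediction.

Two metrics quantify how well a similarity index captures network
structure:

* MS — the fraction of nodes belonging to a mutually-most-similar pair,
  computed on the full observed graph.
* AUC — the probability that a held-out (probe) edge outscores a random
  non-edge, estimated by sampling comparisons or computed exactly, with
  the similarity matrix built from the training graph only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .baselines import DEFAULT_T, compute_index
from .graph import WeightedGraph
from .redd import DEFAULT_D, SimilarityMatrix

__all__ = [
    "LinkPredictionSplit",
    "EvaluationResult",
    "split_edges",
    "mutual_most_similar_ratio",
    "most_similar",
    "most_similar_pairs",
    "auc_sampled",
    "auc_exact",
    "run_experiment",
]


@dataclass(frozen=True)
class LinkPredictionSplit:
    """Random partition of observed edges into training and probe sets.

    The node set is fixed: removing probe edges may isolate nodes but
    never deletes them.  ``unknown_edges`` is the universe of unordered
    node pairs that are non-adjacent in the *original* graph.
    """

    training_edges: tuple[tuple[int, int], ...]
    probe_edges: tuple[tuple[int, int], ...]
    unknown_edges: tuple[tuple[int, int], ...]
    graph: WeightedGraph
    seed: int

    def training_graph(self) -> WeightedGraph:
        """The original graph with probe edges removed (weights kept)."""
        w = self.graph.weights.copy()
        for x, y in self.probe_edges:
            w[x, y] = w[y, x] = 0.0
        return WeightedGraph(self.graph.node_labels, w)


@dataclass(frozen=True)
class EvaluationResult:
    metric: str
    value: float
    replicates: int
    per_replicate: tuple[float, ...]
    base_seed: int
    index_name: str


def split_edges(
    graph: WeightedGraph, train_fraction: float, seed: int
) -> LinkPredictionSplit:
    """Uniformly random edge partition; probe size is round-half-up of
    (1 - train_fraction) * m.  Deterministic per seed."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    edges = [(x, y) for x, y, _ in graph.edges()]
    m = len(edges)
    if m < 2:
        raise ValueError("need at least 2 edges to split")
    n_probe = int(math.floor((1.0 - train_fraction) * m + 0.5))
    if n_probe == 0:
        raise ValueError("train_fraction leaves an empty probe set")
    rng = np.random.default_rng(seed)
    probe_idx = set(rng.choice(m, size=n_probe, replace=False).tolist())
    probe = tuple(e for i, e in enumerate(edges) if i in probe_idx)
    training = tuple(e for i, e in enumerate(edges) if i not in probe_idx)
    a = graph.adjacency
    xs, ys = np.nonzero(np.triu(1.0 - a, k=1))
    unknown = tuple(zip(xs.tolist(), ys.tolist()))
    return LinkPredictionSplit(
        training_edges=training,
        probe_edges=probe,
        unknown_edges=unknown,
        graph=graph,
        seed=seed,
    )


def most_similar(sim: SimilarityMatrix) -> np.ndarray:
    """Index of each node's most similar other node (ties: lowest index)."""
    scores = sim.scores.copy()
    np.fill_diagonal(scores, -np.inf)
    return scores.argmax(axis=1)


def mutual_most_similar_ratio(sim: SimilarityMatrix) -> float:
    """MS = n_ms / n, the fraction of nodes in mutually-most-similar pairs."""
    if sim.n < 2:
        raise ValueError("MS requires n >= 2")
    best = most_similar(sim)
    mutual = best[best] == np.arange(sim.n)
    return float(mutual.sum()) / sim.n


def most_similar_pairs(sim: SimilarityMatrix) -> pd.DataFrame:
    """One row per node: its most similar node, with hub diagnostics.

    The ``general_similar_node`` column flags targets that attract more
    than half of all nodes (the pathological hub case).
    """
    best = most_similar(sim)
    labels = sim.node_labels
    counts = np.bincount(best, minlength=sim.n)
    hubs = set(np.nonzero(counts > sim.n / 2)[0].tolist())
    return pd.DataFrame(
        {
            "node": list(labels),
            "most_similar": [labels[b] for b in best],
            "general_similar_node": [int(b) in hubs for b in best],
        }
    )


def _pair_scores(sim: SimilarityMatrix, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    idx = np.asarray(pairs, dtype=int)
    return sim.scores[idx[:, 0], idx[:, 1]]


def auc_sampled(
    sim: SimilarityMatrix,
    split: LinkPredictionSplit,
    r: int = 10_000,
    seed: int = 0,
) -> float:
    """Sampled link-prediction AUC = (r1 + r2/2) / r.

    Draws r (probe edge, unknown edge) pairs uniformly with replacement;
    r1 counts probe-above-unknown comparisons, r2 counts ties.  ``sim``
    must have been computed from the training graph.
    """
    probe, unknown = _check_sets(split)
    rng = np.random.default_rng(seed)
    p = _pair_scores(sim, probe)[rng.integers(0, len(probe), size=r)]
    u = _pair_scores(sim, unknown)[rng.integers(0, len(unknown), size=r)]
    r1 = np.count_nonzero(p > u)
    r2 = np.count_nonzero(p == u)
    return (r1 + 0.5 * r2) / r


def auc_exact(sim: SimilarityMatrix, split: LinkPredictionSplit) -> float:
    """Exact AUC: mean over all probe x unknown pairs of
    [p > u] + [p == u] / 2.  The expectation of :func:`auc_sampled`."""
    probe, unknown = _check_sets(split)
    p = _pair_scores(sim, probe)
    u = _pair_scores(sim, unknown)
    greater = np.count_nonzero(p[:, None] > u[None, :])
    equal = np.count_nonzero(p[:, None] == u[None, :])
    return (greater + 0.5 * equal) / (len(p) * len(u))


def _check_sets(split: LinkPredictionSplit):
    if not split.probe_edges:
        raise ValueError("probe set is empty")
    if not split.unknown_edges:
        raise ValueError("unknown-edge universe is empty")
    return split.probe_edges, split.unknown_edges


def run_experiment(
    graph: WeightedGraph,
    index_name: str,
    metric: str = "auc",
    d: int = DEFAULT_D,
    t: int = DEFAULT_T,
    train_fraction: float = 0.9,
    replicates: int = 30,
    r: int = 10_000,
    base_seed: int = 0,
) -> EvaluationResult:
    """Run the full evaluation protocol for one index.

    AUC: per replicate i, a fresh split with seed base_seed + i, the
    index computed on the training graph, and a sampled AUC; the value
    is the replicate mean.  MS: a single deterministic evaluation on the
    full graph (no randomness is involved).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    metric = metric.lower()
    if metric == "ms":
        sim = compute_index(graph, index_name, d=d, t=t)
        value = mutual_most_similar_ratio(sim)
        return EvaluationResult("ms", value, 1, (value,), base_seed, index_name)
    if metric != "auc":
        raise ValueError(f"unknown metric {metric!r}")
    values = []
    for i in range(replicates):
        split = split_edges(graph, train_fraction, seed=base_seed + i)
        sim = compute_index(split.training_graph(), index_name, d=d, t=t)
        values.append(auc_sampled(sim, split, r=r, seed=base_seed + i))
    return EvaluationResult(
        "auc", float(np.mean(values)), replicates, tuple(values), base_seed, index_name
    )


def write_results_csv(
    results: Sequence[EvaluationResult],
    dest: IO[str],
    network: str = "",
    d: int | None = None,
) -> None:
    dest.write("network,index,d,metric,value,replicates,seed\n")
    for res in results:
        dest.write(
            f"{network},{res.index_name},{'' if d is None else d},"
            f"{res.metric},{res.value!r},{res.replicates},{res.base_seed}\n"
        )
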