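import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reddsim import (
    WeightedGraph,
    distance_distribution,
    node_distance,
    pairwise_difference,
    probability_distribution,
    redd_similarity_matrix,
    reduced_distribution,
    relative_entropy,
    structural_weight_set,
    symmetrized_kl,
    top_d_nodes,
)
from reddsim.redd import NodeProbabilityDistribution, TopDSet

from conftest import random_weighted_graph
from oracles import naive_redd_matrix


class TestNodeDistance:
    def test_self_distance_zero(self, p4):
        sws = structural_weight_set(p4)
        assert node_distance(sws, 1, 1) == 0.0

    def test_uniform_triangle_all_pairs_zero(self, triangle):
        sws = structural_weight_set(triangle)
        assert node_distance(sws, 0, 2) == 0.0

    def test_p4_endpoints_match_three_term_evaluation(self, p4):
        sws = structural_weight_set(p4)
        t = sws.triples()
        expect = (
            (t[0, 0] - t[3, 0]) ** 2 + (t[0, 1] - t[3, 1]) ** 2 + (t[0, 2] - t[3, 2]) ** 2
        ) ** 0.5
        assert node_distance(sws, 0, 3) == pytest.approx(expect, abs=1e-14)

    def test_distance_distribution_matches_pairwise(self, p4):
        sws = structural_weight_set(p4)
        for x in range(4):
            dd = distance_distribution(sws, x)
            assert dd[x] == 0.0
            for y in range(4):
                assert dd[y] == pytest.approx(node_distance(sws, x, y), abs=1e-14)


class TestProbabilityDistribution:
    def test_forced_arithmetic(self):
        pd = probability_distribution(np.array([0.0, 1.0, 3.0]))
        assert pd.probabilities == pytest.approx([1.0, 0.75, 0.25])

    def test_self_entry_one_and_sum_n_minus_one(self, rng):
        for _ in range(10):
            g = random_weighted_graph(rng, int(rng.integers(3, 10)))
            sws = structural_weight_set(g)
            for x in range(g.n):
                dd = distance_distribution(sws, x)
                if dd.sum() == 0:
                    continue
                pd = probability_distribution(dd, owner=x)
                assert pd.probabilities[x] == pytest.approx(1.0)
                assert pd.probabilities.sum() == pytest.approx(g.n - 1)
                assert np.all(pd.probabilities >= 0) and np.all(pd.probabilities <= 1)

    def test_degenerate_all_zero_distances_fall_back_to_ones(self):
        pd = probability_distribution(np.zeros(4))
        assert pd.probabilities.tolist() == [1.0] * 4


class TestTopD:
    def test_sorting(self):
        sws_unit = np.array([5.0, 2.0, 9.0])
        fake = _fake_sws(sws_unit)
        assert top_d_nodes(fake, 2).members == (2, 0)

    def test_tie_break_ascending_index(self):
        fake = _fake_sws(np.array([1.0, 1.0, 1.0]))
        assert top_d_nodes(fake, 3).members == (0, 1, 2)

    def test_prefix_property_and_full_sort_oracle(self, rng):
        g = random_weighted_graph(rng, 15)
        sws = structural_weight_set(g)
        full = sorted(
            (x for x in range(g.n) if not sws.isolated[x]),
            key=lambda x: (-sws.unit[x], x),
        )
        prev = ()
        for d in range(1, g.n + 1):
            members = top_d_nodes(sws, d).members
            assert members == tuple(full[: len(members)])
            assert members[: len(prev)] == prev  # growing d extends a prefix
            prev = members

    def test_d_out_of_range(self, triangle):
        sws = structural_weight_set(triangle)
        with pytest.raises(ValueError):
            top_d_nodes(sws, 0)
        with pytest.raises(ValueError):
            top_d_nodes(sws, 4)


def _fake_sws(unit):
    from reddsim.structural import StructuralWeightSet

    n = unit.shape[0]
    return StructuralWeightSet(
        unit=unit, degree=np.zeros(n), strength=np.zeros(n),
        isolated=np.zeros(n, dtype=bool),
    )


class TestReducedDistribution:
    def test_normalization(self):
        pd = NodeProbabilityDistribution(0, (0, 1, 2), np.array([0.5, 0.5, 1.0]))
        r = reduced_distribution(pd, TopDSet(3, (0, 1, 2)))
        assert r.probabilities == pytest.approx([0.25, 0.25, 0.5])

    def test_all_equal_becomes_uniform(self):
        pd = NodeProbabilityDistribution(0, (0, 1, 2), np.array([0.3, 0.3, 0.3]))
        r = reduced_distribution(pd, TopDSet(3, (0, 1, 2)))
        assert r.probabilities == pytest.approx([1 / 3] * 3)

    def test_zero_mass_uniform_fallback(self):
        pd = NodeProbabilityDistribution(0, (0, 1, 2, 3), np.array([0.0, 0.0, 0.7, 0.1]))
        r = reduced_distribution(pd, TopDSet(2, (0, 1)))
        assert r.probabilities == pytest.approx([0.5, 0.5])

    def test_own_entry_is_one_before_renormalization(self, rng):
        g = random_weighted_graph(rng, 8)
        sws = structural_weight_set(g)
        top = top_d_nodes(sws, 4)
        x = top.members[0]
        dd = distance_distribution(sws, x)
        if dd.sum() > 0:
            pd = probability_distribution(dd, owner=x)
            assert pd.probabilities[x] == pytest.approx(1.0)


class TestRelativeEntropy:
    def test_identical_distributions_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert relative_entropy(p, p) == 0.0

    def test_forced_arithmetic_with_zero_convention(self):
        assert relative_entropy(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == pytest.approx(1.0)

    def test_matches_term_by_term_oracle(self, rng):
        import math

        for _ in range(50):
            d = int(rng.integers(2, 8))
            p = rng.dirichlet(np.ones(d))
            q = rng.dirichlet(np.ones(d))
            expect = sum(
                p[z] * math.log2(p[z] / q[z]) for z in range(d) if p[z] > 0 and q[z] > 0
            )
            assert relative_entropy(p, q) == pytest.approx(expect, abs=1e-12)

    def test_mismatched_supports_rejected(self):
        a = NodeProbabilityDistribution(0, (0, 1), np.array([0.5, 0.5]), True)
        b = NodeProbabilityDistribution(1, (0, 2), np.array([0.5, 0.5]), True)
        with pytest.raises(ValueError):
            relative_entropy(a, b)


class TestSymmetrizedKL:
    def test_pairwise_difference_is_average(self):
        p = np.array([0.7, 0.3])
        q = np.array([0.4, 0.6])
        expect = (relative_entropy(p, q) + relative_entropy(q, p)) / 2
        assert pairwise_difference(p, q) == pytest.approx(expect, abs=1e-15)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), d=st.integers(2, 9))
    def test_symmetry_and_single_sum_expansion(self, seed, d):
        r = np.random.default_rng(seed)
        p = r.dirichlet(np.ones(d))
        q = r.dirichlet(np.ones(d))
        rd = symmetrized_kl(p, q)
        assert rd == pytest.approx(symmetrized_kl(q, p), abs=1e-12)
        # the expanded single-sum form sum (p-q) log2(p/q) / 2
        single = float(np.sum((p - q) * np.log2(p / q)) / 2)
        assert rd == pytest.approx(single, abs=1e-12)
        assert symmetrized_kl(p, p) == 0.0


class TestReddMatrix:
    def test_uniform_triangle_all_ones(self, triangle):
        s = redd_similarity_matrix(triangle, d=2).scores
        assert np.array_equal(s, np.ones((3, 3)))

    def test_structure_and_extremes(self, rng):
        g = random_weighted_graph(rng, 10)
        s = redd_similarity_matrix(g, d=4).scores
        assert np.allclose(s, s.T)
        assert np.all(s >= -1e-12) and np.all(s <= 1 + 1e-12)
        assert np.allclose(np.diag(s), 1.0)
        off = s[~np.eye(g.n, dtype=bool)]
        if not np.allclose(off, 1.0):
            assert off.min() == pytest.approx(0.0, abs=1e-12)  # d_max pair scores 0

    def test_matches_naive_oracle_small_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            g = random_weighted_graph(rng, n)
            d = int(rng.integers(2, min(7, n) + 1))
            s = redd_similarity_matrix(g, d=d).scores
            expect = np.array(naive_redd_matrix(g.weights.tolist(), d))
            assert np.allclose(s, expect, atol=1e-10)

    def test_automorphic_nodes_score_one(self):
        # nodes 1 and 4 are swapped by an automorphism of this path
        g = WeightedGraph.from_edges([(1, 2, 2.0), (2, 3, 5.0), (3, 4, 2.0)])
        s = redd_similarity_matrix(g, d=3).scores
        assert s[0, 3] == pytest.approx(1.0, abs=1e-12)

    def test_edgeless_graph_all_ones(self):
        g = WeightedGraph((1, 2, 3), np.zeros((3, 3)))
        assert np.array_equal(redd_similarity_matrix(g, d=2).scores, np.ones((3, 3)))
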