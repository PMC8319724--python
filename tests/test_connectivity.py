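import math

import numpy as np
import pytest

from consynt.connectivity import (
    StudyPoint,
    _random_graph_arrays,
    assess_connectivity,
    conservation_connectivity_correlation,
    links_per_gene,
    random_null,
)
from consynt.io import InteractionGraph


def triangle():
    return InteractionGraph([("A", "B"), ("B", "C"), ("C", "A")])


class TestLinksPerGene:
    def test_triangle_full_set(self):
        assert links_per_gene(triangle(), ["A", "B", "C"]) == (3, 2.0)

    def test_isolated_member_dilutes_denominator(self):
        assert links_per_gene(triangle(), ["A", "B", "C", "D"]) == (3, 1.5)

    def test_covered_denominator_mode_ignores_missing(self):
        within, lpg = links_per_gene(
            triangle(), ["A", "B", "C", "D"], denominator="covered"
        )
        assert (within, lpg) == (3, 2.0)

    def test_disjoint_set_is_zero(self):
        assert links_per_gene(triangle(), ["X", "Y"]) == (0, 0.0)

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            links_per_gene(triangle(), [])

    def test_edge_outside_set_changes_nothing(self):
        g = InteractionGraph([("A", "B"), ("B", "C"), ("C", "A"), ("C", "Z")])
        assert links_per_gene(g, ["A", "B", "C"]) == (3, 2.0)

    def test_invariant_under_node_relabeling(self):
        g1 = InteractionGraph([("A", "B"), ("B", "C")])
        g2 = InteractionGraph([("x", "y"), ("y", "z")])
        assert links_per_gene(g1, ["A", "B", "C"]) == links_per_gene(
            g2, ["x", "y", "z"]
        )

    def test_matches_networkx_subgraph_count(self):
        # independent route: networkx subgraph edge count on a random graph
        rng = np.random.default_rng(0)
        u, v = _random_graph_arrays(60, 0.1, rng)
        names = [f"n{i}" for i in range(60)]
        g = InteractionGraph.from_arrays(names, u, v)
        subset = names[:25]
        nx_edges = g.to_networkx().subgraph(subset).number_of_edges()
        within, lpg = links_per_gene(g, subset)
        assert within == nx_edges
        assert lpg == pytest.approx(2 * nx_edges / 25)


class TestRandomNull:
    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(1)
        u, v = _random_graph_arrays(200, 0.05, rng)
        g = InteractionGraph.from_arrays([f"n{i}" for i in range(200)], u, v)
        universe = g.node_list
        a = random_null(g, universe, 50, n_sets=4, seed=9)
        b = random_null(g, universe, 50, n_sets=4, seed=9)
        assert a == b
        c = random_null(g, universe, 50, n_sets=4, seed=10)
        assert a.per_set_values != c.per_set_values

    def test_per_set_values_homogeneous_on_uniform_graph(self):
        rng = np.random.default_rng(2)
        u, v = _random_graph_arrays(1000, 0.02, rng)
        g = InteractionGraph.from_arrays([f"n{i}" for i in range(1000)], u, v)
        null = random_null(g, g.node_list, 150, n_sets=4, seed=0)
        spread = max(null.per_set_values) - min(null.per_set_values)
        assert spread < 6 * null.sd + 1e-9  # all four within a tight band

    def test_null_mean_matches_analytic_expectation(self):
        # E[links/gene] = p * (set_size - 1) on an Erdos-Renyi graph when the
        # universe equals the node set; checked within 5% at n_sets=200
        rng = np.random.default_rng(3)
        n, p, size = 2000, 0.01, 300
        u, v = _random_graph_arrays(n, p, rng)
        g = InteractionGraph.from_arrays([f"n{i}" for i in range(n)], u, v)
        null = random_null(g, g.node_list, size, n_sets=200, seed=4)
        expected = p * (size - 1)
        assert abs(null.mean - expected) / expected < 0.05

    def test_set_size_exceeding_universe_rejected(self):
        g = triangle()
        with pytest.raises(ValueError):
            random_null(g, ["A", "B", "C"], 4, seed=0)


class TestAssessConnectivity:
    def test_observed_equal_to_null_not_significant(self):
        g = triangle()
        res = assess_connectivity(g, ["A", "B", "C"], ["A", "B", "C"], seed=0)
        # null sets are the whole universe -> identical statistic, sd = 0
        assert res.links_per_gene == res.null_mean
        assert not res.significant

    def test_zero_cutoff_degenerates_to_mean_comparison(self):
        rng = np.random.default_rng(5)
        u, v = _random_graph_arrays(300, 0.03, rng)
        names = [f"n{i}" for i in range(300)]
        g = InteractionGraph.from_arrays(names, u, v)
        res = assess_connectivity(g, names[:60], names, cutoff_sd=0.0, seed=6)
        assert res.significant == (res.links_per_gene > res.null_mean)
        assert res.ci_bound == pytest.approx(res.null_mean)

    def test_planted_dense_set_detected(self):
        rng = np.random.default_rng(7)
        risk_idx = np.arange(100, dtype=np.int64)
        u, v = _random_graph_arrays(
            1500, 0.01, rng, risk_index=risk_idx, p_within=0.08
        )
        names = [f"n{i}" for i in range(1500)]
        g = InteractionGraph.from_arrays(names, u, v)
        res = assess_connectivity(g, names[:100], names, n_sets=20, seed=8)
        assert res.significant
        assert res.links_per_gene > 4 * res.null_mean

    def test_invariants_of_result(self):
        rng = np.random.default_rng(9)
        u, v = _random_graph_arrays(400, 0.02, rng)
        names = [f"n{i}" for i in range(400)]
        g = InteractionGraph.from_arrays(names, u, v)
        res = assess_connectivity(g, names[:80], names, seed=10)
        assert res.links_per_gene == pytest.approx(
            2 * res.within_edges / res.n_genes
        )
        assert res.ci_bound == pytest.approx(
            res.null_mean + res.cutoff_sd * res.null_sd
        )
        assert len(res.null_values) == res.null_sets


class TestCorrelation:
    def test_printed_study_points_give_097(self):
        points = [
            StudyPoint("schizophrenia", 75, 8),
            StudyPoint("mdd", 82, 13),
            StudyPoint("bipolar", 87, 22),
        ]
        r2, r_full = conservation_connectivity_correlation(points)
        assert r2 == 0.97
        # cross-check against the from-scratch covariance formula
        x = np.array([75.0, 82.0, 87.0])
        y = np.array([8.0, 13.0, 22.0])
        manual = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert abs(r_full - manual) < 1e-12

    def test_collinear_points_give_one(self):
        pts = [StudyPoint(str(i), 10.0 * i, 2.0 * i + 1) for i in range(1, 4)]
        assert conservation_connectivity_correlation(pts)[0] == 1.0

    def test_sign_flip_negates(self):
        pts = [StudyPoint("a", 75, 8), StudyPoint("b", 82, 13), StudyPoint("c", 87, 22)]
        flipped = [
            StudyPoint(p.study_label, p.conservation_pct, -p.links_per_gene)
            for p in pts
        ]
        assert (
            conservation_connectivity_correlation(pts)[1]
            == -conservation_connectivity_correlation(flipped)[1]
        )

    def test_too_few_points_or_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            conservation_connectivity_correlation(
                [StudyPoint("a", 1, 2), StudyPoint("b", 3, 4)]
            )
        with pytest.raises(ValueError):
            conservation_connectivity_correlation(
                [StudyPoint("a", 5, 1), StudyPoint("b", 5, 2), StudyPoint("c", 5, 3)]
            )
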