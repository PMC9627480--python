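"""Topology statistics, power-law fitting and the hierarchy assessment."""

import math

import networkx as nx
import numpy as np
import pytest

from mirnome.network_build import GeneNetwork
from mirnome.topology import (
    DegreeDistribution,
    FitError,
    assess_hierarchy,
    avg_neighbors,
    clustering_coefficient,
    degree_distribution,
    degree_sequence,
    fit_power_law,
    shortest_path_stats,
    topology_report,
)

from conftest import net_from_edges, oracle_clustering, oracle_path_stats, random_network


class TestElementary:
    def test_degree_sequences(self, triangle, star5):
        assert set(degree_sequence(triangle).values()) == {2}
        degs = degree_sequence(star5)
        assert degs["hub"] == 5 and all(degs[f"leaf{i}"] == 1 for i in range(5))
        path = net_from_edges([("A", "B"), ("B", "C")])
        assert sorted(degree_sequence(path).values()) == [1, 1, 2]

    @pytest.mark.parametrize(
        "n,e,expected",
        [(2665, 6599, 4.952), (1746, 6529, 7.479)],
    )
    def test_avg_neighbors_identity(self, n, e, expected):
        # 2E/N reproduces the printed 3-decimal values for both network sizes
        g = GeneNetwork(graph=nx.gnm_random_graph(n, e, seed=0))
        assert round(avg_neighbors(g), 3) == expected

    def test_avg_neighbors_edgeless(self):
        assert avg_neighbors(net_from_edges([], isolated=["a", "b"])) == 0.0


class TestClustering:
    def test_triangle_and_star(self, triangle, star5):
        per, avg = clustering_coefficient(triangle)
        assert avg == 1.0 and set(per.values()) == {1.0}
        per, avg = clustering_coefficient(star5)
        assert avg == 0.0  # only the centre is eligible, C=0

    def test_four_clique_minus_edge(self):
        # two degree-3 nodes have C=2/3, two degree-2 nodes C=1; average 5/6
        net = net_from_edges([("a", "b"), ("a", "c"), ("a", "d"),
                              ("b", "c"), ("b", "d")])
        per, avg = clustering_coefficient(net)
        assert per["a"] == pytest.approx(2 / 3) and per["c"] == pytest.approx(1.0)
        assert avg == pytest.approx(5 / 6)

    def test_all_nodes_mode_counts_low_degree_as_zero(self, star5):
        _, avg_all = clustering_coefficient(star5, mode="all_nodes")
        assert avg_all == 0.0
        tri_plus_leaf = net_from_edges([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        _, eligible = clustering_coefficient(tri_plus_leaf)
        _, allm = clustering_coefficient(tri_plus_leaf, mode="all_nodes")
        assert allm < eligible  # the k=1 leaf dilutes the all-nodes average

    def test_matches_triangle_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            net = random_network(rng)
            per, _ = clustering_coefficient(net)
            oracle = oracle_clustering(net)
            assert per == pytest.approx(oracle)


class TestShortestPaths:
    def test_path_graph(self):
        n_pairs, pct, cpl, diameter = shortest_path_stats(
            net_from_edges([("A", "B"), ("B", "C")])
        )
        assert (n_pairs, pct, diameter) == (6, 100.0, 2)
        assert cpl == pytest.approx(4 / 3)

    def test_triangle_plus_isolated(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")], isolated=["x"])
        n_pairs, pct, cpl, diameter = shortest_path_stats(net)
        assert (n_pairs, pct, cpl, diameter) == (6, 50.0, 1.0, 1)

    def test_edgeless(self):
        n_pairs, pct, cpl, diameter = shortest_path_stats(
            net_from_edges([], isolated=["a", "b", "c"])
        )
        assert (n_pairs, pct, diameter) == (0, 0.0, 0)
        assert math.isnan(cpl)

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            net = random_network(rng)
            got = shortest_path_stats(net)
            want = oracle_path_stats(net)
            assert got[0] == want[0] and got[3] == want[3]
            assert got[1] == pytest.approx(want[1])
            if got[0]:
                assert got[2] == pytest.approx(want[2])
            assert got[2] <= got[3] or got[0] == 0  # CPL <= diameter


class TestDegreeDistribution:
    def test_histograms(self, star5, triangle):
        assert degree_distribution(star5).counts == {1: 5, 5: 1}
        ring = net_from_edges([(i, (i + 1) % 6) for i in range(6)])
        assert degree_distribution(ring).counts == {2: 6}
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")], isolated=["x"])
        dist = degree_distribution(net)
        assert dist.counts == {2: 3} and dist.n_zero == 1

    def test_conservation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            net = random_network(rng)
            dist = degree_distribution(net)
            assert sum(dist.counts.values()) + dist.n_zero == net.n_nodes
            assert sum(k * c for k, c in dist.counts.items()) == 2 * net.n_edges
            probs = [dist.probability(k) for k in list(dist.counts) + [0]]
            assert sum(probs) == pytest.approx(1.0)


class TestPowerLawFit:
    def test_exact_model_recovery(self):
        # counts generated exactly as a*k^gamma are refit to machine precision
        for gamma in (-1.702, -2.0, -0.5):
            counts = {k: 1000.0 * k**gamma for k in (1, 2, 4, 8, 16)}
            dist = DegreeDistribution(counts=counts, n_zero=0, n_nodes=1)
            fit = fit_power_law(dist)
            assert abs(fit.gamma - gamma) < 1e-6
            assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_rounded_power_law(self):
        counts = {k: round(1000 * k**-2.0) for k in (1, 2, 4, 8)}
        fit = fit_power_law(DegreeDistribution(counts=counts, n_zero=0, n_nodes=1))
        assert abs(fit.gamma + 2.0) < 0.01 and fit.r_squared > 0.999

    def test_flat_counts_zero_slope(self):
        fit = fit_power_law(
            DegreeDistribution(counts={k: 10 for k in range(1, 6)}, n_zero=0, n_nodes=50)
        )
        assert fit.gamma == pytest.approx(0.0, abs=1e-12)

    def test_against_closed_form_ols(self):
        counts = {1: 100, 2: 25, 4: 6, 8: 2}
        fit = fit_power_law(DegreeDistribution(counts=counts, n_zero=0, n_nodes=133))
        x = np.log10(list(counts.keys()))
        y = np.log10(list(counts.values()))
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert fit.gamma == pytest.approx(slope, abs=1e-12)
        assert abs(fit.gamma - slope) < 0.05
        # r_squared equals the squared Pearson correlation of the log-log points
        assert fit.r_squared == pytest.approx(float(np.corrcoef(x, y)[0, 1]) ** 2)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_power_law(DegreeDistribution(counts={3: 10}, n_zero=0, n_nodes=10))


class TestHierarchy:
    def test_exact_hierarchical_fixture(self):
        # Feed C(k) = 1/k through the regression via a constructed assessment:
        # a graph whose mean clustering per degree follows 1/k exactly is
        # emulated by regressing the closed-form points directly.
        from mirnome.topology import _loglog_ols

        ks = np.array([2.0, 3.0, 4.0, 6.0, 8.0])
        slope, _, r2 = _loglog_ols(ks, 1.0 / ks)
        assert slope == pytest.approx(-1.0) and r2 == pytest.approx(1.0)

    def test_regular_ring_indeterminate(self):
        ring = net_from_edges([(i, (i + 1) % 6) for i in range(6)])
        result = assess_hierarchy(ring)
        assert result.verdict is None

    def test_hierarchical_verdict_on_deterministic_graph(self):
        # two triangles sharing a node: C(2)=1, C(4)=1/3 -> falling C(k)
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c"),
                              ("c", "d"), ("d", "e"), ("c", "e")])
        result = assess_hierarchy(net, cutoff=0.5)
        assert result.slope < 0 and result.verdict is True

    def test_seeded_reproducibility(self):
        from mirnome.synthetic_data import generate_preferential_attachment

        a = assess_hierarchy(generate_preferential_attachment(300, 3, seed=9))
        b = assess_hierarchy(generate_preferential_attachment(300, 3, seed=9))
        assert a == b


class TestReport:
    def test_triangle_report(self, triangle):
        r = topology_report(triangle)
        assert (r.n_nodes, r.n_edges, r.n_components) == (3, 3, 1)
        assert r.avg_clustering == 1.0 and r.diameter == 1
        assert (r.n_shortest_paths, r.shortest_paths_pct) == (6, 100.0)
        assert r.char_path_length == 1.0 and r.avg_neighbors == 2.0

    def test_two_disjoint_edges(self):
        r = topology_report(net_from_edges([("a", "b"), ("c", "d")]))
        assert (r.n_nodes, r.n_edges, r.n_components) == (4, 2, 2)
        assert r.avg_clustering == 0.0 and r.diameter == 1
        assert r.n_shortest_paths == 4
        assert r.shortest_paths_pct == pytest.approx(100 * 4 / 12)
        assert r.char_path_length == 1.0 and r.avg_neighbors == 1.0

    def test_invariants_on_mc_scale_fixture(self):
        from mirnome.synthetic_data import generate_preferential_attachment

        net = generate_preferential_attachment(500, 2, seed=2)
        r = topology_report(net)
        assert r.n_shortest_paths == r.n_nodes * (r.n_nodes - 1)  # connected
        assert r.shortest_paths_pct == 100.0
        assert r.char_path_length <= r.diameter
        assert r.avg_neighbors == pytest.approx(2 * r.n_edges / r.n_nodes)

    def test_adding_edge_monotonicity(self):
        # on a connected graph a new edge can only shorten paths and raise 2E/N
        rng = np.random.default_rng(21)
        for _ in range(10):
            g = nx.connected_watts_strogatz_graph(
                12, 4, 0.3, seed=int(rng.integers(2**31))
            )
            net = GeneNetwork(graph=nx.relabel_nodes(g, str))
            before = topology_report(net)
            non_edges = list(nx.non_edges(net.graph))
            if not non_edges:
                continue
            a, b = non_edges[int(rng.integers(len(non_edges)))]
            net.graph.add_edge(a, b)
            after = topology_report(net)
            assert after.char_path_length <= before.char_path_length
            assert after.avg_neighbors >= before.avg_neighbors
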