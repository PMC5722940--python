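"""Network topology statistics against brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from interoppi.topology import (
    average_path_length,
    clustering_coefficient,
    degree_distribution,
    fit_power_law,
    network_stats,
    random_reference,
    small_world_report,
)


def bfs_all_pairs_oracle(g):
    """Hand-rolled BFS all-pairs shortest paths (connected pairs only)."""
    nodes = list(g.nodes)
    total, count = 0, 0
    for i, src in enumerate(nodes):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v != u and v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for tgt in nodes[i + 1:]:
            if tgt in dist:
                total += dist[tgt]
                count += 1
    return total, count


def triangle_clustering_oracle(g):
    """Mean local clustering via explicit neighbor-pair enumeration."""
    cs = []
    for node in g.nodes:
        nbrs = [v for v in g.neighbors(node) if v != node]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(1 for u, v in itertools.combinations(nbrs, 2) if g.has_edge(u, v))
        cs.append(2.0 * links / (k * (k - 1)))
    return sum(cs) / len(cs)


class TestDegreeDistribution:
    def test_triangle(self):
        assert degree_distribution(nx.complete_graph(3)) == {2: 3}

    def test_star(self):
        assert degree_distribution(nx.star_graph(4)) == {4: 1, 1: 4}

    def test_self_loop_counts_once(self):
        g = nx.Graph([("a", "a"), ("a", "b")])
        assert degree_distribution(g) == {2: 1, 1: 1}

    def test_random_graph_census_oracle(self):
        g = nx.gnm_random_graph(50, 120, seed=3)
        hist = degree_distribution(g)
        assert sum(hist.values()) == g.number_of_nodes()
        census = {}
        for node in g.nodes:
            census[node] = sum(1 for _ in g.neighbors(node))
        expected = {}
        for k in census.values():
            expected[k] = expected.get(k, 0) + 1
        assert hist == expected


class TestPowerLawFit:
    @pytest.mark.parametrize("gamma", [2.0, 3.0])
    def test_exact_power_law_recovered_to_machine_precision(self, gamma):
        ks = range(1, 33)
        hist = {k: 1_000_000 * k**-gamma for k in ks}
        assert fit_power_law(hist) == pytest.approx(gamma, abs=1e-9)

    def test_too_few_support_points(self):
        with pytest.raises(ValueError):
            fit_power_law({1: 5, 2: 3})

    def test_preferential_attachment_exponent_in_plausible_band(self):
        g = nx.barabasi_albert_graph(10_000, 3, seed=11)
        gamma = fit_power_law(degree_distribution(g))
        assert 1.8 <= gamma <= 3.5
        # cross-check against an independent log-log regression
        hist = degree_distribution(g)
        ks = np.array(sorted(k for k, c in hist.items() if k >= 1 and c > 0), float)
        total = sum(c for k, c in hist.items() if k >= 1 and c > 0)
        y = np.log10([hist[int(k)] / total for k in ks])
        x = np.log10(ks)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert gamma == pytest.approx(-slope, abs=1e-9)


class TestAveragePathLength:
    def test_triangle(self):
        assert average_path_length(nx.complete_graph(3)) == 1.0

    def test_three_path(self):
        assert average_path_length(nx.path_graph(3)) == pytest.approx(4 / 3)

    def test_disjoint_edges_exclude_cross_pairs(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert average_path_length(g) == 1.0

    def test_matches_bfs_oracle_on_random_graphs(self):
        for seed in range(25):
            g = nx.gnm_random_graph(40, 70, seed=seed)
            total, count = bfs_all_pairs_oracle(g)
            if count == 0:
                continue
            assert average_path_length(g) == pytest.approx(total / count, abs=1e-12)

    def test_no_connected_pair_is_error(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        with pytest.raises(ValueError):
            average_path_length(g)


class TestClustering:
    def test_triangle(self):
        assert clustering_coefficient(nx.complete_graph(3)) == 1.0

    def test_star_has_no_neighbor_links(self):
        assert clustering_coefficient(nx.star_graph(4)) == 0.0

    def test_triangle_plus_pendant_hand_enumeration(self):
        # nodes: triangle a-b-c plus pendant d on a and isolated e
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("a", "d")])
        g.add_node("e")
        # C_a = 2*1/(3*2) = 1/3, C_b = C_c = 1, C_d = C_e = 0
        assert clustering_coefficient(g) == pytest.approx((1 / 3 + 1 + 1) / 5)

    def test_matches_triangle_oracle_on_random_graphs(self):
        for seed in range(25):
            g = nx.gnm_random_graph(35, 90, seed=seed)
            assert clustering_coefficient(g) == pytest.approx(
                triangle_clustering_oracle(g), abs=1e-12
            )


class TestRandomReference:
    def test_saturated_case_is_complete_graph(self):
        g = random_reference(4, 6, seed=0)
        assert nx.is_isomorphic(g, nx.complete_graph(4))

    def test_same_seed_same_edges(self):
        g1 = random_reference(100, 300, seed=9)
        g2 = random_reference(100, 300, seed=9)
        assert set(g1.edges) == set(g2.edges)

    def test_exact_node_and_edge_counts(self):
        g = random_reference(1000, 3000, seed=1)
        assert g.number_of_nodes() == 1000 and g.number_of_edges() == 3000
        mean_degree = sum(d for _, d in g.degree) / g.number_of_nodes()
        assert mean_degree == 6.0

    def test_infeasible_edge_count(self):
        with pytest.raises(ValueError):
            random_reference(4, 7, seed=0)


class TestSmallWorld:
    def test_preferential_attachment_clusters_above_random(self):
        g = nx.barabasi_albert_graph(300, 3, seed=5)
        rep = small_world_report(g, seed=13, n_reference=5)
        assert rep.clustering_ratio > 1.0

    def test_er_network_judged_not_small_world(self):
        g = nx.gnm_random_graph(300, 900, seed=8)
        rep = small_world_report(g, seed=21, n_reference=5)
        assert not rep.clustering_exceeds_random

    def test_complete_graph_degenerate(self):
        rep = small_world_report(nx.complete_graph(6), seed=0, n_reference=3)
        assert rep.avg_path_length == rep.random_avg_path_length == 1.0


def test_network_stats_consistency():
    g = nx.barabasi_albert_graph(200, 2, seed=2)
    stats = network_stats(g)
    assert sum(stats.degree_histogram.values()) == stats.n_nodes == 200
    assert stats.diameter >= stats.avg_path_length
    assert 0.0 <= stats.clustering_coefficient <= 1.0
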