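import math

import numpy as np
import pytest

from spermnet import (
    DegreeDistribution,
    PowerLawFitError,
    SignalingNetwork,
    build_network,
    closeness_centrality,
    clustering_vs_degree,
    degree_distribution,
    fit_power_law,
    mean_clustering,
    node_clustering,
    path_statistics,
    rank_hubs,
    summarize_topology,
)
from spermnet.records import InteractionRecord

from conftest import random_network
from _oracles import (
    clustering_oracle,
    closeness_oracle,
    degree_counts_oracle,
    path_stats_oracle,
)


class TestDegreeDistribution:
    def test_out_star(self, out_star):
        out = degree_distribution(out_star, "out")
        assert out.points == ((6, 1),)
        assert out.n_zero == 6
        inn = degree_distribution(out_star, "in")
        assert inn.points == ((1, 6),)
        assert inn.n_zero == 1

    def test_directed_cycle_in_equals_out(self, triangle):
        assert degree_distribution(triangle, "in").points == ((1, 3),)
        assert degree_distribution(triangle, "out").points == ((1, 3),)

    def test_matches_per_node_count_oracle(self, rng):
        for _ in range(50):
            net = random_network(rng)
            for mode in ("in", "out", "total"):
                dist = degree_distribution(net, mode)
                points, n_zero = degree_counts_oracle(net.nodes, net.edges, mode)
                assert list(dist.points) == points
                assert dist.n_zero == n_zero

    def test_degree_sums_match_edge_count(self, rng):
        for _ in range(20):
            net = random_network(rng)
            for mode in ("in", "out"):
                d = degree_distribution(net, mode)
                assert sum(k * c for k, c in d.points) == net.n_edges


class TestPowerLawFit:
    def test_exact_power_law_is_recovered_exactly(self):
        points = [(k, 100.0 * k**-2.0) for k in range(1, 11)]
        fit = fit_power_law(points)
        assert fit.b == pytest.approx(-2.0, abs=1e-12)
        assert fit.a == pytest.approx(100.0, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_counts_give_zero_exponent(self):
        fit = fit_power_law([(1, 5), (2, 5), (3, 5), (4, 5)])
        assert fit.b == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("b", [-1.5, -2.0, -2.3])
    def test_exponent_recovery_to_machine_precision(self, b):
        points = [(k, 250.0 * k**b) for k in range(1, 16)]
        fit = fit_power_law(points)
        assert abs(fit.b - b) < 1e-9
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-6)

    def test_too_few_points_is_a_fit_error(self):
        with pytest.raises(PowerLawFitError):
            fit_power_law([(1, 10), (2, 5)])

    def test_correlation_is_bounded(self, rng):
        for _ in range(20):
            ks = np.arange(1, 1 + int(rng.integers(3, 10)))
            cs = rng.integers(1, 50, size=len(ks))
            fit = fit_power_law(list(zip(ks.tolist(), cs.tolist())))
            assert -1.0 <= fit.r <= 1.0
            assert 0.0 <= fit.r2 <= 1.0


class TestClustering:
    def test_triangle_is_fully_clustered(self, triangle):
        assert all(node_clustering(triangle, v) == 1.0 for v in "abc")
        assert mean_clustering(triangle) == 1.0

    def test_path_has_zero_clustering(self):
        net = build_network(
            [InteractionRecord("a", "activation", "b"), InteractionRecord("b", "activation", "c")]
        )
        assert node_clustering(net, "b") == 0.0
        assert mean_clustering(net) == 0.0

    def test_matches_neighbor_pair_enumeration_oracle(self, rng):
        for _ in range(50):
            net = random_network(rng)
            for v in net.sorted_nodes():
                assert node_clustering(net, v) == pytest.approx(
                    clustering_oracle(net.nodes, net.edges, v)
                )

    def test_self_loops_do_not_count_as_neighbors(self):
        net = SignalingNetwork(
            frozenset("ab"),
            frozenset({("a", "a", "activation"), ("a", "b", "activation")}),
        )
        assert node_clustering(net, "a") == 0.0

    def test_directed_variant_halves_reciprocal_triangle(self, triangle):
        # each neighbour pair of the 3-cycle is joined in one direction only
        assert node_clustering(triangle, "a", directed=True) == pytest.approx(0.5)

    def test_mean_excluding_low_degree_nodes(self, chain4):
        # only b and c have two neighbours; both unclustered
        assert mean_clustering(chain4, include_low_degree=False) == 0.0


class TestClusteringVsDegree:
    def test_disjoint_triangles_are_unfittable(self):
        recs = []
        for i in range(4):
            a, b, c = f"a{i}", f"b{i}", f"c{i}"
            recs += [
                InteractionRecord(a, "activation", b),
                InteractionRecord(b, "activation", c),
                InteractionRecord(c, "activation", a),
            ]
        points, fit = clustering_vs_degree(build_network(recs))
        assert points == ((2, 1.0),)
        assert fit is None

    def test_tree_is_unfittable(self, out_star):
        points, fit = clustering_vs_degree(out_star)
        assert fit is None


class TestPaths:
    def test_directed_chain(self, chain4):
        stats = path_statistics(chain4, "directed")
        assert stats.char_path_length == pytest.approx(10 / 6)
        assert stats.diameter == 3
        assert stats.finite_pair_count == 6

    def test_complete_bidirectional(self):
        labels = list("abcd")
        edges = {
            (s, t, "activation") for s in labels for t in labels if s != t
        }
        net = SignalingNetwork(frozenset(labels), frozenset(edges))
        stats = path_statistics(net)
        assert stats.char_path_length == 1.0
        assert stats.diameter == 1

    def test_edgeless_network_has_undefined_paths(self):
        net = SignalingNetwork(frozenset("ab"), frozenset())
        stats = path_statistics(net)
        assert stats.char_path_length is None
        assert stats.diameter is None
        assert stats.finite_pair_count == 0

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(100):
            net = random_network(rng)
            for mode in ("directed", "undirected"):
                stats = path_statistics(net, mode)
                cpl, diam, pairs = path_stats_oracle(
                    net.nodes, net.edges, directed=(mode == "directed")
                )
                assert stats.finite_pair_count == pairs
                assert stats.diameter == diam
                if cpl is None:
                    assert stats.char_path_length is None
                else:
                    assert stats.char_path_length == pytest.approx(cpl)


class TestCloseness:
    def test_chain_head_and_tail(self):
        net = build_network(
            [InteractionRecord("a", "activation", "b"), InteractionRecord("b", "activation", "c")]
        )
        assert closeness_centrality(net, "a") == pytest.approx(2 / 3)
        assert closeness_centrality(net, "c") == 0.0

    def test_star_hub_is_maximally_close(self, out_star):
        assert closeness_centrality(out_star, "h") == 1.0

    def test_matches_oracle_and_stays_in_unit_interval(self, rng):
        for _ in range(50):
            net = random_network(rng)
            for v in net.sorted_nodes():
                cc = closeness_centrality(net, v)
                assert 0.0 <= cc <= 1.0
                assert cc == pytest.approx(closeness_oracle(net.nodes, net.edges, v))


class TestHubs:
    def _net(self):
        recs = []
        for i in range(5):
            recs.append(InteractionRecord("A", "activation", f"x{i}"))
            recs.append(InteractionRecord(f"x{i}", "activation", "B"))
        recs.append(InteractionRecord("A", "activation", "B"))
        return build_network(recs)

    def test_top_n(self):
        hubs = rank_hubs(self._net(), top_n=2)
        assert hubs == [("A", 6), ("B", 6)]  # tie broken lexicographically

    def test_tie_rule_smallest_label_first(self, triangle):
        assert rank_hubs(triangle, top_n=1) == [("a", 2)]

    def test_min_links(self):
        hubs = rank_hubs(self._net(), min_links=6)
        assert [h for h, _ in hubs] == ["A", "B"]

    def test_exactly_one_selector(self, triangle):
        with pytest.raises(ValueError):
            rank_hubs(triangle, top_n=1, min_links=1)


class TestSummary:
    def test_directed_cycle_block(self, triangle):
        s = summarize_topology(triangle)
        assert (s.n_nodes, s.n_edges) == (3, 3)
        # the 3-cycle is a triangle under the direction-blind neighbourhood,
        # so every node is fully clustered
        assert s.mean_clustering == 1.0
        assert s.diameter == 2
        assert s.avg_neighbors == pytest.approx(2.0)
        assert s.char_path_length == pytest.approx(1.5)
        assert s.frac_activation == 1.0

    def test_diameter_bounds_char_path_length(self, rng):
        for _ in range(30):
            net = random_network(rng)
            s = summarize_topology(net)
            if s.diameter is not None:
                assert s.diameter >= s.char_path_length

    def test_avg_neighbors_bounded_by_degree_mean(self, rng):
        for _ in range(30):
            net = random_network(rng)
            s = summarize_topology(net)
            assert s.avg_neighbors <= 2 * s.n_edges / s.n_nodes + 1e-12

    def test_sign_fractions_partition_edges(self, rng):
        for _ in range(20):
            net = random_network(rng)
            s = summarize_topology(net)
            assert s.frac_activation + s.frac_inhibition + s.frac_other == pytest.approx(1.0)

    def test_empty_network(self):
        s = summarize_topology(SignalingNetwork(frozenset(), frozenset()))
        assert s.n_nodes == 0
        assert s.diameter is None
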