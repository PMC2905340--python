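import numpy as np
import pytest

from spermnet import (
    GeneratorSpec,
    build_network,
    degree_distribution,
    fit_poisson,
    gen_directed_er,
    gen_directed_pa,
    gen_hierarchical,
    gen_paper_fixture,
    generate,
    mean_clustering,
    clustering_vs_degree,
    rank_hubs,
    summarize_topology,
)


def assert_simple(net):
    assert not any(s == t for s, t, _ in net.edges)  # no self-loops
    assert len({(s, t, sign) for s, t, sign in net.edges}) == net.n_edges


class TestErdosRenyi:
    def test_exact_counts_at_published_scale(self):
        net = gen_directed_er(146, 197, seed=0)
        assert (net.n_nodes, net.n_edges) == (146, 197)
        assert_simple(net)

    def test_seed_reproducibility(self):
        assert gen_directed_er(50, 80, seed=3).equals(gen_directed_er(50, 80, seed=3))

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValueError):
            gen_directed_er(3, 7, seed=0)

    def test_total_degree_is_poisson_like(self):
        gofs = [
            fit_poisson(degree_distribution(gen_directed_er(146, 197, seed=s), "total")).gof_score
            for s in range(10)
        ]
        assert np.mean(gofs) >= 0.8


class TestPreferentialAttachment:
    def test_exact_counts_at_published_scale(self):
        net = gen_directed_pa(146, 197, seed=0)
        assert (net.n_nodes, net.n_edges) == (146, 197)
        assert_simple(net)

    def test_seed_reproducibility(self):
        assert gen_directed_pa(60, 90, seed=5).equals(gen_directed_pa(60, 90, seed=5))

    def test_hubs_dominate_the_median_node(self):
        hits = 0
        for s in range(10):
            net = gen_directed_pa(146, 197, seed=s)
            degrees = sorted(k for _, k in rank_hubs(net, min_links=1))
            median = degrees[len(degrees) // 2]
            if degrees[-1] >= 5 * median:
                hits += 1
        assert hits >= 9

    def test_sparse_request_warns(self):
        with pytest.warns(UserWarning):
            gen_directed_pa(20, 10, seed=1)


class TestHierarchical:
    def test_node_count_arithmetic(self):
        net = gen_hierarchical(levels=2, module_size=4)
        assert net.n_nodes == 16  # 4 modules of 4

    def test_deterministic_without_seed(self):
        assert gen_hierarchical(3, 5).equals(gen_hierarchical(3, 5))

    def test_clustering_falls_with_degree_as_power_law(self):
        net = gen_hierarchical(levels=3, module_size=5)
        _, fit = clustering_vs_degree(net)
        assert fit is not None
        assert fit.b < 0
        assert fit.r2 >= 0.8

    def test_more_clustered_than_er_at_same_size(self):
        net = gen_hierarchical(levels=3, module_size=5)
        er = gen_directed_er(net.n_nodes, net.n_edges, seed=1)
        assert mean_clustering(net) > mean_clustering(er)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_hierarchical(levels=1, module_size=5)
        with pytest.raises(ValueError):
            gen_hierarchical(levels=2, module_size=2)


class TestPaperFixture:
    def test_capacitation_like_contract(self):
        net, records = gen_paper_fixture("capacitation_like", seed=1)
        assert (net.n_nodes, net.n_edges) == (146, 197)
        s = summarize_topology(net)
        assert rank_hubs(net, top_n=1)[0][0] == "[Ca2+]i"
        assert abs(s.frac_activation - 0.95) <= 0.02
        assert 0.20 <= s.frac_k1 <= 0.35
        assert 0.35 <= s.frac_k2 <= 0.50

    @pytest.mark.parametrize(
        "which,n,e",
        [("ar_like", 141, 191), ("intersection_like", 109, 143)],
    )
    def test_other_presets_have_their_sizes(self, which, n, e):
        net, _ = gen_paper_fixture(which, seed=2)
        assert (net.n_nodes, net.n_edges) == (n, e)

    def test_records_rebuild_the_network_exactly(self):
        net, records = gen_paper_fixture("capacitation_like", seed=3)
        assert build_network(records).equals(net)

    def test_seed_reproducibility(self):
        a, _ = gen_paper_fixture("capacitation_like", seed=4)
        b, _ = gen_paper_fixture("capacitation_like", seed=4)
        assert a.equals(b)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            gen_paper_fixture("oocyte_like", seed=0)


class TestGeneratorSpec:
    def test_dispatch(self):
        net = generate(GeneratorSpec(model="er", n_nodes=30, n_edges=40, seed=1))
        assert (net.n_nodes, net.n_edges) == (30, 40)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(model="er", sign_activation_fraction=1.5)

    def test_too_dense_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(model="er", n_nodes=3, n_edges=100)
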