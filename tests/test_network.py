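import numpy as np
import networkx as nx
import pytest

from epispread import (BrainNetwork, node_set_metrics, out_connectivity,
                       rescale_coupling, resect, threshold_network)
from epispread.network import node_betweenness, node_efficiency


class TestRescaleCoupling:
    @pytest.mark.parametrize("r,expected", [(1.0, 1.0), (0.0, 0.5),
                                            (-0.6, 0.2), (-1.0, 0.0)])
    def test_linear_map(self, r, expected):
        assert rescale_coupling(np.array([r]))[0] == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rescale_coupling(np.array([1.2]))

    def test_diagonal_zeroed_on_matrices(self):
        m = rescale_coupling(np.full((3, 3), 0.5))
        assert np.all(np.diag(m) == 0)


class TestThreshold:
    def test_full_density_complete_matrix(self):
        rng = np.random.default_rng(0)
        w = rng.random((6, 6)) * 0.9 + 0.05
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = threshold_network(w, 1.0)
        assert net.mean_degree == pytest.approx(5.0)

    def test_keeps_exactly_the_largest(self):
        w = np.zeros((4, 4))
        vals = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), v in zip(pairs, vals):
            w[i, j] = w[j, i] = v
        net = threshold_network(w, 0.5)
        kept = set(zip(*np.nonzero(np.triu(net.weights, 1))))
        assert kept == {(0, 1), (0, 2), (0, 3)}
        assert net.n_links == 3

    def test_link_count_matches_round(self):
        rng = np.random.default_rng(1)
        n = 30
        w = rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        for theta in (0.05, 0.123, 0.5):
            net = threshold_network(w, theta)
            assert net.n_links == round(theta * n * (n - 1) / 2)

    def test_kappa_around_paper_scale(self):
        """At n = 246 and theta = 0.10 the mean degree is ~24.5 (2L/n)."""
        rng = np.random.default_rng(2)
        n = 246
        w = rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = threshold_network(w, 0.10)
        assert net.mean_degree == pytest.approx(24.6, abs=0.2)

    def test_idempotent_and_nested(self):
        rng = np.random.default_rng(3)
        w = rng.random((12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        n1 = threshold_network(w, 0.2)
        n1b = threshold_network(n1.weights, 0.2)
        assert np.array_equal(n1.weights, n1b.weights)
        n2 = threshold_network(w, 0.5)
        links1 = set(zip(*np.nonzero(np.triu(n1.weights, 1))))
        links2 = set(zip(*np.nonzero(np.triu(n2.weights, 1))))
        assert links1 <= links2

    def test_zero_links_rejected(self):
        w = np.zeros((4, 4))
        with pytest.raises(ValueError):
            threshold_network(w, 0.5)

    def test_tie_break_deterministic(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0)
        nets = [threshold_network(w, 0.5) for _ in range(3)]
        for net in nets[1:]:
            assert np.array_equal(net.weights, nets[0].weights)
        # lexicographically first pairs win the tie
        kept = set(zip(*np.nonzero(np.triu(nets[0].weights, 1))))
        assert kept == {(0, 1), (0, 2), (0, 3)}


class TestMetrics:
    def test_star_hub(self, star5):
        m = node_set_metrics(star5, [0])
        assert m.out_connectivity == 4
        assert m.clustering == 0.0
        assert m.size == 1

    def test_path_betweenness(self, path3):
        m = node_set_metrics(path3, [1])
        # one shortest path (A-C) crosses B; normalized by the single pair
        assert m.betweenness == pytest.approx(1.0)

    def test_triangle_clustering(self, triangle):
        for v in range(3):
            assert node_set_metrics(triangle, [v]).clustering == pytest.approx(1.0)

    def test_unit_weight_matches_unweighted_textbook(self):
        g = nx.erdos_renyi_graph(8, 0.5, seed=4)
        w = nx.to_numpy_array(g)
        net = BrainNetwork(w)
        bc = node_betweenness(net)
        bc_ref = nx.betweenness_centrality(g, normalized=True)
        assert np.allclose(bc, [bc_ref[i] for i in range(8)])
        eff = node_efficiency(net)
        eff_ref = [sum(1 / d for t, d in
                       nx.single_source_shortest_path_length(g, s).items()
                       if t != s) / 7 for s in range(8)]
        assert np.allclose(eff, eff_ref)

    def test_whole_network_averages_only(self, triangle):
        m = node_set_metrics(triangle)
        assert m.out_connectivity is None and m.betweenness is None
        assert m.clustering == pytest.approx(1.0)
        assert m.efficiency == pytest.approx(1.0)

    def test_empty_set_rejected(self, triangle):
        with pytest.raises(ValueError):
            node_set_metrics(triangle, [])

    def test_path_efficiency(self, path3):
        eff = node_efficiency(path3)
        # end node: 1/1 and 1/2 to the others
        assert eff[0] == pytest.approx((1 + 0.5) / 2)


class TestResect:
    def test_empty_resection_is_identity(self, star5):
        cut = resect(star5, [])
        assert np.array_equal(cut.weights, star5.weights)

    def test_hub_resection_empties_star(self, star5):
        cut = resect(star5, [0])
        assert cut.n_links == 0
        assert cut.n_nodes == 5  # nodes stay

    def test_resected_out_connectivity_zero(self, small_edr):
        net, _ = small_edr
        thr = threshold_network(net.weights, 0.2)
        ra = [3, 7, 9]
        cut = resect(thr, ra)
        assert out_connectivity(cut, ra) == 0

    def test_metrics_match_fresh_network(self, small_edr):
        net, _ = small_edr
        thr = threshold_network(net.weights, 0.2)
        cut = resect(thr, [0, 1])
        fresh = BrainNetwork(cut.weights.copy())
        a = node_set_metrics(cut, [5, 6])
        b = node_set_metrics(fresh, [5, 6])
        assert a == b

    def test_degree_never_increases(self, small_edr):
        net, _ = small_edr
        thr = threshold_network(net.weights, 0.3)
        cut = resect(thr, [2, 4])
        deg0 = (thr.weights > 0).sum(axis=1)
        deg1 = (cut.weights > 0).sum(axis=1)
        assert np.all(deg1 <= deg0)
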