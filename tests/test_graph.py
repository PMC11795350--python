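import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegwmnet as ew
from eegwmnet.graph import (
    betweenness,
    clustering,
    communities,
    hubness,
    lattice_reference,
    path_metrics,
    randomized_reference,
    small_world,
    threshold_proportional,
)
from oracles import brute_betweenness, brute_clustering, brute_path_metrics


def _graph_from(weights, proportion=1.0):
    w = np.asarray(weights, dtype=float)
    return ew.ThresholdedGraph(
        weights=w, retained_edges=int((np.triu(w, 1) > 0).sum()), proportion=proportion
    )


def _random_weighted(rng, n, density=0.6):
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(len(iu[0])) < density
    vals = rng.uniform(0.2, 2.0, len(iu[0])) * mask
    w[iu] = vals
    w += w.T
    return w


class TestThreshold:
    def test_default_30_node_threshold_keeps_239_edges(self):
        rng = np.random.default_rng(0)
        w = _random_weighted(rng, 30, density=1.0)
        tg = threshold_proportional(w, 0.55)
        assert tg.retained_edges == 239  # floor(0.55 * 435)
        assert int((np.triu(tg.weights, 1) > 0).sum()) == 239

    def test_full_proportion_is_identity(self):
        rng = np.random.default_rng(1)
        w = _random_weighted(rng, 12, density=1.0)
        tg = threshold_proportional(w, 1.0)
        np.testing.assert_array_equal(tg.weights, w)

    def test_five_node_toy_keeps_all_nonzero(self):
        w = np.zeros((5, 5))
        for (i, j), v in zip([(0, 1), (0, 2), (1, 3), (2, 4), (3, 4)], [5, 4, 3, 2, 1]):
            w[i, j] = w[j, i] = v
        tg = threshold_proportional(w, 0.55)  # floor(5.5) = 5
        assert tg.retained_edges == 5
        np.testing.assert_array_equal(tg.weights, w)

    def test_retained_weights_unchanged(self):
        rng = np.random.default_rng(2)
        w = _random_weighted(rng, 10, density=1.0)
        tg = threshold_proportional(w, 0.5)
        nz = tg.weights > 0
        np.testing.assert_array_equal(tg.weights[nz], w[nz])

    def test_asymmetric_input_rejected(self):
        w = np.arange(16, dtype=float).reshape(4, 4)
        with pytest.raises(ValueError):
            threshold_proportional(w, 0.5)

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_edge_count_exact_for_any_matrix(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 15))
        w = _random_weighted(rng, n, density=1.0)
        # force some ties at the cut
        iu = np.triu_indices(n, 1)
        w[iu] = np.round(w[iu], 1)
        w = np.triu(w, 1) + np.triu(w, 1).T
        p = float(rng.uniform(0.1, 1.0))
        tg = threshold_proportional(w, p)
        expected = int(np.floor(p * len(iu[0])))
        assert tg.retained_edges == expected
        assert int((np.triu(tg.weights, 1) != 0).sum()) <= expected


class TestHandComputedToys:
    def test_three_node_path(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        pm = path_metrics(_graph_from(w))
        assert pm.cpl == pytest.approx(4 / 3)
        assert pm.global_efficiency == pytest.approx(5 / 6)
        assert not pm.disconnected

    def test_complete_unit_graph(self):
        w = 1.0 - np.eye(6)
        pm = path_metrics(_graph_from(w))
        assert pm.cpl == pytest.approx(1.0)
        assert pm.global_efficiency == pytest.approx(1.0)
        assert betweenness(_graph_from(w)) == pytest.approx(np.zeros(6))

    def test_two_disconnected_dyads(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        pm = path_metrics(_graph_from(w))
        assert pm.cpl == pytest.approx(1.0)
        assert pm.global_efficiency == pytest.approx(1 / 3)
        assert pm.disconnected

    def test_star_centre_betweenness_is_one(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        bc = betweenness(_graph_from(w))
        assert bc[0] == pytest.approx(1.0)
        assert bc[1:] == pytest.approx(np.zeros(4))

    def test_triangle_clustering_is_one_star_is_zero(self):
        tri = 1.0 - np.eye(3)
        cc, mean = clustering(_graph_from(tri))
        assert cc == pytest.approx(np.ones(3))
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 1.0
        cc_s, _ = clustering(_graph_from(star))
        assert cc_s == pytest.approx(np.zeros(5))

    def test_two_cliques_modularity_half(self):
        w = np.zeros((8, 8))
        w[:4, :4] = 1.0 - np.eye(4)
        w[4:, 4:] = 1.0 - np.eye(4)
        module_id, q, _ = communities(_graph_from(w), seed=0)
        assert len(set(module_id)) == 2
        assert len(set(module_id[:4])) == 1 and len(set(module_id[4:])) == 1
        assert q == pytest.approx(0.5)

    def test_complete_graph_single_community(self):
        w = 1.0 - np.eye(10)
        module_id, _, module_z = communities(_graph_from(w), seed=1)
        assert len(set(module_id)) == 1
        assert module_z == pytest.approx(np.zeros(10))  # uniform module

    def test_louvain_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(4)
        w = _random_weighted(rng, 20)
        g = _graph_from(w)
        a = communities(g, seed=42)
        b = communities(g, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]


class TestHubness:
    def test_all_strength_in_own_module_gives_zero(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0 - np.eye(3)
        w[3:, 3:] = 1.0 - np.eye(3)
        part, flags = hubness(_graph_from(w), np.array([0, 0, 0, 1, 1, 1]))
        assert part == pytest.approx(np.zeros(6))
        assert not flags.any()

    def test_equal_split_across_two_modules_gives_half(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        part, flags = hubness(_graph_from(w), np.array([0, 0, 1]))
        assert part[0] == pytest.approx(0.5)
        assert flags[0]

    def test_participation_bounded_by_module_count(self):
        rng = np.random.default_rng(5)
        w = _random_weighted(rng, 15)
        g = _graph_from(w)
        module_id, _, _ = communities(g, seed=3)
        part, _ = hubness(g, module_id)
        n_mod = len(set(module_id))
        assert np.all(part >= 0)
        assert np.all(part <= 1 - 1 / n_mod + 1e-12)

    def test_zero_strength_node_participation_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        part, _ = hubness(_graph_from(w), np.array([0, 0, 1, 1]))
        assert part[2] == 0.0 and part[3] == 0.0


class TestLattice:
    def test_sixty_edges_make_a_degree_four_ring(self):
        lat = lattice_reference(30, 60)
        deg = (lat.weights > 0).sum(axis=1)
        assert np.all(deg == 4)

    def test_edge_count_conserved_at_239(self):
        lat = lattice_reference(30, 239)
        assert int(np.triu(lat.weights, 1).sum()) == 239

    def test_k2_ring_mean_clustering_half(self):
        lat = lattice_reference(30, 60)  # k = 2 per side
        _, mean_cc = clustering(lat)
        assert mean_cc == pytest.approx(0.5)  # 3(k-1)/(2(2k-1))

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValueError):
            lattice_reference(30, 436)


class TestSmallWorld:
    def test_self_reference_gives_unit_ratios(self):
        lat = lattice_reference(30, 239)
        sw = small_world(lat, reference=lat)
        assert sw.gamma == pytest.approx(1.0)
        assert sw.lam == pytest.approx(1.0)
        assert sw.sigma == pytest.approx(1.0)

    def test_sigma_definitionally_gamma_over_lambda(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            w = _random_weighted(rng, 30, density=0.8)
            tg = threshold_proportional(w, 0.55)
            sw = small_world(tg)
            assert sw.sigma == sw.gamma / sw.lam

    def test_reference_mismatch_rejected(self):
        tg = threshold_proportional(1.0 - np.eye(30), 0.55)
        with pytest.raises(ValueError):
            small_world(tg, reference=lattice_reference(30, 100))

    def test_random_graph_is_its_own_null_in_conventional_mode(self):
        """Erdos-Renyi graphs against their rewired ensemble: sigma ~ 1."""
        sigmas = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            w = (rng.random((30, 30)) < 0.3).astype(float)
            w = np.triu(w, 1)
            w += w.T
            tg = _graph_from(w)
            sw = small_world(tg, convention="watts_strogatz", seed=seed)
            sigmas.append(sw.sigma)
        assert abs(np.mean(sigmas) - 1.0) < 0.1


class TestOracleEquivalence:
    def test_fifty_seeded_graphs_match_brute_force(self):
        """L, E_glob, bc, cc agree with independent brute-force code to 1e-9."""
        rng = np.random.default_rng(123)
        for trial in range(50):
            n = int(rng.integers(4, 9))
            w = _random_weighted(rng, n, density=float(rng.uniform(0.4, 0.9)))
            if not (w > 0).any():
                continue
            g = _graph_from(w)
            pm = path_metrics(g)
            cpl_o, geff_o = brute_path_metrics(w)
            assert pm.cpl == pytest.approx(cpl_o, abs=1e-9)
            assert pm.global_efficiency == pytest.approx(geff_o, abs=1e-9)
            np.testing.assert_allclose(betweenness(g), brute_betweenness(w), atol=1e-9)
            cc, _ = clustering(g)
            np.testing.assert_allclose(cc, brute_clustering(w), atol=1e-9)


class TestScaleBehaviour:
    def test_uniform_weight_scaling(self):
        rng = np.random.default_rng(9)
        w = _random_weighted(rng, 18, density=0.7)
        g1, g2 = _graph_from(w), _graph_from(3.5 * w)
        pm1, pm2 = path_metrics(g1), path_metrics(g2)
        assert pm2.cpl == pytest.approx(pm1.cpl / 3.5)
        assert pm2.global_efficiency == pytest.approx(pm1.global_efficiency * 3.5)
        bc1, bc2 = betweenness(g1), betweenness(g2)
        np.testing.assert_array_equal(np.argsort(bc1), np.argsort(bc2))
        m1, _, _ = communities(g1, seed=7)
        m2, _, _ = communities(g2, seed=7)
        np.testing.assert_array_equal(m1, m2)
        p1, _ = hubness(g1, m1)
        p2, _ = hubness(g2, m2)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_edgeless_graph_raises(self):
        with pytest.raises(ValueError):
            path_metrics(_graph_from(np.zeros((5, 5))))


def test_randomized_reference_preserves_degrees():
    rng = np.random.default_rng(11)
    w = (rng.random((20, 20)) < 0.3).astype(float)
    w = np.triu(w, 1)
    w += w.T
    g = _graph_from(w)
    # rewiring conserves each node's degree, so total edges are conserved
    l_rand, c_rand = randomized_reference(g, seed=5, n_realizations=3)
    assert l_rand > 0 and 0 <= c_rand <= 1
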