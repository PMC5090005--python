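"""Graph efficiency metrics against brute-force oracles; null-model properties."""

import numpy as np
import pytest

import effconn as ec
from effconn.efficiency import (
    characteristic_path_length,
    clustering_coefficient,
    rewired_null,
)

from _oracles import (
    bf_clustering,
    bf_global_efficiency,
    bf_local_efficiency,
    bf_nodal_global_efficiency,
    bf_nodal_local_efficiency,
    bf_path_length,
    bf_shortest_paths,
    random_weighted_graph,
)


def _graph(w):
    return ec.WeightedGraph(np.asarray(w, dtype=float), sparsity=0.5)


PATH_ABC = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
TRIANGLE = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)


class TestShortestPaths:
    def test_unit_path_length_two(self):
        d = ec.shortest_weighted_paths(_graph(PATH_ABC))
        assert d[0, 2] == pytest.approx(2.0)

    def test_single_edge_inverse_weight(self):
        w = np.array([[0, 0.5], [0.5, 0]])
        assert ec.shortest_weighted_paths(_graph(w))[0, 1] == pytest.approx(2.0)

    def test_disconnected_pair_infinite(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        d = ec.shortest_weighted_paths(_graph(w))
        assert np.isinf(d[0, 2])

    def test_literal_length_option(self):
        w = np.array([[0, 0.5], [0.5, 0]])
        d = ec.shortest_weighted_paths(_graph(w), length="literal")
        assert d[0, 1] == pytest.approx(0.5)


class TestHandExamples:
    def test_path_nodal_efficiencies(self):
        eg, el = ec.nodal_efficiencies(_graph(PATH_ABC))
        np.testing.assert_allclose(eg, [0.75, 1.0, 0.75])
        np.testing.assert_allclose(el, 0.0)

    def test_triangle_everything_is_one(self):
        eg, el = ec.nodal_efficiencies(_graph(TRIANGLE))
        np.testing.assert_allclose(eg, 1.0)
        np.testing.assert_allclose(el, 1.0)
        gm = ec.global_metrics(_graph(TRIANGLE))
        assert (gm.e_glob, gm.c_w, gm.l_w) == pytest.approx((1.0, 1.0, 1.0))

    def test_path_global_metrics(self):
        gm = ec.global_metrics(_graph(PATH_ABC))
        assert gm.e_glob == pytest.approx(5 / 6)
        assert gm.c_w == pytest.approx(0.0)
        assert gm.l_w == pytest.approx(1.2)

    def test_complete_unit_graph_attains_one(self):
        w = np.ones((6, 6)) - np.eye(6)
        gm = ec.global_metrics(_graph(w))
        assert (gm.e_glob, gm.e_loc, gm.c_w) == pytest.approx((1.0, 1.0, 1.0))

    def test_edgeless_graph(self):
        gm = ec.global_metrics(_graph(np.zeros((4, 4))))
        assert (gm.e_glob, gm.e_loc, gm.c_w) == (0.0, 0.0, 0.0)
        assert np.isinf(gm.l_w)


class TestOracleEquivalence:
    """All metric formulas agree with exhaustive path enumeration to 1e-10."""

    N_GRAPHS = 200

    def test_random_graphs_match_bruteforce(self):
        rng = np.random.default_rng(42)
        max_err = 0.0
        for _ in range(self.N_GRAPHS):
            n = int(rng.integers(4, 9))
            w = random_weighted_graph(rng, n, p=float(rng.uniform(0.3, 0.9)))
            g = _graph(w)
            d = ec.shortest_weighted_paths(g)
            d_bf = bf_shortest_paths(w)
            finite = np.isfinite(d_bf)
            assert (np.isfinite(d) == finite).all()
            max_err = max(max_err, np.abs(d[finite] - d_bf[finite]).max())
            eg, el = ec.nodal_efficiencies(g)
            gm = ec.global_metrics(g)
            max_err = max(
                max_err,
                np.abs(eg - bf_nodal_global_efficiency(w)).max(),
                np.abs(el - bf_nodal_local_efficiency(w)).max(),
                abs(gm.e_glob - bf_global_efficiency(w)),
                abs(gm.e_loc - bf_local_efficiency(w)),
                abs(gm.c_w - bf_clustering(w)),
            )
            lw_bf = bf_path_length(w)
            if np.isfinite(lw_bf):
                max_err = max(max_err, abs(gm.l_w - lw_bf))
        assert max_err < 1e-10

    def test_lw_eglob_identity_on_connected_graphs(self):
        """Harmonic path length is the reciprocal of global efficiency."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 50:
            n = int(rng.integers(4, 12))
            w = random_weighted_graph(rng, n, p=0.7)
            g = _graph(w)
            d = ec.shortest_weighted_paths(g)
            if not np.isfinite(d).all():
                continue
            gm = ec.global_metrics(g)
            assert gm.l_w * gm.e_glob == pytest.approx(1.0, abs=1e-12)
            checked += 1


class TestInvariants:
    def test_adding_edge_never_decreases_global_efficiency(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(5, 10))
            w = random_weighted_graph(rng, n, p=0.4)
            zeros = np.argwhere(np.triu(w == 0, 1))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = rng.uniform(0.1, 1.0)
            e1 = ec.global_metrics(_graph(w)).e_glob
            e2 = ec.global_metrics(_graph(w2)).e_glob
            assert e2 >= e1 - 1e-12

    def test_efficiencies_in_unit_interval_for_unit_weights(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            w = random_weighted_graph(rng, 8, p=0.5)
            g = _graph(w)
            eg, el = ec.nodal_efficiencies(g)
            gm = ec.global_metrics(g)
            assert ((eg >= 0) & (eg <= 1)).all()
            assert ((el >= 0) & (el <= 1)).all()
            assert 0 <= gm.e_glob <= 1 and 0 <= gm.e_loc <= 1


class TestNullModels:
    def _ring(self, n=24):
        w = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                w[i, (i + d) % n] = w[(i + d) % n, i] = 1.0
        return _graph(w)

    def test_null_preserves_degree_sequence_and_weights(self, rng):
        g = self._ring()
        null, flag = rewired_null(g, rng)
        assert not flag
        np.testing.assert_array_equal((null > 0).sum(0), g.degree)
        iu = np.triu_indices(g.n_nodes, 1)
        np.testing.assert_allclose(
            np.sort(null[iu][null[iu] > 0]), np.sort(g.weights[iu][g.weights[iu] > 0])
        )
        # null of a null keeps the same degree sequence
        null2, _ = rewired_null(ec.WeightedGraph(null, 0.1), rng)
        np.testing.assert_array_equal((null2 > 0).sum(0), g.degree)

    def test_ring_lattice_gamma_much_greater_than_one(self):
        sw = ec.null_model_metrics(self._ring(), n_rand=100, seed=5)
        assert sw.gamma > 1.5

    def test_dense_random_graph_gamma_lambda_near_one(self):
        rng = np.random.default_rng(9)
        w = random_weighted_graph(rng, 60, p=0.3)
        g = _graph(w)
        sw = ec.null_model_metrics(g, n_rand=100, seed=2)
        c_real = clustering_coefficient(w)
        l_real = characteristic_path_length(ec.shortest_weighted_paths(g))
        assert abs(c_real - sw.c_w_rand.mean()) < 3 * sw.c_w_rand.std(ddof=1)
        assert abs(l_real - sw.l_w_rand.mean()) < 3 * sw.l_w_rand.std(ddof=1)

    def test_too_sparse_graph_flagged(self, rng):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.warns(UserWarning, match="too sparse"):
            sw = ec.null_model_metrics(_graph(w), n_rand=3, seed=0)
        assert sw.degenerate

    def test_seeded_reproducibility(self):
        g = self._ring()
        a = ec.null_model_metrics(g, n_rand=10, seed=3)
        b = ec.null_model_metrics(g, n_rand=10, seed=3)
        np.testing.assert_array_equal(a.c_w_rand, b.c_w_rand)
        np.testing.assert_array_equal(a.l_w_rand, b.l_w_rand)

    def test_cross_check_against_networkx_rewiring(self, rng):
        """networkx double_edge_swap confirms our null C_w distribution."""
        import networkx as nx

        g = self._ring(20)
        ours = ec.null_model_metrics(g, n_rand=50, seed=1)
        nx_c = []
        iu = np.triu_indices(20, 1)
        weights = g.weights[iu][g.weights[iu] > 0]
        for k in range(50):
            G = nx.from_numpy_array((g.weights > 0).astype(int))
            nx.double_edge_swap(G, nswap=10 * G.number_of_edges(), max_tries=10_000, seed=k)
            null = np.zeros((20, 20))
            perm = np.random.default_rng(k).permutation(len(weights))
            for (a, b), wt in zip(G.edges(), weights[perm]):
                null[a, b] = null[b, a] = wt
            nx_c.append(clustering_coefficient(null))
        # the two null ensembles estimate the same mean clustering
        se = np.hypot(
            ours.c_w_rand.std(ddof=1) / np.sqrt(50), np.std(nx_c, ddof=1) / np.sqrt(50)
        )
        assert abs(ours.c_w_rand.mean() - np.mean(nx_c)) < 4 * se


class TestIntegration:
    def test_constant_curve_rectangle_area(self):
        levels = ec.SparsityGrid().levels
        curve = np.full((1, len(levels)), 3.0)
        area = ec.integrate_curves(curve, levels)[0]
        assert area == pytest.approx(0.48 * 3.0)

    def test_triangular_curve_matches_numeric_oracle(self):
        levels = ec.SparsityGrid().levels
        curve = np.linspace(0, 1, len(levels))[None, :]
        area = ec.integrate_curves(curve, levels)[0]
        assert area == pytest.approx(np.trapezoid(curve[0], levels))
        assert area == pytest.approx(0.24, abs=0.01)

    def test_single_level_integral_is_value(self):
        assert ec.integrate_curves(np.array([[2.5]]), np.array([0.1]))[0] == 2.5

    def test_riemann_option(self):
        levels = np.array([0.0, 0.5, 1.0])
        curve = np.array([[1.0, 2.0, 3.0]])
        assert ec.integrate_curves(curve, levels, method="riemann")[0] == pytest.approx(1.5)

    def test_normalization_means_one_and_equal_nodes_give_one(self):
        np.testing.assert_allclose(ec.normalize_within_subject(np.full(5, 2.2)), 1.0)
        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 1.5, 40)
        assert ec.normalize_within_subject(x).mean() == pytest.approx(1.0)

    def test_all_zero_metrics_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ec.normalize_within_subject(np.zeros(4))
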