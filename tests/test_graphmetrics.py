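import numpy as np
import pytest

import fnirsnet.graphmetrics as gm
from conftest import random_adjacency

from _oracles import (
    assortativity_oracle,
    betweenness_oracle,
    betweenness_path_enumeration_oracle,
    clustering_oracle,
    efficiency_oracle,
    floyd_warshall_oracle,
    lp_oracle,
    ols_slope_oracle,
)


def complete(n):
    a = np.ones((n, n), dtype=bool)
    np.fill_diagonal(a, False)
    return a


def star(n):
    a = np.zeros((n, n), dtype=bool)
    a[0, 1:] = a[1:, 0] = True
    return a


def path(n):
    a = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = True
    return a


def ring_lattice(n, k):
    a = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            a[i, j] = a[j, i] = True
    return a


def watts_strogatz(n, k, p, rng):
    a = ring_lattice(n, k)
    iu, ju = np.nonzero(np.triu(a, 1))
    for i, j in zip(iu, ju):
        if rng.random() < p:
            free = [m for m in range(n) if m != i and not a[i, m]]
            if free:
                m = int(rng.choice(free))
                a[i, j] = a[j, i] = False
                a[i, m] = a[m, i] = True
    return a


class TestClosedForms:
    def test_complete_graph(self):
        a = complete(14)
        _, cp = gm.clustering(a)
        assert cp == 1.0
        assert gm.char_path_length(a) == 1.0
        eg, ne, _, eloc = gm.efficiencies(a)
        assert eg == 1.0 and np.all(ne == 1.0) and eloc == 1.0
        assert np.all(gm.betweenness(a) == 0.0)
        assert np.isnan(gm.assortativity(a))  # regular graph: undefined

    def test_star_graph(self):
        a = star(5)
        ncp, cp = gm.clustering(a)
        assert cp == 0.0
        bc = gm.betweenness(a)
        assert bc[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert np.all(bc[1:] == 0.0)
        assert gm.assortativity(a) == pytest.approx(-1.0)
        assert np.array_equal(gm.degrees(a), [4, 1, 1, 1, 1])

    def test_path_graphs(self):
        assert gm.char_path_length(path(4)) == pytest.approx(10 / 6)
        eg, _, _, _ = gm.efficiencies(path(3))
        assert eg == pytest.approx(5 / 6)
        d = gm.shortest_paths(path(4))
        assert d[0, 3] == 3

    def test_lp_at_least_one_with_any_edge(self, rng):
        for _ in range(20):
            a = random_adjacency(rng)
            if a.any():
                assert gm.char_path_length(a) >= 1.0

    def test_hierarchy_exact_power_law(self):
        # NCp_i = Dc_i^(-1) exactly -> b = 1 from the log-log regression
        k = np.array([2.0, 3.0, 4.0, 6.0])
        ncp = 1.0 / k
        assert gm.hierarchy_slope(ncp, k) == pytest.approx(1.0)

    def test_hierarchy_undefined_without_degree_variance(self):
        assert np.isnan(gm.hierarchy_slope(np.array([0.5, 0.5]), np.array([3.0, 3.0])))
        assert np.isnan(gm.hierarchy(complete(5)))

    def test_disconnected_pairs_excluded_from_lp(self):
        a = np.zeros((4, 4), dtype=bool)
        a[0, 1] = a[1, 0] = True  # one edge, two isolated nodes
        assert gm.char_path_length(a) == 1.0
        eg, _, _, _ = gm.efficiencies(a)
        assert eg == pytest.approx(2 / 12)  # only the connected ordered pair


class TestOracleEquivalence:
    def test_all_metrics_match_independent_oracles(self, rng):
        for _ in range(200):
            a = random_adjacency(rng)
            assert np.array_equal(gm.degrees(a), a.sum(axis=1))
            ncp, cp = gm.clustering(a)
            exp_ncp = clustering_oracle(a)
            assert np.allclose(ncp, exp_ncp, atol=1e-10)
            assert cp == pytest.approx(exp_ncp.mean(), abs=1e-10)
            d = gm.shortest_paths(a)
            assert np.array_equal(d, floyd_warshall_oracle(a))
            lp = gm.char_path_length(a)
            exp_lp = lp_oracle(a)
            assert (np.isnan(lp) and np.isnan(exp_lp)) or lp == pytest.approx(exp_lp, abs=1e-10)
            eg, ne, nle, eloc = gm.efficiencies(a)
            oeg, one, onle, oeloc = efficiency_oracle(a)
            assert eg == pytest.approx(oeg, abs=1e-10)
            assert np.allclose(ne, one, atol=1e-10)
            assert np.allclose(nle, onle, atol=1e-10)
            assert eloc == pytest.approx(oeloc, abs=1e-10)
            assert np.allclose(gm.betweenness(a), betweenness_oracle(a), atol=1e-10)
            r = gm.assortativity(a)
            orr = assortativity_oracle(a)
            assert (np.isnan(r) and np.isnan(orr)) or r == pytest.approx(orr, abs=1e-8)
            b = gm.hierarchy(a)
            k = gm.degrees(a).astype(float)
            elig = (k >= 2) & (ncp > 0)
            if elig.sum() >= 2 and np.ptp(np.log(k[elig])) > 0:
                exp_b = -ols_slope_oracle(np.log(k[elig]), np.log(ncp[elig]))
                assert b == pytest.approx(exp_b, abs=1e-10)
            else:
                assert np.isnan(b)

    def test_betweenness_matches_path_enumeration(self, rng):
        for _ in range(30):
            a = random_adjacency(rng, n=int(rng.integers(5, 11)))
            assert np.allclose(
                gm.betweenness(a), betweenness_path_enumeration_oracle(a), atol=1e-9
            )

    def test_handshake_identity(self, rng):
        for _ in range(20):
            a = random_adjacency(rng)
            assert gm.degrees(a).sum() == a.sum()


class TestInvarianceAndMonotonicity:
    def test_isomorphism_invariance(self, rng):
        for _ in range(20):
            a = random_adjacency(rng, n=12)
            perm = rng.permutation(12)
            ap = a[np.ix_(perm, perm)]
            res = gm.network_metrics(a, n_rand=0)
            resp = gm.network_metrics(ap, n_rand=0)
            for m in ("Cp", "Lp", "Eloc", "Eg", "r", "b"):
                x, y = res["global"][m], resp["global"][m]
                assert (np.isnan(x) and np.isnan(y)) or x == pytest.approx(y, abs=1e-9)
            for m in ("NCp", "Ne", "NLe", "Dc", "Bc"):
                assert np.allclose(res["nodal"][m][perm], resp["nodal"][m], atol=1e-9)

    def test_adding_edge_improves_paths_and_efficiency(self, rng):
        for _ in range(30):
            a = random_adjacency(rng, n=10, p=0.3)
            free = np.argwhere(~a & ~np.eye(10, dtype=bool))
            free = free[free[:, 0] < free[:, 1]]
            if len(free) == 0 or not a.any():
                continue
            i, j = free[rng.integers(0, len(free))]
            b = a.copy()
            b[i, j] = b[j, i] = True
            eg_a = gm.efficiencies(a)[0]
            eg_b = gm.efficiencies(b)[0]
            assert eg_b >= eg_a - 1e-12
            # Lp on the same connected pair set cannot increase; compare on
            # graphs where both are fully connected to keep the pair sets equal
            da, db = gm.shortest_paths(a), gm.shortest_paths(b)
            if np.isfinite(da).all():
                assert gm.char_path_length(b) <= gm.char_path_length(a) + 1e-12
            assert np.all(db <= da)


class TestRandomReferences:
    def test_degree_sequence_and_edge_count_preserved(self, rng):
        a = random_adjacency(rng, n=14, p=0.3)
        refs = gm.random_references(a, n_rand=25, seed=3)
        for r in refs:
            assert np.array_equal(r.sum(axis=1), a.sum(axis=1))
            assert r.sum() == a.sum()
            assert np.array_equal(r, r.T) and not r.diagonal().any()

    def test_rewiring_reduces_lattice_clustering(self):
        a = ring_lattice(14, 4)
        refs = gm.random_references(a, n_rand=100, seed=0)
        cp0 = gm.clustering(a)[1]
        cp_mean = np.mean([gm.clustering(r)[1] for r in refs])
        assert cp_mean < cp0

    def test_seed_determinism(self, rng):
        a = random_adjacency(rng, n=12, p=0.4)
        r1 = gm.random_references(a, n_rand=5, seed=11)
        r2 = gm.random_references(a, n_rand=5, seed=11)
        assert all(np.array_equal(x, y) for x, y in zip(r1, r2))

    def test_too_few_edges_raises(self):
        a = np.zeros((4, 4), dtype=bool)
        a[0, 1] = a[1, 0] = True
        with pytest.raises(ValueError):
            gm.random_references(a, 5, seed=0)


class TestSmallWorld:
    def test_self_reference_normalizes_to_one(self, rng):
        a = random_adjacency(rng, n=10, p=0.4)
        gamma, lam, sigma = gm.small_world(a, [a])
        assert gamma == pytest.approx(1.0)
        assert lam == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)

    def test_ws_ring_is_small_world(self, rng):
        sigmas = []
        for k in range(5):
            a = watts_strogatz(14, 4, 0.1, rng)
            refs = gm.random_references(a, n_rand=100, seed=k)
            sigmas.append(gm.small_world(a, refs)[2])
        assert np.nanmean(sigmas) > 1.0

    def test_empty_refs_rejected(self, rng):
        with pytest.raises(ValueError):
            gm.small_world(random_adjacency(rng), [])


class TestAUC:
    thresholds = np.round(np.arange(0.15, 0.501, 0.05), 2)

    def test_constant_curve(self):
        v = 0.7
        assert gm.auc_over_thresholds(np.full(8, v), self.thresholds) == pytest.approx(0.35 * v)

    def test_linear_ramp(self):
        vals = np.linspace(0, 1, 8)
        assert gm.auc_over_thresholds(vals, self.thresholds) == pytest.approx(0.175)

    def test_matches_fine_grid_quadrature_for_polynomials(self):
        coeffs = [0.3, -1.2, 2.0]
        poly = np.polynomial.polynomial.Polynomial(coeffs)
        vals = poly(self.thresholds)
        fine = np.linspace(0.15, 0.50, 20001)
        expected = np.trapezoid(poly(fine), fine)
        # trapezoid on 8 points is exact for degree <= 1; the quadratic term
        # carries the known O(h^2) discretization error
        h = 0.05
        bound = h**2 / 12 * abs(2 * coeffs[2]) * 0.35
        assert abs(gm.auc_over_thresholds(vals, self.thresholds) - expected) <= bound * 1.01
        linear = np.polynomial.polynomial.Polynomial(coeffs[:2])
        assert gm.auc_over_thresholds(linear(self.thresholds), self.thresholds) == pytest.approx(
            np.trapezoid(linear(fine), fine), rel=1e-10
        )

    def test_missing_value_propagates(self):
        vals = np.full(8, 1.0)
        vals[3] = np.nan
        assert np.isnan(gm.auc_over_thresholds(vals, self.thresholds))

    def test_bad_thresholds_raise(self):
        with pytest.raises(ValueError):
            gm.auc_over_thresholds([1.0], [0.15])


class TestMetricSet:
    def test_sweep_produces_79_auc_values(self, rng):
        from fnirsnet.connectivity import ConnectivityMatrix

        z = np.abs(rng.normal(size=(14, 14)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        ms = gm.compute_metric_set(ConnectivityMatrix(z, state="task", subject_id="s"),
                                   n_rand=5, seed=0)
        n_values = len(ms.global_auc) + ms.nodal_auc.size
        assert n_values == 79
        assert ms.global_curves.shape == (8, 9)
        # Sigma = Gamma / Lambda wherever both are finite
        g, l, s = (ms.global_curves[m] for m in ("Gamma", "Lambda", "Sigma"))
        finite = np.isfinite(g) & np.isfinite(l)
        assert np.allclose(s[finite], g[finite] / l[finite])
        # Dc AUCs are nonnegative; bounded metrics stay in [0, 1]
        for m in ("Cp", "Eloc", "Eg"):
            assert np.all((ms.global_curves[m] >= 0) & (ms.global_curves[m] <= 1))
        finite_r = ms.global_curves["r"].dropna()
        assert np.all((finite_r >= -1) & (finite_r <= 1))
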