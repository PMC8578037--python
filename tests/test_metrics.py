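"""Graph-topology metrics against closed forms and brute-force oracles."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    oracle_best_modularity,
    oracle_betweenness,
    oracle_clustering,
    oracle_efficiency,
    oracle_path_length,
)
from subscn.metrics import (
    DisconnectedGraphError,
    MetricError,
    betweenness,
    characteristic_path_length,
    clustering,
    fit_truncated_power_law,
    global_efficiency,
    modularity_optimal,
    modularity_q,
    normalized_small_world,
    random_failure,
    rewire_degree_preserving,
)


def _nx_adj(g) -> np.ndarray:
    return nx.to_numpy_array(g).astype(np.uint8)


def _random_graph(n, p, seed, connected=False):
    rng = np.random.default_rng(seed)
    while True:
        a = np.triu((rng.random((n, n)) < p), 1).astype(np.uint8)
        a = a + a.T
        if not connected or nx.is_connected(nx.from_numpy_array(a)):
            return a


class TestClosedForms:
    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_graph(self, n):
        a = _nx_adj(nx.complete_graph(n))
        assert clustering(a)[1] == pytest.approx(1.0)
        assert characteristic_path_length(a) == pytest.approx(1.0)
        assert global_efficiency(a) == pytest.approx(1.0)

    def test_five_cycle(self):
        a = _nx_adj(nx.cycle_graph(5))
        assert characteristic_path_length(a) == pytest.approx(1.5)
        assert global_efficiency(a) == pytest.approx(0.75)
        assert clustering(a)[1] == pytest.approx(0.0)

    def test_path_graph_has_no_triangles(self):
        a = _nx_adj(nx.path_graph(4))
        assert clustering(a)[1] == pytest.approx(0.0)

    def test_triangle(self):
        a = _nx_adj(nx.complete_graph(3))
        c, mean = clustering(a)
        np.testing.assert_allclose(c, 1.0)

    def test_two_disconnected_dyads_efficiency(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, 1] = a[1, 0] = 1
        a[2, 3] = a[3, 2] = 1
        assert global_efficiency(a) == pytest.approx(1 / 3)

    def test_star_betweenness(self):
        a = _nx_adj(nx.star_graph(5))  # node 0 is the hub
        b = betweenness(a)
        assert b[0] == pytest.approx(1.0)
        np.testing.assert_allclose(b[1:], 0.0)

    def test_five_path_middle_node(self):
        a = _nx_adj(nx.path_graph(5))
        assert betweenness(a)[2] == pytest.approx(4 / 6)

    def test_two_cliques_modularity(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        q, labels, n_mod = modularity_optimal(_nx_adj(g), n_iter=20, seed=0)
        assert q == pytest.approx(0.5)
        assert n_mod == 2

    def test_complete_graph_modularity_zero(self):
        q, _, n_mod = modularity_optimal(_nx_adj(nx.complete_graph(8)), n_iter=20, seed=0)
        assert q == pytest.approx(0.0)
        assert n_mod == 1

    def test_disconnected_path_length_refused(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, 1] = a[1, 0] = 1
        with pytest.raises(DisconnectedGraphError):
            characteristic_path_length(a)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(8))
    def test_metrics_match_bruteforce_on_random_graphs(self, seed):
        a = _random_graph(12, 0.3, seed, connected=True)
        np.testing.assert_allclose(clustering(a)[0], oracle_clustering(a)[0], atol=1e-12)
        assert characteristic_path_length(a) == pytest.approx(oracle_path_length(a))
        assert global_efficiency(a) == pytest.approx(oracle_efficiency(a))
        np.testing.assert_allclose(betweenness(a), oracle_betweenness(a), atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_modularity_reaches_exhaustive_optimum_small(self, seed):
        a = _random_graph(7, 0.4, seed, connected=True)
        q, labels, _ = modularity_optimal(a, n_iter=30, seed=seed)
        assert q == pytest.approx(oracle_best_modularity(a), abs=1e-10)
        assert modularity_q(a, labels) == pytest.approx(q, abs=1e-12)

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(0)
        blocks = [range(0, 10), range(10, 20), range(20, 30), range(30, 40)]
        a = np.zeros((40, 40), dtype=np.uint8)
        for i in range(40):
            for j in range(i + 1, 40):
                same = any(i in b and j in b for b in blocks)
                p = 0.9 if same else 0.05
                if rng.random() < p:
                    a[i, j] = a[j, i] = 1
        q, labels, n_mod = modularity_optimal(a, n_iter=50, seed=1)
        assert n_mod == 4
        from sklearn.metrics import adjusted_rand_score

        truth = np.repeat(np.arange(4), 10)
        assert adjusted_rand_score(truth, labels) > 0.9


class TestRewiring:
    def test_degree_sequence_preserved(self):
        a = _random_graph(30, 0.2, 0, connected=True)
        r = rewire_degree_preserving(a, seed=5)
        np.testing.assert_array_equal(a.sum(0), r.sum(0))

    def test_same_seed_same_output(self):
        a = _random_graph(30, 0.2, 1, connected=True)
        r1 = rewire_degree_preserving(a, seed=9)
        r2 = rewire_degree_preserving(a, seed=9)
        np.testing.assert_array_equal(r1, r2)

    def test_lattice_loses_clustering(self):
        a = _nx_adj(nx.watts_strogatz_graph(100, 6, 0.0, seed=0))  # ring lattice
        r = rewire_degree_preserving(a, seed=2)
        assert clustering(r)[1] < clustering(a)[1]

    def test_no_self_loops_or_multiedges(self):
        a = _random_graph(20, 0.3, 2, connected=True)
        r = rewire_degree_preserving(a, seed=3)
        assert r.diagonal().sum() == 0
        assert r.max() <= 1


class TestSmallWorld:
    def test_er_graph_is_its_own_null(self):
        a = _random_graph(100, 0.3, 0, connected=True)
        sw = normalized_small_world(a, n_random=10, seed=0)
        assert 0.9 <= sw.sigma <= 1.1

    def test_ring_lattice_strongly_clustered(self):
        a = _nx_adj(nx.watts_strogatz_graph(100, 6, 0.0, seed=0))
        sw = normalized_small_world(a, n_random=5, seed=0)
        assert sw.gamma > 2.0

    def test_rewired_input_self_null(self):
        a = _random_graph(60, 0.2, 3, connected=True)
        r = rewire_degree_preserving(a, seed=7)
        sw = normalized_small_world(r, n_random=10, seed=1)
        assert 0.85 <= sw.sigma <= 1.15


class TestDegreeFit:
    @staticmethod
    def _sample_degrees(a, b, n, seed, kmax=60):
        # the survival form k^(a-1) exp(-k/b) is monotone only beyond its
        # peak at (a-1)b, so sample from k >= ceil((a-1)b)
        kmin = max(1, int(np.ceil((a - 1.0) * b)))
        ks = np.arange(kmin, kmax + 1, dtype=float)
        surv = ks ** (a - 1.0) * np.exp(-ks / b)
        surv /= surv[0]
        pmf = np.diff(-np.append(surv, 0.0))
        pmf = np.clip(pmf, 0.0, None)
        pmf /= pmf.sum()
        rng = np.random.default_rng(seed)
        return rng.choice(np.arange(kmin, kmax + 1), size=n, p=pmf)

    def test_parameter_recovery(self):
        degrees = self._sample_degrees(1.5, 4.0, 2000, seed=0)
        fit = fit_truncated_power_law(degrees)
        assert abs(fit.a - 1.5) < 0.2
        assert abs(fit.b - 4.0) / 4.0 < 0.2
        assert fit.r_squared > 0.9

    def test_regular_graph_rejected(self):
        a = _nx_adj(nx.cycle_graph(30))  # all degrees 2
        with pytest.raises(MetricError, match="distinct"):
            fit_truncated_power_law(a)


class TestResilience:
    def test_zero_fraction_full_component(self):
        a = _random_graph(30, 0.3, 4, connected=True)
        rc = random_failure(a, fractions=[0.0, 0.2], reps=10, seed=0)
        assert rc.relative_lcc[0] == pytest.approx(1.0)

    def test_complete_graph_exact_half(self):
        a = _nx_adj(nx.complete_graph(100))
        rc = random_failure(a, fractions=[0.5], reps=5, seed=1)
        assert rc.relative_lcc[0] == pytest.approx(0.5)

    def test_curve_non_increasing_within_noise(self):
        a = _random_graph(50, 0.15, 5, connected=True)
        rc = random_failure(a, fractions=np.arange(0, 0.9, 0.1), reps=60, seed=2)
        increases = np.diff(rc.relative_lcc)
        assert (increases < 0.05).all()  # two MC standard errors at reps=60


class TestProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(5, 16), st.floats(0.15, 0.6), st.integers(0, 10**6))
    def test_degree_sum_twice_edges(self, n, p, seed):
        a = _random_graph(n, p, seed)
        assert a.sum() == 2 * (np.triu(a, 1).sum())

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(6, 12), st.integers(0, 10**6))
    def test_modularity_never_below_single_community(self, n, seed):
        a = _random_graph(n, 0.4, seed)
        if a.sum() == 0:
            return
        q, _, _ = modularity_optimal(a, n_iter=10, seed=0)
        assert q >= -1e-12
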