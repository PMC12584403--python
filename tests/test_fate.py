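import numpy as np
import pytest
import scipy.sparse as sp

from eecfate.fate import (
    absorption_exact,
    build_chain,
    fate_from_ensemble,
    simulate_walks,
    solve_potential,
    trajectory_profile,
)
from eecfate.manifold import NeighborGraph


def graph_from_dense(a):
    a = np.asarray(a, float)
    return NeighborGraph([np.array([])] * len(a), sp.csr_matrix(a), "toy", 0)


def path_graph(n, weight=1.0):
    a = np.zeros((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = weight
    return graph_from_dense(a)


def random_connected_graph(seed, n=20, p=0.25):
    rng = np.random.default_rng(seed)
    a = np.triu((rng.random((n, n)) < p) * rng.random((n, n)), 1)
    a = a + a.T
    for i in range(1, n):  # spanning chain guarantees connectivity
        a[i - 1, i] = a[i, i - 1] = max(a[i - 1, i], 0.5)
    return graph_from_dense(a)


class TestSolvePotential:
    def test_path_closed_form(self):
        pf = solve_potential(path_graph(3), sources=[0], sinks={"f": [2]})
        np.testing.assert_allclose(pf.potential, [1.0, 0.5, 0.0], atol=1e-10)
        assert pf.residual < 1e-10

    def test_boundary_exact_and_maximum_principle(self):
        g = random_connected_graph(0)
        pf = solve_potential(g, sources=[0, 1], sinks={"a": [10], "b": [15]})
        assert (pf.potential[[0, 1]] == 1.0).all()
        assert (pf.potential[[10, 15]] == 0.0).all()
        interior = np.setdiff1d(np.arange(20), [0, 1, 10, 15])
        assert (pf.potential[interior] > 0).all()
        assert (pf.potential[interior] < 1).all()

    def test_interior_is_weighted_neighbor_mean(self):
        g = random_connected_graph(1)
        pf = solve_potential(g, sources=[0], sinks={"a": [19]})
        w = g.connectivities.toarray()
        for i in range(1, 19):
            want = (w[i] @ pf.potential) / w[i].sum()
            assert pf.potential[i] == pytest.approx(want, abs=1e-9)

    def test_overlap_and_disconnection_errors(self):
        with pytest.raises(ValueError, match="source and sink"):
            solve_potential(path_graph(3), [0], {"f": [0, 2]})
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1  # node 2-3 component disconnected
        a[2, 3] = a[3, 2] = 1
        with pytest.raises(ValueError, match="disconnected"):
            solve_potential(graph_from_dense(a), [0], {"f": [1]})


class TestBuildChain:
    def test_beta_zero_uniform_over_closed_neighborhood(self):
        g = path_graph(3)
        pf = solve_potential(g, [0], {"f": [2]})
        chain = build_chain(g, pf, beta=0.0)
        row = chain.transition[1].toarray().ravel()
        np.testing.assert_allclose(row, [1 / 3, 1 / 3, 1 / 3])

    def test_large_beta_goes_downhill(self):
        g = path_graph(3)
        pf = solve_potential(g, [0], {"f": [2]})
        chain = build_chain(g, pf, beta=1e6)
        row = chain.transition[1].toarray().ravel()
        assert row[2] == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_softmax(self):
        # 4-node star: 0 connected to 1,2,3 with V = (0.8, 0.5, 0.2, 1.0)
        a = np.zeros((4, 4))
        a[0, 1:] = a[1:, 0] = 1.0
        g = graph_from_dense(a)
        from eecfate.fate import PotentialField

        v = np.array([0.8, 0.5, 0.2, 1.0])
        pf = PotentialField(potential=v, sources=np.array([3]),
                           sinks={"f": np.array([2])}, residual=0.0)
        chain = build_chain(g, pf, beta=1.0)
        logits = np.exp(-1.0 * (v[[1, 2, 3, 0]] - v[0]))
        want = logits / logits.sum()
        row = chain.transition[0].toarray().ravel()
        np.testing.assert_allclose(row[[1, 2, 3, 0]], want, atol=1e-12)

    def test_rows_stochastic_and_sinks_absorbing(self):
        g = random_connected_graph(2)
        pf = solve_potential(g, [0], {"a": [18], "b": [19]})
        chain = build_chain(g, pf, beta=7.0)
        sums = np.asarray(chain.transition.sum(axis=1)).ravel()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert chain.transition[18, 18] == 1.0
        assert chain.transition[19, 19] == 1.0

    def test_negative_beta_rejected(self):
        g = path_graph(3)
        pf = solve_potential(g, [0], {"f": [2]})
        with pytest.raises(ValueError):
            build_chain(g, pf, beta=-1.0)

    def test_increasing_beta_increases_mean_potential_drop(self):
        g = random_connected_graph(3)
        pf = solve_potential(g, [0], {"a": [19]})
        v = pf.potential
        drops = []
        for beta in (0.0, 1.0, 5.0, 25.0):
            chain = build_chain(g, pf, beta=beta)
            p = chain.transition.toarray()
            per_state = ((v[:, None] - v[None, :]) * p).sum(axis=1)
            drops.append(per_state[~chain.absorbing].mean())
        assert all(b > a for a, b in zip(drops, drops[1:]))


class TestSimulateWalks:
    def test_bit_identical_given_seed(self):
        g = random_connected_graph(4)
        pf = solve_potential(g, [0], {"a": [19]})
        chain = build_chain(g, pf, beta=3.0)
        e1 = simulate_walks(chain, [0, 1], n_iterations=50, seed=7)
        e2 = simulate_walks(chain, [0, 1], n_iterations=50, seed=7)
        assert all((w1 == w2).all() for w1, w2 in zip(e1.walks, e2.walks))
        assert (e1.fate_labels == e2.fate_labels).all()

    def test_single_reachable_sink_fully_absorbed(self):
        g = random_connected_graph(5)
        pf = solve_potential(g, [0], {"a": [19]})
        chain = build_chain(g, pf, beta=2.0)
        ens = simulate_walks(chain, [0], n_iterations=200, max_steps=5000, seed=0)
        assert (ens.fate_labels == "a").all()
        for walk in ens.walks:
            assert walk[-1] == 19
            # consecutive states are chain-supported transitions
            p = chain.transition
            for s, t in zip(walk[:-1], walk[1:]):
                assert p[s, t] > 0

    def test_deterministic_chain_walks_shortest_downhill_path(self):
        g = path_graph(4)
        pf = solve_potential(g, [0], {"f": [3]})
        chain = build_chain(g, pf, beta=1e6)
        ens = simulate_walks(chain, [0], n_iterations=5, seed=1)
        for walk in ens.walks:
            assert walk.tolist() == [0, 1, 2, 3]

    def test_start_inside_sink_absorbed_at_step_zero(self):
        g = path_graph(3)
        pf = solve_potential(g, [0], {"f": [2]})
        chain = build_chain(g, pf, beta=1.0)
        ens = simulate_walks(chain, [2], n_iterations=3, seed=0)
        assert (ens.fate_labels == "f").all()
        assert all(len(w) == 1 for w in ens.walks)


class TestAbsorptionExact:
    def test_sink_is_one_hot(self):
        g = random_connected_graph(6)
        pf = solve_potential(g, [0], {"a": [18], "b": [19]})
        chain = build_chain(g, pf, beta=2.0)
        fp = absorption_exact(chain)
        assert fp.probabilities.loc[18, "a"] == 1.0
        assert fp.probabilities.loc[18, "b"] == 0.0

    def test_symmetric_path_is_half_half(self):
        g = path_graph(3)
        pf = solve_potential(g, [1], {"l": [0], "r": [2]})
        chain = build_chain(g, pf, beta=0.0)
        fp = absorption_exact(chain)
        np.testing.assert_allclose(fp.probabilities.loc[1], [0.5, 0.5], atol=1e-10)

    def test_rows_sum_to_one(self):
        g = random_connected_graph(7)
        pf = solve_potential(g, [0], {"a": [17], "b": [18], "c": [19]})
        chain = build_chain(g, pf, beta=4.0)
        fp = absorption_exact(chain)
        np.testing.assert_allclose(fp.probabilities.sum(axis=1), 1.0, atol=1e-10)

    def test_unreachable_sink_flagged(self):
        # directed trap: make an absorbing state that is not a named sink
        from eecfate.fate import MarkovChain

        p = sp.csr_matrix(np.array([[0.0, 1.0, 0.0],
                                    [0.0, 1.0, 0.0],   # node 1 traps walks
                                    [0.0, 0.0, 1.0]]))
        chain = MarkovChain(transition=p, beta=0.0,
                           absorbing=np.array([False, False, True]),
                           fates={"f": np.array([2])})
        with pytest.raises(ValueError, match="reach"):
            absorption_exact(chain)

    def test_matches_monte_carlo_within_3se(self):
        g = random_connected_graph(8, n=12)
        pf = solve_potential(g, [0], {"a": [10], "b": [11]})
        chain = build_chain(g, pf, beta=1.5)
        fp = absorption_exact(chain)
        n_walks = 100_000
        ens = simulate_walks(chain, [0], n_iterations=n_walks, seed=3,
                             record_paths=False)
        p_a = fp.probabilities.loc[0, "a"]
        emp = (ens.fate_labels == "a").mean()
        se = np.sqrt(p_a * (1 - p_a) / n_walks)
        assert abs(emp - p_a) <= 3 * se


class TestFateFromEnsemble:
    def _toy(self):
        g = path_graph(5)
        pf = solve_potential(g, [2], {"l": [0], "r": [4]})
        chain = build_chain(g, pf, beta=0.5)
        return g, chain

    def test_visiting_walk_estimator_agrees_with_exact(self):
        g, chain = self._toy()
        exact = absorption_exact(chain)
        ens = simulate_walks(chain, [2], n_iterations=50_000, seed=5)
        fp = fate_from_ensemble(ens, chain.n_states, min_visits=10)
        # start cell: every walk visits it, so the estimate is plain MC
        for fate_name in ("l", "r"):
            p = exact.probabilities.loc[2, fate_name]
            se = np.sqrt(p * (1 - p) / fp.n_visits[2])
            assert abs(fp.probabilities.loc[2, fate_name] - p) <= 3 * se

    def test_cell_exclusive_to_one_fate(self):
        g, chain = self._toy()
        ens = simulate_walks(chain, [2], n_iterations=2000, seed=6)
        fp = fate_from_ensemble(ens, chain.n_states)
        # cell 3 is only on paths that end right (cell 4); any walk through
        # it that returns and dies left still counts -- but cell 4 itself
        # is one-hot by construction
        assert fp.probabilities.loc[4, "r"] == 1.0

    def test_unvisited_cell_flagged_undefined(self):
        g = path_graph(4)
        pf = solve_potential(g, [2], {"r": [3], "l": [0]})
        chain = build_chain(g, pf, beta=1e6)  # deterministic: 2 -> 3
        ens = simulate_walks(chain, [2], n_iterations=100, seed=0)
        fp = fate_from_ensemble(ens, chain.n_states)
        assert np.isnan(fp.probabilities.loc[1]).all()
        assert fp.low_confidence[1]


class TestTrajectoryProfile:
    def _ensemble(self, seed=0, beta=5.0):
        g = path_graph(8)
        pf = solve_potential(g, [0], {"f": [7]})
        chain = build_chain(g, pf, beta=beta)
        return pf, simulate_walks(chain, [0], n_iterations=300, seed=seed)

    def test_constant_values_flat_profile(self):
        _, ens = self._ensemble()
        prof = trajectory_profile(ens, np.full(8, 3.25), "f", n_grid=10)
        np.testing.assert_allclose(prof.mean, 3.25, atol=1e-12)

    def test_potential_decreases_along_walks(self):
        pf, ens = self._ensemble()
        prof = trajectory_profile(ens, pf.potential, "f", n_grid=10, smooth_window=3)
        assert (np.diff(prof.mean) < 0).all()

    def test_planted_rising_marker(self):
        pf, ens = self._ensemble(seed=1)
        marker = np.linspace(0, 1, 8) ** 2
        prof = trajectory_profile(ens, marker, "f", n_grid=10, smooth_window=3)
        assert prof.mean[-1] > prof.mean[0]
        assert np.corrcoef(prof.t_grid, prof.mean)[0, 1] > 0.95

    def test_missing_fate_errors(self):
        _, ens = self._ensemble()
        with pytest.raises(ValueError, match="no walk"):
            trajectory_profile(ens, np.zeros(8), "nope")
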