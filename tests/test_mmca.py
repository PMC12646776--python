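"""MMCA core: Fermi rule, payoffs, retention/avoidance, master-equation step."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epigame import (
    ModelParams,
    ParameterError,
    StateError,
    StateMatrix,
    avoidance_probabilities,
    expected_payoffs,
    fermi_probability,
    mmca_step,
    retention_probabilities,
    run_mmca,
    state_payoffs,
    steady_summary,
)
from conftest import random_network, random_state


def brute_force_step(state, network, params):
    """Literal nested-loop transcription of the retention/avoidance products
    and the four master equations; the oracle for the vectorized step."""
    n = network.n_nodes
    p = state.probs
    a, b = network.adj_behaviour, network.adj_contact
    pD = p[:, 0] + p[:, 1]
    pT = p[:, 2] + p[:, 3]
    pI = p[:, 1] + p[:, 3]
    payoff_vec = state_payoffs(params)
    pay = p @ payoff_vec
    new = np.zeros_like(p)
    for i in range(n):
        r_d = r_t = q_d = q_t = 1.0
        for j in range(n):
            gamma = 1.0 / (1.0 + np.exp(-(pay[j] - pay[i]) / params.omega))
            r_d *= 1.0 - a[j, i] * pT[j] * gamma
            r_t *= 1.0 - a[j, i] * pD[j] * gamma
            q_d *= 1.0 - b[j, i] * pI[j] * params.beta
            q_t *= 1.0 - b[j, i] * pI[j] * params.d * params.beta
        ds, di, ts, ti = p[i]
        mu = params.mu
        new[i, 0] = ds * r_d * q_d + di * r_d * mu + ts * (1 - r_t) * q_d + ti * (1 - r_t) * mu
        new[i, 1] = (
            ds * r_d * (1 - q_d)
            + di * r_d * (1 - mu)
            + ts * (1 - r_t) * (1 - q_d)
            + ti * (1 - r_t) * (1 - mu)
        )
        new[i, 2] = ds * (1 - r_d) * q_t + di * (1 - r_d) * mu + ts * r_t * q_t + ti * r_t * mu
        new[i, 3] = (
            ds * (1 - r_d) * (1 - q_t)
            + di * (1 - r_d) * (1 - mu)
            + ts * r_t * (1 - q_t)
            + ti * r_t * (1 - mu)
        )
    return new


class TestFermiRule:
    def test_equal_payoffs_give_half(self):
        assert fermi_probability(-0.5, -0.5, 0.5) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        assert fermi_probability(-0.2, 0.0, 0.5) == pytest.approx(
            1.0 / (1.0 + np.exp(-0.4))
        )

    @given(
        a=st.floats(-10, 10), b=st.floats(-10, 10), omega=st.floats(0.01, 10)
    )
    @settings(derandomize=True, max_examples=50)
    def test_complementarity(self, a, b, omega):
        """Γ(a,b) + Γ(b,a) = 1: logistic symmetry of the imitation rule."""
        assert fermi_probability(a, b, omega) + fermi_probability(b, a, omega) == pytest.approx(1.0)

    def test_monotone_in_payoff_gap(self):
        probs = [fermi_probability(0.0, x, 0.5) for x in (-1.0, 0.0, 1.0, 2.0)]
        assert probs == sorted(probs)
        assert all(0 < p < 1 for p in probs)

    def test_nonpositive_omega_rejected(self):
        with pytest.raises(ParameterError):
            fermi_probability(0.0, 1.0, 0.0)


class TestPayoffs:
    @pytest.mark.parametrize(
        "ci, expected",
        [(2.0, (0, -2, -0.2, -2.2)), (4.0, (0, -4, -0.2, -4.2))],
    )
    def test_state_payoff_vector(self, ci, expected):
        params = ModelParams(
            beta=0.3, mu=0.5, d=0.6, cost_infection=ci, cost_support=0.2, omega=0.5
        )
        assert state_payoffs(params) == pytest.approx(expected)

    def test_state_payoff_ordering(self, base_params):
        """DS > TS > DI > TI whenever CI > CT: infection dominates support cost."""
        pi = state_payoffs(base_params)
        assert pi[0] > pi[2] > pi[1] > pi[3]

    def test_expected_payoffs(self, base_params):
        state = StateMatrix(
            np.array([[1, 0, 0, 0], [0.25, 0.25, 0.25, 0.25], [0, 0, 0, 1]])
        )
        pay = expected_payoffs(state, base_params)
        assert pay == pytest.approx([0.0, -1.1, -2.2])
        assert np.all(pay <= 0)


class TestRetentionAvoidance:
    def test_isolated_node_retains_and_avoids(self, base_params):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        from epigame import MultiplexNetwork

        net = MultiplexNetwork(3, adj, adj.copy())
        rng = np.random.default_rng(0)
        state = random_state(3, rng)
        pay = expected_payoffs(state, base_params)
        r_d, r_t = retention_probabilities(state, pay, net, base_params)
        q_d, q_t = avoidance_probabilities(state, net, base_params)
        assert r_d[2] == 1.0 and r_t[2] == 1.0
        assert q_d[2] == 1.0 and q_t[2] == 1.0

    def test_single_neighbour_factor(self, edge_network, base_params):
        # node 1 pure TS, node 0 pure DS with equal payoffs forced via state
        state = StateMatrix(np.array([[0.0, 0.5, 0.5, 0.0], [0.0, 0.0, 1.0, 0.0]]))
        pay = np.array([-1.1, -1.1])  # equal payoffs -> Gamma = 1/2
        r_d, _ = retention_probabilities(state, pay, edge_network, base_params)
        assert r_d[0] == pytest.approx(1 - 1.0 * 0.5)  # p_1^T = 1, Gamma = 0.5

    def test_avoidance_single_infected_neighbour(self, edge_network, base_params):
        state = StateMatrix(np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]]))
        q_d, q_t = avoidance_probabilities(state, edge_network, base_params)
        assert q_d[0] == pytest.approx(1 - 0.3)
        assert q_t[0] == pytest.approx(1 - 0.6 * 0.3)
        # the infected node itself faces no pressure from its healthy neighbour
        assert q_d[1] == 1.0 and q_t[1] == 1.0

    def test_protection_never_hurts(self, base_params):
        """q^T >= q^D element-wise for any state, since d <= 1."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 8))
            net = random_network(n, rng)
            state = random_state(n, rng)
            q_d, q_t = avoidance_probabilities(state, net, base_params)
            assert np.all(q_t >= q_d - 1e-15)


class TestMmcaStep:
    def test_disease_free_all_D_is_absorbing(self, path3_network, base_params):
        state = StateMatrix(np.tile([1.0, 0, 0, 0], (3, 1)))
        out = mmca_step(state, path3_network, base_params)
        assert np.allclose(out.probs, state.probs)

    def test_two_node_hand_evaluation(self, edge_network, base_params):
        """Single step on an infected-DI / healthy-DS pair, checked by hand.

        With no T mass anywhere the behaviour phase is inert (R^D = 1) and
        the step reduces to recovery of node 0 and exposure of node 1.
        """
        state = StateMatrix(np.array([[0, 1.0, 0, 0], [1.0, 0, 0, 0]]))
        out = mmca_step(state, edge_network, base_params)
        assert out.probs[0] == pytest.approx([0.5, 0.5, 0.0, 0.0])
        assert out.probs[1] == pytest.approx([0.7, 0.3, 0.0, 0.0])

    def test_matches_brute_force_on_small_networks(self, base_params):
        """Vectorized step equals the literal nested-loop transcription."""
        rng = np.random.default_rng(12345)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            net = random_network(n, rng)
            state = random_state(n, rng)
            expected = brute_force_step(state, net, base_params)
            got = mmca_step(state, net, base_params).probs
            np.testing.assert_allclose(got, expected, atol=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_conservation(self, seed):
        """Row sums stay 1: the four master equations partition probability."""
        base_params = ModelParams(
            beta=0.3, mu=0.5, d=0.6, cost_infection=2.0, cost_support=0.2, omega=0.5
        )
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        net = random_network(n, rng)
        state = random_state(n, rng)
        out = mmca_step(state, net, base_params)
        np.testing.assert_allclose(out.probs.sum(axis=1), 1.0, atol=1e-10)

    def test_invalid_row_sums_rejected(self, edge_network, base_params):
        with pytest.raises(StateError):
            StateMatrix(np.array([[0.5, 0.5, 0.5, 0.0], [1.0, 0, 0, 0]]))


class TestRunMmca:
    def test_no_infection_channel(self, path3_network, base_params):
        params = ModelParams(
            beta=0.0, mu=0.5, d=0.6, cost_infection=2.0, cost_support=0.2, omega=0.5
        )
        init = StateMatrix.uniform_mixing(3, 0.2, 0.0)
        traj = run_mmca(init, path3_network, params, 50)
        assert np.all(traj.rho_I == 0.0)

    def test_certain_recovery_clears_infection(self, path3_network):
        params = ModelParams(
            beta=0.0, mu=1.0, d=0.6, cost_infection=2.0, cost_support=0.2, omega=0.5
        )
        init = StateMatrix.uniform_mixing(3, 0.2, 0.3)
        traj = run_mmca(init, path3_network, params, 5)
        assert traj.rho_I[0] == pytest.approx(0.3)
        assert np.all(traj.rho_I[1:] == 0.0)

    def test_disease_free_geometric_decay(self, base_params, path3_network):
        """With beta = 0, rho_I decays exactly at rate (1 - mu)."""
        params = ModelParams(
            beta=0.0, mu=0.5, d=0.6, cost_infection=2.0, cost_support=0.2, omega=0.5
        )
        init = StateMatrix.uniform_mixing(3, 0.2, 0.4)
        traj = run_mmca(init, path3_network, params, 20)
        expected = 0.4 * 0.5 ** np.arange(21)
        np.testing.assert_allclose(traj.rho_I, expected, atol=1e-12)


class TestSteadySummary:
    def test_constant_series(self):
        traj = _fake_traj(np.full(300, 0.7), np.full(300, 0.2))
        assert steady_summary(traj, 100) == pytest.approx((0.7, 0.2, 0.0, 0.0))

    def test_alternating_series(self):
        rho_i = np.tile([0.1, 0.3], 100)
        traj = _fake_traj(np.zeros(200), rho_i)
        mt, mi, at, ai = steady_summary(traj, 100)
        assert mi == pytest.approx(0.2)
        assert ai == pytest.approx(0.2)

    def test_window_longer_than_series_rejected(self):
        traj = _fake_traj(np.zeros(50), np.zeros(50))
        with pytest.raises(ParameterError):
            steady_summary(traj, 100)


def _fake_traj(rho_t, rho_i):
    from epigame import TrajectorySummary

    return TrajectorySummary(
        times=np.arange(len(rho_t)),
        rho_T=np.asarray(rho_t),
        rho_I=np.asarray(rho_i),
        final_state=StateMatrix.uniform_mixing(2),
    )
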