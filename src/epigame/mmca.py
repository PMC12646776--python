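"""Deterministic four-state MMCA dynamics of the coupled game-epidemic model.

Each node occupies a probability distribution over four states that combine
a strategy — support (T) or disregard (D) the government response — with a
health status — susceptible (S) or infected (I). One discrete time step has
two phases. In the behaviour phase node i keeps its strategy with the
retention probability

    R_i^D = Π_j (1 − a_ji · p_j^T · Γ(π_i, π_j)),
    R_i^T = Π_j (1 − a_ji · p_j^D · Γ(π_i, π_j)),

where Γ is the Fermi imitation rule and π the expected payoff. In the health
phase a susceptible node avoids infection with probability

    q_i^D = Π_j (1 − b_ji · p_j^I · β),
    q_i^T = Π_j (1 − b_ji · p_j^I · d·β),

the attenuation d < 1 rewarding T-adopters with a reduced infection rate,
while infected nodes recover with probability μ. The master equations
combine the two phases, the infection channel following the *post*-behaviour
strategy. The update is fully synchronous: all retention and avoidance
probabilities are evaluated on the time-t state before any node advances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, StateError
from .network import MultiplexNetwork

# Column order of the state matrix.
STATE_NAMES = ("DS", "DI", "TS", "TI")
DS, DI, TS, TI = range(4)

_ROW_SUM_TOL = 1e-10
_CLIP_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Scalar constants of the coupled game-epidemic model.

    Attributes
    ----------
    beta
        Infection probability per infected contact per step, in [0, 1].
    mu
        Recovery probability per step, in (0, 1].
    d
        Government response strength: T-adopters are infected at rate d·β.
        0 < d ≤ 1; d = 1 is the decoupled limit where protection is void.
    cost_infection
        CI ≥ 0, the cost of being infected.
    cost_support
        CT ≥ 0, the cost of supporting the government response; CI > CT is
        required for the strategy choice to be a genuine dilemma.
    omega
        Selection intensity ω > 0 of the Fermi rule; small ω makes imitation
        nearly deterministic, large ω nearly random.
    """

    beta: float
    mu: float
    d: float
    cost_infection: float
    cost_support: float
    omega: float

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ParameterError(f"beta must be in [0,1], got {self.beta}")
        if not 0.0 < self.mu <= 1.0:
            raise ParameterError(f"mu must be in (0,1], got {self.mu}")
        if not 0.0 < self.d <= 1.0:
            raise ParameterError(f"d must be in (0,1], got {self.d}")
        if self.cost_infection < 0 or self.cost_support < 0:
            raise ParameterError("costs must be nonnegative")
        if not self.cost_infection > self.cost_support:
            raise ParameterError(
                f"cost_infection must exceed cost_support, got "
                f"CI={self.cost_infection}, CT={self.cost_support}"
            )
        if not self.omega > 0:
            raise ParameterError(f"omega must be positive, got {self.omega}")


class StateMatrix:
    """Per-node occupation probabilities over (DS, DI, TS, TI).

    Rows are probability distributions: entries in [0, 1], each row summing
    to 1 within 1e-10. Derived marginals: p^D = p^DS + p^DI (D-adopters),
    p^T = p^TS + p^TI (T-adopters), p^I = p^DI + p^TI (infected).
    """

    __slots__ = ("probs",)

    def __init__(self, probs: np.ndarray):
        probs = np.asarray(probs, dtype=np.float64)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise StateError(f"state matrix must be N x 4, got shape {probs.shape}")
        if probs.min() < -_CLIP_TOL or probs.max() > 1 + _CLIP_TOL:
            raise StateError("state probabilities outside [0, 1]")
        sums = probs.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > _ROW_SUM_TOL:
            worst = int(np.argmax(np.abs(sums - 1.0)))
            raise StateError(
                f"row {worst} sums to {sums[worst]!r}, expected 1 within {_ROW_SUM_TOL}"
            )
        self.probs = np.clip(probs, 0.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return self.probs.shape[0]

    @property
    def p_D(self) -> np.ndarray:
        return self.probs[:, DS] + self.probs[:, DI]

    @property
    def p_T(self) -> np.ndarray:
        return self.probs[:, TS] + self.probs[:, TI]

    @property
    def p_I(self) -> np.ndarray:
        return self.probs[:, DI] + self.probs[:, TI]

    @property
    def rho_T(self) -> float:
        """Population density of T-adopters."""
        return float(self.p_T.mean())

    @property
    def rho_I(self) -> float:
        """Population density of infected individuals."""
        return float(self.p_I.mean())

    def copy(self) -> "StateMatrix":
        out = StateMatrix.__new__(StateMatrix)
        out.probs = self.probs.copy()
        return out

    @classmethod
    def uniform_mixing(cls, n_nodes: int, sigma0: float = 0.5, rho0: float = 0.1) -> "StateMatrix":
        """Homogeneous product-mixing start: every node is a T-adopter with
        probability ``sigma0`` and infected with probability ``rho0``,
        independently."""
        if not 0.0 <= sigma0 <= 1.0 or not 0.0 <= rho0 <= 1.0:
            raise ParameterError("sigma0 and rho0 must be in [0, 1]")
        row = np.array(
            [
                (1 - sigma0) * (1 - rho0),
                (1 - sigma0) * rho0,
                sigma0 * (1 - rho0),
                sigma0 * rho0,
            ]
        )
        return cls(np.tile(row, (n_nodes, 1)))


@dataclass
class TrajectorySummary:
    """Recorded densities along an MMCA run.

    ``times[k]`` indexes the state after k steps (``times[0] = 0`` is the
    initial condition); ``rho_T``/``rho_I`` are the population densities at
    those times. ``pT_window_mean``, when present, is the per-node p^T
    averaged over the final summary window — the representative strategy
    vector used by the threshold analysis.
    """

    times: np.ndarray
    rho_T: np.ndarray
    rho_I: np.ndarray
    final_state: StateMatrix
    pT_window_mean: np.ndarray | None = field(default=None)


def fermi_probability(payoff_i, payoff_j, omega: float):
    """Fermi imitation rule Γ(π_i, π_j) = 1 / (1 + exp(−(π_j − π_i)/ω)).

    The probability that i copies j's strategy; strictly increasing in the
    payoff advantage π_j − π_i, equal to 1/2 at parity. Accepts scalars or
    broadcastable arrays.
    """
    if not omega > 0:
        raise ParameterError(f"omega must be positive, got {omega}")
    diff = (np.asarray(payoff_j, dtype=np.float64) - np.asarray(payoff_i, dtype=np.float64)) / omega
    with np.errstate(over="ignore"):  # exp overflow saturates to Gamma = 0
        out = 1.0 / (1.0 + np.exp(-diff))
    if out.ndim == 0:
        return float(out)
    return out


def state_payoffs(params: ModelParams) -> np.ndarray:
    """Per-state payoff vector (π_DS, π_DI, π_TS, π_TI) = (0, −CI, −CT, −CI−CT)."""
    ci, ct = params.cost_infection, params.cost_support
    return np.array([0.0, -ci, -ct, -ci - ct])


def expected_payoffs(state: StateMatrix, params: ModelParams) -> np.ndarray:
    """Expected payoff π_i = Σ_C π^C p_i^C of every node; always ≤ 0."""
    return state.probs @ state_payoffs(params)


def _imitation_matrix(payoffs: np.ndarray, omega: float) -> np.ndarray:
    """G[i, j] = Γ(π_i, π_j), the probability that i imitates j."""
    return fermi_probability(payoffs[:, None], payoffs[None, :], omega)


def retention_probabilities(
    state: StateMatrix,
    payoffs: np.ndarray,
    network: MultiplexNetwork,
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Strategy-retention probabilities (R^D, R^T) for every node.

    R_i^D multiplies, over neighbours j on the behaviour layer, the
    probability that j is a T-adopter *and* i imitates it — the complement
    of any imitation trigger firing. Isolated nodes retain with probability
    exactly 1 (empty product).
    """
    payoffs = np.asarray(payoffs, dtype=np.float64)
    if payoffs.shape != (network.n_nodes,):
        raise ParameterError(
            f"payoffs must have shape ({network.n_nodes},), got {payoffs.shape}"
        )
    if state.n_nodes != network.n_nodes:
        raise ParameterError("state and network sizes differ")
    a = network.adj_behaviour
    gamma_ji = _imitation_matrix(payoffs, params.omega).T  # [j, i] = Γ(π_i, π_j)
    r_d = np.prod(1.0 - a * state.p_T[:, None] * gamma_ji, axis=0)
    r_t = np.prod(1.0 - a * state.p_D[:, None] * gamma_ji, axis=0)
    return r_d, r_t


def avoidance_probabilities(
    state: StateMatrix, network: MultiplexNetwork, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Infection-avoidance probabilities (q^D, q^T) for every node.

    q_i^D = Π_j (1 − b_ji p_j^I β) and q_i^T uses the attenuated rate d·β,
    so q^T ≥ q^D always. Isolated nodes avoid infection with probability 1.
    """
    if state.n_nodes != network.n_nodes:
        raise ParameterError("state and network sizes differ")
    b = network.adj_contact
    pressure = b * state.p_I[:, None]  # [j, i] = b_ji p_j^I
    q_d = np.prod(1.0 - pressure * params.beta, axis=0)
    q_t = np.prod(1.0 - pressure * (params.d * params.beta), axis=0)
    return q_d, q_t


def mmca_step(
    state: StateMatrix, network: MultiplexNetwork, params: ModelParams
) -> StateMatrix:
    """Advance the master equations one synchronous step.

    Behaviour phase first, then the health phase through the infection
    channel of the post-behaviour strategy:

        p^DS' = p^DS R^D q^D + p^DI R^D μ + p^TS (1−R^T) q^D + p^TI (1−R^T) μ
        p^DI' = p^DS R^D (1−q^D) + p^DI R^D (1−μ) + p^TS (1−R^T)(1−q^D) + p^TI (1−R^T)(1−μ)
        p^TS' = p^DS (1−R^D) q^T + p^DI (1−R^D) μ + p^TS R^T q^T + p^TI R^T μ
        p^TI' = p^DS (1−R^D)(1−q^T) + p^DI (1−R^D)(1−μ) + p^TS R^T (1−q^T) + p^TI R^T (1−μ)

    The four right-hand sides partition the probability tree, so row sums
    are preserved exactly up to rounding.
    """
    p = state.probs
    payoffs = expected_payoffs(state, params)
    r_d, r_t = retention_probabilities(state, payoffs, network, params)
    q_d, q_t = avoidance_probabilities(state, network, params)
    mu = params.mu

    ds, di, ts, ti = p[:, DS], p[:, DI], p[:, TS], p[:, TI]
    new = np.empty_like(p)
    new[:, DS] = ds * r_d * q_d + di * r_d * mu + ts * (1 - r_t) * q_d + ti * (1 - r_t) * mu
    new[:, DI] = (
        ds * r_d * (1 - q_d)
        + di * r_d * (1 - mu)
        + ts * (1 - r_t) * (1 - q_d)
        + ti * (1 - r_t) * (1 - mu)
    )
    new[:, TS] = ds * (1 - r_d) * q_t + di * (1 - r_d) * mu + ts * r_t * q_t + ti * r_t * mu
    new[:, TI] = (
        ds * (1 - r_d) * (1 - q_t)
        + di * (1 - r_d) * (1 - mu)
        + ts * r_t * (1 - q_t)
        + ti * r_t * (1 - mu)
    )
    return StateMatrix(new)


def run_mmca(
    initial: StateMatrix,
    network: MultiplexNetwork,
    params: ModelParams,
    n_steps: int,
    intervention=None,
    pT_window: int | None = None,
) -> TrajectorySummary:
    """Iterate the master equations for ``n_steps`` steps.

    If an intervention is supplied its seed nodes are clamped to the T
    strategy at its application time and — when persistent — after every
    subsequent step, so seeds show p^T = 1 at all recorded times from
    ``apply_time`` on. When ``pT_window`` is given, the per-node p^T
    averaged over the final ``pT_window`` recorded states is returned in the
    summary for use by the threshold analysis. Fully deterministic.
    """
    if n_steps < 1:
        raise ParameterError(f"n_steps must be >= 1, got {n_steps}")
    if pT_window is not None and pT_window > n_steps + 1:
        raise ParameterError("pT_window exceeds trajectory length")

    def clamp(s: StateMatrix, t: int) -> StateMatrix:
        if intervention is None or not intervention.seed_set:
            return s
        if t == intervention.apply_time or (
            intervention.persistent and t >= intervention.apply_time
        ):
            from .interventions import modulate_mmca

            return modulate_mmca(s, intervention.seed_set)
        return s

    state = clamp(initial, 0)
    rho_t = np.empty(n_steps + 1)
    rho_i = np.empty(n_steps + 1)
    rho_t[0], rho_i[0] = state.rho_T, state.rho_I
    pt_acc = np.zeros(network.n_nodes) if pT_window is not None else None
    window_start = n_steps + 1 - (pT_window or 0)
    if pt_acc is not None and 0 >= window_start:
        pt_acc += state.p_T
    for t in range(1, n_steps + 1):
        state = clamp(mmca_step(state, network, params), t)
        rho_t[t], rho_i[t] = state.rho_T, state.rho_I
        if pt_acc is not None and t >= window_start:
            pt_acc += state.p_T
    summary = TrajectorySummary(
        times=np.arange(n_steps + 1), rho_T=rho_t, rho_I=rho_i, final_state=state
    )
    if pt_acc is not None:
        summary.pT_window_mean = pt_acc / pT_window
    return summary


def steady_summary(
    traj: TrajectorySummary, window: int = 100
) -> tuple[float, float, float, float]:
    """Mean and peak-to-trough amplitude of ρ_T and ρ_I over the last window.

    Returns ``(rho_T_mean, rho_I_mean, rho_T_amplitude, rho_I_amplitude)``.
    Averaging over a trailing window is the right summary here because the
    steady regime of the coupled system is periodic, not a fixed point.
    """
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    if window > len(traj.rho_T):
        raise ParameterError(
            f"window {window} exceeds trajectory length {len(traj.rho_T)}"
        )
    tail_t = traj.rho_T[-window:]
    tail_i = traj.rho_I[-window:]
    return (
        float(tail_t.mean()),
        float(tail_i.mean()),
        float(tail_t.max() - tail_t.min()),
        float(tail_i.max() - tail_i.min()),
    )


def run_frozen_sis(
    network: MultiplexNetwork,
    pT_frozen: np.ndarray,
    beta: float,
    mu: float,
    initial_pI: np.ndarray | float,
    n_steps: int,
    d: float = 1.0,
) -> np.ndarray:
    """SIS dynamics with the strategy distribution frozen at ``pT_frozen``.

    Strategy updates are switched off: node i is a T-adopter with fixed
    probability pT_i each step, so its avoidance probability mixes the two
    infection channels,

        q_i = (1 − pT_i)·Π_j(1 − b_ji p_j^I β) + pT_i·Π_j(1 − b_ji p_j^I d·β),

    and p_i^I evolves by the usual SIS balance. The linearisation of this
    dynamic around the disease-free state has growth matrix (1−μ)E + β·H
    with H the behaviour-weighted contact matrix, so it exercises the
    epidemic threshold exactly. Returns the trajectory of p^I as an
    (n_steps+1) × N array.
    """
    pT_frozen = np.broadcast_to(np.asarray(pT_frozen, dtype=np.float64), (network.n_nodes,))
    p_i = np.broadcast_to(
        np.asarray(initial_pI, dtype=np.float64), (network.n_nodes,)
    ).copy()
    b = network.adj_contact
    out = np.empty((n_steps + 1, network.n_nodes))
    out[0] = p_i
    for t in range(1, n_steps + 1):
        pressure = b * p_i[:, None]
        q_d = np.prod(1.0 - pressure * beta, axis=0)
        q_t = np.prod(1.0 - pressure * (d * beta), axis=0)
        q = (1.0 - pT_frozen) * q_d + pT_frozen * q_t
        p_i = p_i * (1.0 - mu) + (1.0 - p_i) * (1.0 - q)
        out[t] = p_i
    return out
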