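"""Stochastic agent-based counterpart of the MMCA dynamics.

Each node holds one discrete state from {DS, DI, TS, TI}. A synchronous
step realises the same two-phase probability tree as the master equations:

* Behaviour phase — every neighbour j holding the opposite strategy
  triggers imitation independently with the Fermi probability Γ(π_i, π_j);
  the agent switches if at least one trigger fires. Payoffs are the
  *current-state* payoffs of the two agents (an agent is in exactly one
  state), which is the standard relationship to the mean-field MMCA where
  payoffs are expectations.
* Health phase — a susceptible agent escapes infection from each neighbour
  infected at time t independently, at rate β or d·β according to the
  agent's *post-behaviour* strategy; infected agents recover with
  probability μ.

The module also provides an exact Markov-chain propagation over all 4^N
configurations for tiny networks, used as a brute-force oracle for the
sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapacityError, ParameterError, StateError
from .mmca import DI, DS, TI, TS, ModelParams, state_payoffs
from .network import MultiplexNetwork

#: Strategy of each discrete state: False = D, True = T.
_IS_T = np.array([False, False, True, True])
#: Health of each discrete state: False = susceptible, True = infected.
_IS_I = np.array([False, True, False, True])


@dataclass
class AgentConfiguration:
    """Discrete state assignment of all agents at one time step."""

    states: np.ndarray
    step: int = 0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1:
            raise StateError("states must be a 1-D vector")
        if not np.isin(self.states, (DS, DI, TS, TI)).all():
            raise StateError("states must be in {DS, DI, TS, TI} = {0,1,2,3}")

    @property
    def is_T(self) -> np.ndarray:
        return _IS_T[self.states]

    @property
    def is_infected(self) -> np.ndarray:
        return _IS_I[self.states]

    @property
    def rho_T(self) -> float:
        return float(self.is_T.mean())

    @property
    def rho_I(self) -> float:
        return float(self.is_infected.mean())


@dataclass
class EnsembleSummary:
    """Across-run statistics of a Monte Carlo ensemble.

    ``rho_*_mean``/``rho_*_sd`` are per-step across-run means and standard
    deviations; ``steady_rho_I`` is the across-run mean of each run's
    trailing-window ρ_I average.
    """

    n_runs: int
    rho_T_mean: np.ndarray
    rho_T_sd: np.ndarray
    rho_I_mean: np.ndarray
    rho_I_sd: np.ndarray
    steady_rho_I: float


def _switch_probabilities(
    config: AgentConfiguration, network: MultiplexNetwork, params: ModelParams
) -> np.ndarray:
    """Per-agent probability of switching strategy in the behaviour phase.

    1 − Π over opposite-strategy neighbours j of (1 − Γ(π_i, π_j)), the
    complement of the retention product evaluated at the realised states.
    """
    payoff_vec = state_payoffs(params)
    pay = payoff_vec[config.states]
    with np.errstate(over="ignore"):  # exp overflow saturates to Gamma = 0
        gamma = 1.0 / (1.0 + np.exp(-(pay[None, :] - pay[:, None]) / params.omega))
    opposite = config.is_T[None, :] != config.is_T[:, None]
    factors = 1.0 - network.adj_behaviour * opposite * gamma
    return 1.0 - np.prod(factors, axis=1)


def mc_step(
    config: AgentConfiguration,
    network: MultiplexNetwork,
    params: ModelParams,
    rng: np.random.Generator,
) -> AgentConfiguration:
    """One synchronous stochastic step: behaviour phase, then health phase."""
    if len(config.states) != network.n_nodes:
        raise ParameterError("configuration and network sizes differ")
    n = network.n_nodes

    # Phase 1: strategy imitation.
    switch = rng.random(n) < _switch_probabilities(config, network, params)
    new_is_t = np.where(switch, ~config.is_T, config.is_T)

    # Phase 2: infection / recovery using time-t health states. Each
    # infected neighbour is an independent trigger at the same rate, so the
    # escape probability collapses to (1 - rate)^(#infected neighbours).
    n_inf = network.adj_contact @ config.is_infected.astype(np.float64)
    rate = np.where(new_is_t, params.d * params.beta, params.beta)
    p_infect = 1.0 - (1.0 - rate) ** n_inf
    draws = rng.random(n)
    new_infected = np.where(
        config.is_infected, draws >= params.mu, draws < p_infect
    )

    new_states = np.where(
        new_is_t,
        np.where(new_infected, TI, TS),
        np.where(new_infected, DI, DS),
    )
    return AgentConfiguration(states=new_states, step=config.step + 1)


def sample_initial_configuration(
    n_nodes: int, sigma0: float, rho0: float, rng: np.random.Generator
) -> AgentConfiguration:
    """Draw i.i.d. node states from the (σ0, ρ0) product mixing."""
    is_t = rng.random(n_nodes) < sigma0
    infected = rng.random(n_nodes) < rho0
    states = np.where(is_t, np.where(infected, TI, TS), np.where(infected, DI, DS))
    return AgentConfiguration(states=states, step=0)


def run_mc(
    network: MultiplexNetwork,
    params: ModelParams,
    initial: AgentConfiguration,
    n_steps: int,
    rng: np.random.Generator,
    intervention=None,
) -> tuple[np.ndarray, np.ndarray]:
    """One trajectory; returns (rho_T, rho_I) arrays of length n_steps + 1."""

    def clamp(c: AgentConfiguration, t: int) -> AgentConfiguration:
        if intervention is None or not intervention.seed_set:
            return c
        if t == intervention.apply_time or (
            intervention.persistent and t >= intervention.apply_time
        ):
            from .interventions import modulate_mc

            return modulate_mc(c, intervention.seed_set)
        return c

    config = clamp(initial, 0)
    rho_t = np.empty(n_steps + 1)
    rho_i = np.empty(n_steps + 1)
    rho_t[0], rho_i[0] = config.rho_T, config.rho_I
    for t in range(1, n_steps + 1):
        config = clamp(mc_step(config, network, params, rng), t)
        rho_t[t], rho_i[t] = config.rho_T, config.rho_I
    return rho_t, rho_i


def run_mc_ensemble(
    network: MultiplexNetwork,
    params: ModelParams,
    init_fracs: tuple[float, float],
    n_steps: int,
    n_runs: int,
    rng_seed: int,
    intervention=None,
    steady_window: int = 100,
) -> EnsembleSummary:
    """Average ``n_runs`` independent trajectories with distinct sub-seeds.

    Initial configurations are drawn i.i.d. per node from the product
    mixing ``init_fracs = (sigma0, rho0)``; any intervention is applied
    identically in every run. Deterministic for a fixed ``rng_seed``.
    """
    if n_runs < 1:
        raise ParameterError(f"n_runs must be >= 1, got {n_runs}")
    if steady_window > n_steps + 1:
        raise ParameterError("steady_window exceeds trajectory length")
    sigma0, rho0 = init_fracs
    seeds = np.random.SeedSequence(rng_seed).spawn(n_runs)
    all_t = np.empty((n_runs, n_steps + 1))
    all_i = np.empty((n_runs, n_steps + 1))
    for k, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        init = sample_initial_configuration(network.n_nodes, sigma0, rho0, rng)
        all_t[k], all_i[k] = run_mc(
            network, params, init, n_steps, rng, intervention=intervention
        )
    steady = float(all_i[:, -steady_window:].mean(axis=1).mean())
    return EnsembleSummary(
        n_runs=n_runs,
        rho_T_mean=all_t.mean(axis=0),
        rho_T_sd=all_t.std(axis=0, ddof=0),
        rho_I_mean=all_i.mean(axis=0),
        rho_I_sd=all_i.std(axis=0, ddof=0),
        steady_rho_I=steady,
    )


def _per_agent_next_distribution(
    states: np.ndarray, network: MultiplexNetwork, params: ModelParams
) -> np.ndarray:
    """N×4 matrix of each agent's next-state distribution given the full
    configuration; agents transition independently given time-t states."""
    config = AgentConfiguration(states=states)
    n = network.n_nodes
    switch = _switch_probabilities(config, network, params)
    n_inf = network.adj_contact @ config.is_infected.astype(np.float64)
    out = np.zeros((n, 4))
    for i in range(n):
        for strat_is_t, p_strat in (
            (config.is_T[i], 1.0 - switch[i]),
            (not config.is_T[i], switch[i]),
        ):
            rate = params.d * params.beta if strat_is_t else params.beta
            if config.is_infected[i]:
                p_inf = 1.0 - params.mu
            else:
                p_inf = 1.0 - (1.0 - rate) ** n_inf[i]
            s_state, i_state = (TS, TI) if strat_is_t else (DS, DI)
            out[i, s_state] += p_strat * (1.0 - p_inf)
            out[i, i_state] += p_strat * p_inf
    return out


def exact_transition_matrix(
    network: MultiplexNetwork, params: ModelParams
) -> np.ndarray:
    """Exact 4^N × 4^N one-step transition matrix of the agent dynamics.

    Configurations are indexed in base 4, node 0 the most significant
    digit. Feasible only for N ≤ 4 (≤ 256 configurations).
    """
    n = network.n_nodes
    if n > 4:
        raise CapacityError(f"exact enumeration limited to N <= 4, got N={n}")
    n_cfg = 4**n
    digits = (np.arange(n_cfg)[:, None] // (4 ** np.arange(n - 1, -1, -1))[None, :]) % 4
    trans = np.empty((n_cfg, n_cfg))
    for c in range(n_cfg):
        per_agent = _per_agent_next_distribution(digits[c], network, params)
        # P(c -> c') = prod_i per_agent[i, state_i(c')]
        probs = per_agent[np.arange(n)[None, :], digits]  # (n_cfg, n)
        trans[c] = probs.prod(axis=1)
    return trans


def exact_chain_distribution(
    network: MultiplexNetwork,
    params: ModelParams,
    initial_distribution: np.ndarray,
    n_steps: int,
) -> np.ndarray:
    """Propagate a distribution over all 4^N configurations exactly."""
    dist = np.asarray(initial_distribution, dtype=np.float64)
    trans = exact_transition_matrix(network, params)
    if dist.shape != (trans.shape[0],):
        raise ParameterError(
            f"initial distribution must have length {trans.shape[0]}, got {dist.shape}"
        )
    for _ in range(n_steps):
        dist = dist @ trans
    return dist


def configuration_index(states: np.ndarray) -> int:
    """Base-4 index of a configuration (node 0 most significant)."""
    states = np.asarray(states)
    n = len(states)
    return int((states * 4 ** np.arange(n - 1, -1, -1)).sum())
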