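"""Network interventions: seed selection, behavioural modulation, K-sweeps.

Both seeding strategies exploit the friendship paradox — a random neighbour
of a random node has above-average degree — to reach well-connected
individuals without global degree information. The ego-based strategy draws
a random node (the ego) and selects one of its neighbours at random; the
alter-based strategy includes each of the ego's neighbours independently
with probability P. Selected seeds have their strategy clamped to support
(T); their health status is never touched.

The K-sweep maps out infection density and epidemic threshold as a function
of the number of seeds, locating the interval of intervention proportions
that beats the no-intervention baseline on both indicators at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, SelectionExhaustionError
from .mmca import DI, DS, TI, TS, ModelParams, StateMatrix, run_mmca, steady_summary
from .network import MultiplexNetwork
from .threshold import epidemic_threshold

_MAX_ATTEMPT_FACTOR = 200  # draw attempts per requested seed before giving up


@dataclass
class InterventionSpec:
    """Specification and realisation of one network intervention.

    ``strategy`` is ``"none"``, ``"ego"`` or ``"alter"``; ``k_seeds`` the
    number K of seed nodes; ``neighbour_prob`` the per-neighbour inclusion
    probability P (alter only); ``apply_time`` the step at which clamping
    starts; ``persistent`` whether seeds are re-clamped after every
    subsequent step (the default — one-shot modulation decays by imitation
    within a few steps). ``seed_set`` is filled by :func:`realize`.
    """

    strategy: str = "none"
    k_seeds: int = 0
    neighbour_prob: float = 1.0
    apply_time: int = 0
    persistent: bool = True
    rng_seed: int = 0
    seed_set: tuple[int, ...] = field(default=())

    def __post_init__(self):
        if self.strategy not in ("none", "ego", "alter"):
            raise ParameterError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "none" and self.k_seeds != 0:
            raise ParameterError("strategy 'none' requires k_seeds = 0")
        if self.k_seeds < 0:
            raise ParameterError("k_seeds must be nonnegative")
        if not 0.0 < self.neighbour_prob <= 1.0:
            raise ParameterError("neighbour_prob must be in (0, 1]")
        if self.apply_time < 0:
            raise ParameterError("apply_time must be nonnegative")

    def realize(self, network: MultiplexNetwork, rng=None) -> "InterventionSpec":
        """Return a copy with ``seed_set`` drawn for ``network``."""
        if rng is None:
            rng = np.random.default_rng(self.rng_seed)
        if self.strategy == "none" or self.k_seeds == 0:
            seeds: tuple[int, ...] = ()
        elif self.strategy == "ego":
            seeds = tuple(sorted(select_seeds_ego(network, self.k_seeds, rng)))
        else:
            seeds = tuple(
                sorted(select_seeds_alter(network, self.k_seeds, self.neighbour_prob, rng))
            )
        return InterventionSpec(
            strategy=self.strategy,
            k_seeds=self.k_seeds,
            neighbour_prob=self.neighbour_prob,
            apply_time=self.apply_time,
            persistent=self.persistent,
            rng_seed=self.rng_seed,
            seed_set=seeds,
        )


def _neighbour_lists(network: MultiplexNetwork) -> list[np.ndarray]:
    return [np.flatnonzero(network.adj_behaviour[i]) for i in range(network.n_nodes)]


def select_seeds_ego(
    network: MultiplexNetwork, k_seeds: int, rng: np.random.Generator
) -> set[int]:
    """Ego-based seeding: repeat (random ego → one random neighbour) until K
    distinct seeds are collected. Degree-0 egos are redrawn."""
    n = network.n_nodes
    if k_seeds > n:
        raise ParameterError(f"k_seeds={k_seeds} exceeds n_nodes={n}")
    neigh = _neighbour_lists(network)
    seeds: set[int] = set()
    attempts = 0
    max_attempts = _MAX_ATTEMPT_FACTOR * max(k_seeds, 1)
    while len(seeds) < k_seeds:
        if attempts >= max_attempts:
            raise SelectionExhaustionError(
                f"collected {len(seeds)}/{k_seeds} seeds after {attempts} attempts"
            )
        attempts += 1
        ego = int(rng.integers(n))
        if len(neigh[ego]) == 0:
            continue
        seeds.add(int(rng.choice(neigh[ego])))
    return seeds


def select_seeds_alter(
    network: MultiplexNetwork,
    k_seeds: int,
    neighbour_prob: float,
    rng: np.random.Generator,
) -> set[int]:
    """Alter-based seeding: each neighbour of a random ego enters the seed
    set independently with probability P; if the final batch overshoots K,
    the excess is dropped uniformly at random from that batch."""
    n = network.n_nodes
    if not 0.0 < neighbour_prob <= 1.0:
        raise ParameterError("neighbour_prob must be in (0, 1]")
    if k_seeds > n:
        raise ParameterError(f"k_seeds={k_seeds} exceeds n_nodes={n}")
    neigh = _neighbour_lists(network)
    seeds: set[int] = set()
    attempts = 0
    max_attempts = _MAX_ATTEMPT_FACTOR * max(k_seeds, 1)
    while len(seeds) < k_seeds:
        if attempts >= max_attempts:
            raise SelectionExhaustionError(
                f"collected {len(seeds)}/{k_seeds} seeds after {attempts} attempts"
            )
        attempts += 1
        ego = int(rng.integers(n))
        candidates = neigh[ego]
        if len(candidates) == 0:
            continue
        included = candidates[rng.random(len(candidates)) < neighbour_prob]
        batch = [int(c) for c in included if int(c) not in seeds]
        room = k_seeds - len(seeds)
        if len(batch) > room:
            batch = list(rng.choice(batch, size=room, replace=False))
        seeds.update(batch)
    return seeds


def modulate_mmca(state: StateMatrix, seed_set) -> StateMatrix:
    """Clamp seed nodes to the T strategy, preserving health marginals.

    Per seed: p^TS += p^DS, p^TI += p^DI, then p^DS = p^DI = 0, so p^T = 1
    afterwards and the population infection density is unchanged.
    """
    idx = np.asarray(sorted(seed_set), dtype=np.int64)
    if idx.size == 0:
        return state
    if idx.min() < 0 or idx.max() >= state.n_nodes:
        raise ParameterError("seed index out of range")
    p = state.probs.copy()
    p[idx, TS] += p[idx, DS]
    p[idx, TI] += p[idx, DI]
    p[idx, DS] = 0.0
    p[idx, DI] = 0.0
    return StateMatrix(p)


def modulate_mc(config, seed_set):
    """Clamp seed agents to the T strategy: DS → TS, DI → TI."""
    from .montecarlo import AgentConfiguration

    idx = np.asarray(sorted(seed_set), dtype=np.int64)
    if idx.size == 0:
        return config
    if idx.min() < 0 or idx.max() >= len(config.states):
        raise ParameterError("seed index out of range")
    states = config.states.copy()
    states[idx] = np.where(states[idx] == DS, TS, states[idx])
    states[idx] = np.where(states[idx] == DI, TI, states[idx])
    return AgentConfiguration(states=states, step=config.step)


def sweep_seed_counts(
    network: MultiplexNetwork,
    params: ModelParams,
    strategy: str,
    k_grid,
    neighbour_prob: float = 0.4,
    n_replicates: int = 10,
    rng_seed: int = 0,
    initial: StateMatrix | None = None,
    n_steps: int = 2000,
    window: int = 100,
    apply_time: int = 0,
) -> pd.DataFrame:
    """Steady infection density and epidemic threshold versus seed count K.

    For each K > 0 and each replicate, seeds are drawn afresh with a
    distinct sub-seed, clamped persistently from ``apply_time``, the MMCA is
    run, and β_c is computed from that run's own trailing-window p^T. The
    K = 0 row is the deterministic no-intervention baseline (zero sd).

    Returns a DataFrame with columns
    ``K, rho_I_mean, rho_I_sd, beta_c_mean, beta_c_sd``.
    """
    if strategy not in ("ego", "alter"):
        raise ParameterError(f"sweep strategy must be 'ego' or 'alter', got {strategy!r}")
    k_grid = sorted(int(k) for k in k_grid)
    if any(k < 0 or k > network.n_nodes for k in k_grid):
        raise ParameterError("k_grid values must lie in [0, N]")
    if initial is None:
        initial = StateMatrix.uniform_mixing(network.n_nodes)
    seed_seq = np.random.SeedSequence(rng_seed)
    rows = []
    for k in k_grid:
        if k == 0:
            rho, bc = _one_sweep_run(network, params, initial, None, n_steps, window)
            rows.append((k, rho, 0.0, bc, 0.0))
            continue
        rhos, bcs = [], []
        for sub in seed_seq.spawn(n_replicates):
            rng = np.random.default_rng(sub)
            spec = InterventionSpec(
                strategy=strategy,
                k_seeds=k,
                neighbour_prob=neighbour_prob,
                apply_time=apply_time,
                persistent=True,
            ).realize(network, rng)
            rho, bc = _one_sweep_run(network, params, initial, spec, n_steps, window)
            rhos.append(rho)
            bcs.append(bc)
        rows.append(
            (k, float(np.mean(rhos)), float(np.std(rhos)), float(np.mean(bcs)), float(np.std(bcs)))
        )
    return pd.DataFrame(
        rows, columns=["K", "rho_I_mean", "rho_I_sd", "beta_c_mean", "beta_c_sd"]
    )


def _one_sweep_run(network, params, initial, spec, n_steps, window):
    traj = run_mmca(
        initial, network, params, n_steps, intervention=spec, pT_window=window
    )
    _, rho_i, _, _ = steady_summary(traj, window)
    bc = epidemic_threshold(network, traj.pT_window_mean, params).beta_c
    return rho_i, bc


def optimal_interval(sweep: pd.DataFrame) -> list[int]:
    """Seed counts beating the no-intervention baseline on both indicators.

    Returns the sorted K > 0 with mean ρ_I(K) < ρ_I(0) and mean
    β_c(K) > β_c(0). Requires the K = 0 baseline row.
    """
    baseline = sweep[sweep["K"] == 0]
    if baseline.empty:
        raise ParameterError("sweep table lacks the K = 0 baseline row")
    rho0 = float(baseline["rho_I_mean"].iloc[0])
    bc0 = float(baseline["beta_c_mean"].iloc[0])
    good = sweep[
        (sweep["K"] > 0)
        & (sweep["rho_I_mean"] < rho0)
        & (sweep["beta_c_mean"] > bc0)
    ]
    return sorted(int(k) for k in good["K"])
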