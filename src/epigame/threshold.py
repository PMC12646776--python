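"""Epidemic threshold of the coupled game-epidemic system.

Linearising the master equations around the disease-free state shows that
the critical infection rate is β_c = μ / Λ_max(H), where H is the contact
adjacency reweighted by the steady-state strategy distribution:

    h_ji = (1 − (1 − d) · p_i^T) · b_ji.

More support for the protective strategy (larger p^T) shrinks the entries
of H, lowers its Perron root and raises the threshold; d = 1 (no protection
benefit) collapses H to the bare contact matrix B. Because the steady
regime of the full system is periodic rather than stationary, the p^T
vector fed into H is the per-node average over a trailing window of an MMCA
run at the scenario's operating β.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateThresholdError, ParameterError
from .mmca import ModelParams, StateMatrix, run_mmca
from .network import MultiplexNetwork


@dataclass(frozen=True)
class ThresholdResult:
    """Epidemic threshold and the ingredients it was computed from."""

    beta_c: float
    spectral_radius: float
    pT_steady: np.ndarray
    reference_beta: float


def build_h_matrix(
    network: MultiplexNetwork, pT_steady: np.ndarray, d: float
) -> np.ndarray:
    """Behaviour-weighted contact matrix H with h_ji = (1 − (1−d) p_i^T) b_ji.

    The factor involving node i scales *column* i of B: it encodes how much
    node i's own protective behaviour attenuates the infection pressure it
    receives. With p^T ≡ 0 or d = 1, H = B; with p^T ≡ 1, H = d·B.
    """
    pT = np.asarray(pT_steady, dtype=np.float64)
    if pT.shape != (network.n_nodes,):
        raise ParameterError(
            f"pT_steady must have shape ({network.n_nodes},), got {pT.shape}"
        )
    if pT.min() < -1e-9 or pT.max() > 1 + 1e-9:
        raise ParameterError("pT_steady entries must lie in [0, 1]")
    factor = 1.0 - (1.0 - d) * np.clip(pT, 0.0, 1.0)
    return network.adj_contact * factor[None, :]


def spectral_radius(matrix: np.ndarray) -> float:
    """Largest-magnitude eigenvalue; equals the Perron root for nonnegative H."""
    return float(np.max(np.abs(np.linalg.eigvals(matrix))))


def epidemic_threshold(
    network: MultiplexNetwork,
    pT_steady: np.ndarray,
    params: ModelParams,
    reference_beta: float | None = None,
) -> ThresholdResult:
    """Critical infection rate β_c = μ / Λ_max(H).

    The disease-free state is locally stable for β < β_c and unstable for
    β > β_c. Raises if the contact graph has no edges (Λ_max = 0).
    """
    h = build_h_matrix(network, pT_steady, params.d)
    lam = spectral_radius(h)
    if lam <= 0:
        raise DegenerateThresholdError(
            "contact graph has no edges: spectral radius is zero"
        )
    return ThresholdResult(
        beta_c=params.mu / lam,
        spectral_radius=lam,
        pT_steady=np.asarray(pT_steady, dtype=np.float64).copy(),
        reference_beta=params.beta if reference_beta is None else reference_beta,
    )


def steady_state_pT(
    network: MultiplexNetwork,
    params: ModelParams,
    initial: StateMatrix,
    n_steps: int = 2000,
    window: int = 100,
    intervention=None,
) -> np.ndarray:
    """Per-node p^T averaged over the final ``window`` steps of an MMCA run.

    Runs the full coupled dynamics at the scenario's parameters, including
    any intervention clamping; trailing-window averaging turns the periodic
    steady regime into one representative strategy vector.
    """
    traj = run_mmca(
        initial, network, params, n_steps, intervention=intervention, pT_window=window
    )
    return traj.pT_window_mean


def threshold_from_run(
    network: MultiplexNetwork,
    params: ModelParams,
    initial: StateMatrix,
    n_steps: int = 2000,
    window: int = 100,
    intervention=None,
) -> ThresholdResult:
    """Convenience: run the dynamics at the operating β, then compute β_c."""
    pT = steady_state_pT(network, params, initial, n_steps, window, intervention)
    return epidemic_threshold(network, pT, params)


def threshold_fixed_point(
    network: MultiplexNetwork,
    params: ModelParams,
    initial: StateMatrix,
    n_steps: int = 2000,
    window: int = 100,
    intervention=None,
    rel_tol: float = 1e-4,
    max_iter: int = 20,
) -> ThresholdResult:
    """Self-consistent threshold: re-evaluate the steady p^T at β = β_c.

    Iterates β ← μ / Λ_max(H(p^T(β))) until the relative change in β_c
    falls below ``rel_tol``. Off the default path: the per-scenario
    convention is to evaluate p^T at the operating β.
    """
    beta = params.beta
    result = None
    for _ in range(max_iter):
        p = ModelParams(
            beta=beta,
            mu=params.mu,
            d=params.d,
            cost_infection=params.cost_infection,
            cost_support=params.cost_support,
            omega=params.omega,
        )
        pT = steady_state_pT(network, p, initial, n_steps, window, intervention)
        result = epidemic_threshold(network, pT, p, reference_beta=beta)
        if abs(result.beta_c - beta) <= rel_tol * max(beta, 1e-12):
            return result
        beta = min(result.beta_c, 1.0)
    return result
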