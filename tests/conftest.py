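import numpy as np
import pytest

from epigame import ModelParams, MultiplexNetwork, StateMatrix, generate_ba_network


@pytest.fixture
def base_params() -> ModelParams:
    """Scalar constants of the base oscillatory scenario."""
    return ModelParams(
        beta=0.3, mu=0.5, d=0.6, cost_infection=2.0, cost_support=0.2, omega=0.5
    )


@pytest.fixture
def edge_network() -> MultiplexNetwork:
    """Two nodes joined by a single edge."""
    adj = np.array([[0, 1], [1, 0]], dtype=float)
    return MultiplexNetwork(2, adj, adj.copy())


@pytest.fixture
def path3_network() -> MultiplexNetwork:
    """Three-node path 0–1–2."""
    adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return MultiplexNetwork(3, adj, adj.copy())


@pytest.fixture
def star5_network() -> MultiplexNetwork:
    """Star on 5 nodes; node 0 is the hub."""
    adj = np.zeros((5, 5))
    adj[0, 1:] = adj[1:, 0] = 1.0
    return MultiplexNetwork(5, adj, adj.copy())


@pytest.fixture(scope="session")
def ba500() -> MultiplexNetwork:
    """The N=500, m=3 scale-free substrate used in the figure-scale scenarios."""
    return generate_ba_network(500, 3, 1)


@pytest.fixture(scope="session")
def ba200() -> MultiplexNetwork:
    return generate_ba_network(200, 3, 1)


def random_state(n_nodes: int, rng: np.random.Generator) -> StateMatrix:
    """Uniformly random valid state matrix (Dirichlet rows)."""
    return StateMatrix(rng.dirichlet(np.ones(4), size=n_nodes))


def random_network(n_nodes: int, rng: np.random.Generator, p: float = 0.5) -> MultiplexNetwork:
    """Random symmetric simple graph (Erdős–Rényi-style)."""
    upper = rng.random((n_nodes, n_nodes)) < p
    adj = np.triu(upper, 1).astype(float)
    adj = adj + adj.T
    return MultiplexNetwork(n_nodes, adj, adj.copy())
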