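"""Multiplex network substrate shared by the behaviour and contact layers.

The coupled game-epidemic model runs on a two-layer multiplex network: an
upper behaviour layer on which strategies are imitated and a lower contact
layer on which the disease spreads. Both layers share the node set and, in
the regime studied here, the same edge set, so every constructor in this
module builds one undirected simple graph and assigns its adjacency matrix
to both layers.

Besides synthetic scale-free substrates (Barabási–Albert growth) the module
reads two plain-text formats: static edge lists and temporal contact files
in the SocioPatterns dialect (rows ``t i j`` on a 20-second lattice), the
latter aggregated into a static daily-union contact graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import EmptyNetworkError, ParameterError, ParseError

logger = logging.getLogger(__name__)

#: Resolution of SocioPatterns-style proximity sensors, in seconds.
CONTACT_RESOLUTION_S = 20

#: Default aggregation window: one day, in seconds.
DAY_S = 86_400


@dataclass(frozen=True)
class MultiplexNetwork:
    """Two-layer multiplex network over a shared node set.

    Attributes
    ----------
    n_nodes
        Number of nodes N.
    adj_behaviour
        N×N symmetric binary adjacency matrix A of the behaviour layer.
    adj_contact
        N×N symmetric binary adjacency matrix B of the contact layer.
    node_ids
        External labels in internal-index order (index ``i`` ↔ ``node_ids[i]``).
    """

    n_nodes: int
    adj_behaviour: np.ndarray
    adj_contact: np.ndarray
    node_ids: tuple = field(default=())

    def __post_init__(self):
        a = np.asarray(self.adj_behaviour)
        b = np.asarray(self.adj_contact)
        n = self.n_nodes
        if n <= 0:
            raise EmptyNetworkError("network must contain at least one node")
        for name, m in (("behaviour", a), ("contact", b)):
            if m.shape != (n, n):
                raise ParameterError(f"{name} adjacency must be {n}x{n}, got {m.shape}")
            if not np.array_equal(m, m.T):
                raise ParameterError(f"{name} adjacency must be symmetric")
            if np.any(np.diag(m) != 0):
                raise ParameterError(f"{name} adjacency must have zero diagonal")
            if not np.isin(m, (0, 1)).all():
                raise ParameterError(f"{name} adjacency entries must be 0 or 1")
        if self.node_ids and len(self.node_ids) != n:
            raise ParameterError("node_ids length must equal n_nodes")
        object.__setattr__(self, "adj_behaviour", a.astype(np.float64))
        object.__setattr__(self, "adj_contact", b.astype(np.float64))
        if not self.node_ids:
            object.__setattr__(self, "node_ids", tuple(range(n)))

    @property
    def degrees(self) -> np.ndarray:
        """Node degrees on the (shared) contact layer."""
        return self.adj_contact.sum(axis=1).astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.adj_contact.sum()) // 2

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "MultiplexNetwork":
        """Build a multiplex with both layers equal to ``graph``'s adjacency.

        Node labels are kept as external ids; internal indices follow the
        graph's node insertion order.
        """
        if graph.number_of_nodes() == 0:
            raise EmptyNetworkError("graph has no nodes")
        nodes = list(graph.nodes())
        adj = nx.to_numpy_array(graph, nodelist=nodes, dtype=np.float64)
        adj = (adj > 0).astype(np.float64)
        np.fill_diagonal(adj, 0.0)
        return cls(len(nodes), adj, adj.copy(), tuple(nodes))


@dataclass(frozen=True, order=True)
class TemporalContactRecord:
    """One proximity event: nodes ``node_u`` and ``node_v`` in contact at ``timestamp`` seconds."""

    timestamp: int
    node_u: str
    node_v: str


def generate_ba_network(n_nodes: int, m_attach: int, rng_seed: int) -> MultiplexNetwork:
    """Grow a scale-free multiplex substrate by preferential attachment.

    The graph starts from a complete seed graph on ``m_attach + 1`` nodes and
    adds the remaining nodes one at a time, each wiring ``m_attach`` edges to
    existing nodes with probability proportional to their current degree
    (Barabási–Albert growth). The result is connected and is used for both
    the behaviour and contact layers.

    Parameters
    ----------
    n_nodes
        Final number of nodes N; must exceed ``m_attach``.
    m_attach
        Edges attached by each incoming node; must be ≥ 1.
    rng_seed
        Seed for the growth process; the construction is reproducible.
    """
    if m_attach < 1:
        raise ParameterError(f"m_attach must be >= 1, got {m_attach}")
    if n_nodes <= m_attach + 1:
        # the complete seed graph already has m_attach + 1 nodes; growth
        # needs at least one arriving node beyond it
        raise ParameterError(
            f"n_nodes must exceed m_attach + 1, got n_nodes={n_nodes}, m_attach={m_attach}"
        )
    seed_graph = nx.complete_graph(m_attach + 1)
    graph = nx.barabasi_albert_graph(
        n_nodes, m_attach, seed=int(rng_seed), initial_graph=seed_graph
    )
    return MultiplexNetwork.from_graph(graph)


def load_edge_list(path) -> MultiplexNetwork:
    """Load an undirected simple graph from a two-column text edge list.

    Rows are two whitespace-separated node labels; lines starting with ``#``
    and blank lines are ignored. Duplicate rows and reversed duplicates
    collapse to a single edge. Labels are mapped to dense 0-based indices in
    first-appearance order; both layers share the loaded edge set.
    """
    graph = nx.Graph()
    n_rows = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(
                    f"expected two whitespace-separated labels, got {line!r}", lineno
                )
            u, v = parts
            if u == v:
                raise ParseError(f"self-loop on node {u!r} is not allowed", lineno)
            graph.add_edge(u, v)
            n_rows += 1
    if n_rows == 0:
        raise EmptyNetworkError(f"edge list {path!s} contains no edges")
    return MultiplexNetwork.from_graph(graph)


def load_temporal_contacts(path) -> list[TemporalContactRecord]:
    """Parse a SocioPatterns-style temporal contact file.

    Rows are ``t i j``: an integer timestamp in seconds followed by two node
    labels. Records are returned sorted by timestamp. Self-contacts are
    dropped with a warning rather than rejected, since sensor artefacts of
    this kind occur in deployed datasets.
    """
    records: list[TemporalContactRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"expected 't i j', got {line!r}", lineno)
            t_str, u, v = parts
            try:
                t = int(t_str)
            except ValueError:
                raise ParseError(f"non-integer timestamp {t_str!r}", lineno) from None
            if t < 0:
                raise ParseError(f"negative timestamp {t}", lineno)
            if u == v:
                logger.warning(
                    "%s:%d: dropping self-contact of node %r at t=%d", path, lineno, u, t
                )
                continue
            records.append(TemporalContactRecord(t, u, v))
    records.sort(key=lambda r: r.timestamp)
    return records


def aggregate_window(
    records: list[TemporalContactRecord],
    window_start: int | None = None,
    window_length: int = DAY_S,
) -> MultiplexNetwork:
    """Collapse temporal contacts in a time window into a static union graph.

    An edge (u, v) exists iff at least one contact between u and v falls in
    ``[window_start, window_start + window_length)``; contact counts are
    discarded, matching the binary adjacency the dynamics use. Nodes with no
    contact in the window are excluded and N is the number of active nodes.

    ``window_start`` defaults to the earliest timestamp among the records;
    ``window_length`` defaults to one day.
    """
    if window_length <= 0:
        raise ParameterError(f"window_length must be positive, got {window_length}")
    if not records:
        raise EmptyNetworkError("no contact records supplied")
    if window_start is None:
        window_start = min(r.timestamp for r in records)
    window_end = window_start + window_length
    graph = nx.Graph()
    for rec in records:
        if window_start <= rec.timestamp < window_end:
            graph.add_edge(rec.node_u, rec.node_v)
    if graph.number_of_nodes() == 0:
        raise EmptyNetworkError(
            f"no contacts in window [{window_start}, {window_end})"
        )
    return MultiplexNetwork.from_graph(graph)


def make_fixture_contacts(n_nodes: int, n_records: int, rng_seed: int, path) -> None:
    """Write a synthetic temporal-contact file in the SocioPatterns dialect.

    Emits ``n_records`` rows ``t i j`` with timestamps on the 20-second
    sensor lattice, node labels drawn uniformly from ``0..n_nodes-1`` with
    u ≠ v guaranteed, timestamps sorted ascending. Byte-identical output for
    a fixed seed, and round-trips through :func:`load_temporal_contacts`.
    """
    if n_nodes < 2:
        raise ParameterError(f"need at least 2 nodes to form contacts, got {n_nodes}")
    if n_records < 1:
        raise ParameterError(f"n_records must be >= 1, got {n_records}")
    rng = np.random.default_rng(rng_seed)
    # Timestamps spread over one day on the sensor lattice.
    n_slots = DAY_S // CONTACT_RESOLUTION_S
    times = np.sort(rng.integers(0, n_slots, size=n_records)) * CONTACT_RESOLUTION_S
    us = rng.integers(0, n_nodes, size=n_records)
    offsets = rng.integers(1, n_nodes, size=n_records)
    vs = (us + offsets) % n_nodes  # never equal to us
    with open(path, "w") as fh:
        for t, u, v in zip(times, us, vs):
            fh.write(f"{t}\t{u}\t{v}\n")
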