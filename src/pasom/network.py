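"""Starting-network generation and the edge-rewiring rules.

The graph is undirected and simple, over 0-based integer agent IDs, and is
backed by a dense boolean adjacency matrix: populations are small (hundreds
of agents) and the per-round observation counts are matrix-vector products
against the adjacency, so dense storage is both the fastest and the simplest
representation.  Conversion to/from :mod:`networkx` is provided at the
boundaries for I/O and interoperability.

Three rewiring rules act at the end of each round:

* ``disconnect_toxic`` — a constructive sharer with at least one surplus
  connection drops one neighbour who attacked the side it supported;
* ``connect_originator`` — a constructive sharer short of connections links
  to a same-side originator from its own sharing chain;
* ``reconnect_isolated`` — an agent with no connections joins a like-minded
  agent (same side of 0.5, or within gamma on the other side).
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable, Sequence

import networkx as nx
import numpy as np

from .config import ConfigError, NetworkSpec

if TYPE_CHECKING:  # pragma: no cover
    from .behaviour import RoundRecord

__all__ = [
    "NetworkState",
    "generate_cluster_network",
    "generate_lattice_network",
    "generate_network",
    "disconnect_toxic",
    "connect_originator",
    "reconnect_isolated",
]


class NetworkState:
    """Undirected simple graph over agents 0..n-1.

    ``adj`` is a symmetric boolean matrix with a zero diagonal.  ``partition``
    optionally records the cluster membership the generator used.
    """

    def __init__(self, n_agents: int,
                 edges: Iterable[tuple[int, int]] | None = None,
                 partition: np.ndarray | None = None):
        self.adj = np.zeros((n_agents, n_agents), dtype=bool)
        self.partition = partition
        if edges is not None:
            for i, j in edges:
                self.add_edge(int(i), int(j))

    # -- basic queries -------------------------------------------------
    @property
    def n_agents(self) -> int:
        return self.adj.shape[0]

    def degree(self) -> np.ndarray:
        return self.adj.sum(axis=1)

    def degree_of(self, i: int) -> int:
        return int(self.adj[i].sum())

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adj[i])

    def has_edge(self, i: int, j: int) -> bool:
        return bool(self.adj[i, j])

    @property
    def n_edges(self) -> int:
        return int(self.adj.sum()) // 2

    def edges(self) -> list[tuple[int, int]]:
        """Edge list with i < j, sorted."""
        ii, jj = np.nonzero(np.triu(self.adj, k=1))
        return list(zip(ii.tolist(), jj.tolist()))

    # -- mutation ------------------------------------------------------
    def add_edge(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("self-loops are not allowed")
        self.adj[i, j] = True
        self.adj[j, i] = True

    def remove_edge(self, i: int, j: int) -> None:
        self.adj[i, j] = False
        self.adj[j, i] = False

    def copy(self) -> "NetworkState":
        out = NetworkState.__new__(NetworkState)
        out.adj = self.adj.copy()
        out.partition = None if self.partition is None else self.partition.copy()
        return out

    # -- interop -------------------------------------------------------
    def to_networkx(self, opinions: np.ndarray | None = None) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_agents))
        g.add_edges_from(self.edges())
        if opinions is not None:
            nx.set_node_attributes(
                g, {i: float(op) for i, op in enumerate(opinions)}, "opinion")
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, n_agents: int | None = None) -> "NetworkState":
        n = n_agents if n_agents is not None else g.number_of_nodes()
        return cls(n, edges=((int(i), int(j)) for i, j in g.edges()))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NetworkState) and bool(np.array_equal(self.adj, other.adj))


def _cluster_sizes(n_agents: int, n_clusters: int, mean_size: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Random cluster sizes with mean ``mean_size`` and modest spread.

    Each cluster gets ``mean_size - 1`` agents deterministically and the
    remaining ``n_clusters`` agents are allocated multinomially, so sizes
    vary but the mean degree of the resulting graph stays close to the
    fully-balanced value.
    """
    base = mean_size - 1
    remainder = n_agents - base * n_clusters
    sizes = np.full(n_clusters, base, dtype=int)
    sizes += rng.multinomial(remainder, np.full(n_clusters, 1.0 / n_clusters))
    return sizes


def generate_cluster_network(spec: NetworkSpec, n_agents: int,
                             rng: np.random.Generator,
                             sizes: Sequence[int] | None = None) -> NetworkState:
    """Generate the clustered starting network.

    Agents are partitioned into ``spec.n_clusters`` groups; within-cluster
    pairs connect with ``p_within`` and between-cluster pairs with
    ``p_between``.  ``sizes`` overrides the random size draw (must sum to
    ``n_agents``).
    """
    if spec.n_clusters < 1 or n_agents < 1:
        raise ConfigError("cluster network needs at least one cluster and one agent")
    if sizes is None:
        sizes_arr = _cluster_sizes(n_agents, spec.n_clusters, spec.mean_cluster_size, rng)
    else:
        sizes_arr = np.asarray(sizes, dtype=int)
        if sizes_arr.sum() != n_agents:
            raise ConfigError("cluster sizes must sum to n_agents")
    labels = np.repeat(np.arange(len(sizes_arr)), sizes_arr)

    same = labels[:, None] == labels[None, :]
    p = np.where(same, spec.p_within, spec.p_between)
    upper = np.triu(rng.random((n_agents, n_agents)) < p, k=1)

    net = NetworkState(n_agents, partition=labels)
    net.adj = upper | upper.T
    return net


def _grid_shape(n: int) -> tuple[int, int, int]:
    """Most-cubic factorisation a <= b <= c with a*b*c = n."""
    best: tuple[int, int, int] | None = None
    for a in range(1, round(n ** (1 / 3)) + 2):
        if n % a:
            continue
        m = n // a
        for b in range(a, int(m ** 0.5) + 1):
            if m % b:
                continue
            cand = (a, b, m // b)
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] > best[1]):
                best = cand
    assert best is not None
    return best


def generate_lattice_network(n_agents: int) -> NetworkState:
    """3-D grid (lattice) network with nearest-neighbour edges.

    ``n_agents`` must factor into a genuine 3-D shape (a single agent is the
    degenerate 1x1x1 grid).
    """
    if n_agents < 1:
        raise ConfigError("need at least one agent")
    shape = _grid_shape(n_agents)
    if n_agents > 1 and shape[1] == 1:
        raise ConfigError(f"{n_agents} agents cannot form a 3-D grid")
    g = nx.grid_graph(dim=list(shape))
    mapping = {node: idx for idx, node in enumerate(sorted(g.nodes()))}
    return NetworkState.from_networkx(nx.relabel_nodes(g, mapping), n_agents)


def generate_network(spec: NetworkSpec, n_agents: int,
                     rng: np.random.Generator) -> NetworkState:
    """Dispatch on ``spec.kind`` (cluster, lattice, or file)."""
    if spec.kind == "cluster":
        return generate_cluster_network(spec, n_agents, rng)
    if spec.kind == "lattice":
        return generate_lattice_network(n_agents)
    if spec.kind == "file":
        from .io import read_network
        assert spec.path is not None
        return read_network(spec.path, n_agents=n_agents)
    raise ConfigError(f"unknown network kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Rewiring rules
# ---------------------------------------------------------------------------

def toxic_against(record: "RoundRecord", polarity: int) -> np.ndarray:
    """Boolean mask of agents whose toxic share this round attacked ``polarity``.

    A toxic share attacks the position opposite to the one its author
    supported, so the attackers of side I are the toxic sharers supporting
    1 - I.
    """
    from .behaviour import TOXIC
    return (record.action == TOXIC) & (record.supported == 1 - polarity)


def disconnect_toxic(agent: int, supported: int, desired_K: float,
                     network: NetworkState, record: "RoundRecord",
                     rng: np.random.Generator,
                     snapshot: NetworkState | None = None) -> bool:
    """Drop one connection that attacked the agent's supported side.

    Fires only when the agent holds at least one more connection than its
    optimum (``desired_K - K <= -1``) and at least one neighbour acted
    toxically against ``supported`` this round; the victim is chosen
    uniformly among those neighbours.  Candidates are evaluated on
    ``snapshot`` (the pre-rewiring graph) but the removal is applied to
    ``network``; a removal already performed from the other endpoint is
    skipped.  Returns True if an edge was removed.
    """
    view = snapshot if snapshot is not None else network
    K = view.degree_of(agent)
    if desired_K - K > -1:
        return False
    nb = view.neighbors(agent)
    candidates = nb[toxic_against(record, supported)[nb]]
    if candidates.size == 0:
        return False
    victim = int(rng.choice(candidates))
    if not network.has_edge(agent, victim):
        return False
    network.remove_edge(agent, victim)
    return True


def connect_originator(agent: int, supported: int, desired_K: float,
                       chain_id: int, record: "RoundRecord",
                       network: NetworkState, rng: np.random.Generator,
                       snapshot: NetworkState | None = None) -> bool:
    """Link to a same-side originator from the agent's own sharing chain.

    Fires only when the agent wants at least one more connection
    (``desired_K - K >= 1``).  Candidates are originators in the same chain
    who supported ``supported`` and are not already connected; one is chosen
    uniformly.  Returns True if an edge was added.
    """
    view = snapshot if snapshot is not None else network
    K = view.degree_of(agent)
    if desired_K - K < 1:
        return False
    mask = (record.originator
            & (record.chain == chain_id)
            & (record.supported == supported)
            & ~view.adj[agent])
    mask[agent] = False
    candidates = np.flatnonzero(mask)
    if candidates.size == 0:
        return False
    target = int(rng.choice(candidates))
    if network.has_edge(agent, target):
        return False
    network.add_edge(agent, target)
    return True


def reconnect_isolated(agent: int, opinions: np.ndarray, gamma: float,
                       network: NetworkState, rng: np.random.Generator) -> bool:
    """Connect an isolated agent to a like-minded one.

    Candidates share the agent's side of 0.5, or sit on the other side but
    within ``gamma`` of the agent's opinion.  One candidate is chosen
    uniformly; with no candidates the agent stays isolated.  Returns True if
    an edge was added.
    """
    own = opinions[agent]
    same_side = (opinions > 0.5) == (own > 0.5)
    within_tolerance = np.abs(opinions - own) <= gamma
    mask = same_side | within_tolerance
    mask[agent] = False
    candidates = np.flatnonzero(mask)
    if candidates.size == 0:
        return False
    network.add_edge(agent, int(rng.choice(candidates)))
    return True
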