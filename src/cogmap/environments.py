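"""Problem spaces for the cognitive map learner.

Two families of discrete environments are provided:

* abstract graphs, where every node is a distinct one-hot observation and
  every directed traversal of an edge is a distinct action (two actions per
  undirected edge);
* 2D grids (rectilinear or hexagonal), where observations are cells but the
  small action set (4 or 6 moves) is state-invariant — the same one-hot code
  means "move east" everywhere, which is what lets a learner generalize to
  edges it never traversed.

Both expose the same stepping protocol consumed by the planner:
``reset(node) -> node``, ``step(action) -> node``, ``affordances() -> g``,
``observation_vector(node) -> one-hot``.  Affordances are [0, 1] scores: 0
for an unavailable action, 1 for a free one, ``1/cost`` on weighted graphs
so that cheap edges are preferred at equal utility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GraphEnvironment",
    "GridEnvironment",
    "ReplayBuffer",
    "generate_random_graph",
    "generate_small_world",
    "generate_challenge_graph",
    "assign_edge_costs",
    "add_virtual_goal",
    "generate_grid",
    "sample_exploration",
    "read_edge_list",
    "write_edge_list",
]


class GenerationError(RuntimeError):
    """A generator could not realize the requested structure."""


# --------------------------------------------------------------------- #
# discrete environment base


class _DiscreteEnvironment:
    """Tabular environment: transition table + affordance matrix.

    ``transitions[u, k]`` is the node reached by action k from node u, or -1
    if k is not afforded there.  ``afford[u, k]`` is the affordance score.
    """

    def __init__(self, transitions: np.ndarray, afford: np.ndarray,
                 action_costs: np.ndarray | None = None):
        self.transitions = transitions
        self.afford = afford
        self.action_costs = action_costs  # same shape as transitions, or None
        self._current: int | None = None

    @property
    def n_o(self) -> int:
        return self.transitions.shape[0]

    @property
    def n_a(self) -> int:
        return self.transitions.shape[1]

    # planner protocol ------------------------------------------------- #

    def reset(self, node: int) -> int:
        if not 0 <= node < self.n_o:
            raise ValueError(f"node {node} outside [0, {self.n_o})")
        self._current = int(node)
        return self._current

    def step(self, action: int) -> int:
        if self._current is None:
            raise RuntimeError("call reset() before step()")
        nxt = int(self.transitions[self._current, action])
        if nxt < 0:
            raise ValueError(f"action {action} not afforded at node {self._current}")
        self._current = nxt
        return nxt

    def affordances(self, node: int | None = None) -> np.ndarray:
        u = self._current if node is None else node
        return self.afford[u].copy()

    def observation_vector(self, node: int) -> np.ndarray:
        v = np.zeros(self.n_o)
        v[node] = 1.0
        return v

    def is_goal(self, node: int, goal: int) -> bool:
        return node == goal

    def action_cost(self, node: int, action: int) -> float:
        if self.action_costs is None:
            return 1.0
        return float(self.action_costs[node, action])

    def neighbors_of(self, node: int) -> list[tuple[int, int]]:
        """(action, next node) pairs afforded at ``node``."""
        row = self.transitions[node]
        return [(k, int(row[k])) for k in np.flatnonzero(row >= 0)]


class GraphEnvironment(_DiscreteEnvironment):
    """Simple connected undirected graph; two directed actions per edge.

    Edges are stored sorted; the traversal u->v of the i-th edge (u, v)
    with u < v has action index 2i, and v->u has 2i + 1.
    """

    def __init__(self, n_nodes: int, edges: Iterable[tuple[int, int]],
                 costs: Mapping[tuple[int, int], float] | None = None,
                 afford_override: Mapping[tuple[int, int], float] | None = None):
        edges = sorted(tuple(sorted(map(int, e))) for e in edges)
        if len(set(edges)) != len(edges):
            raise ValueError("duplicate edges")
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                raise ValueError(f"edge ({u},{v}) outside node range")
        g = nx.Graph(edges)
        g.add_nodes_from(range(n_nodes))
        if n_nodes > 1 and not nx.is_connected(g):
            raise ValueError("graph is not connected")
        self.n_nodes = n_nodes
        self.edges = edges
        self.costs = dict(costs) if costs else None
        if self.costs is not None:
            for e, c in self.costs.items():
                if c <= 0:
                    raise ValueError(f"non-positive cost on edge {e}")
        n_a = 2 * len(edges)
        transitions = -np.ones((n_nodes, n_a), dtype=np.int64)
        afford = np.zeros((n_nodes, n_a))
        action_costs = np.ones((n_nodes, n_a))
        for i, (u, v) in enumerate(edges):
            cost = self.costs.get((u, v), 1.0) if self.costs else 1.0
            for k, (a, b) in ((2 * i, (u, v)), (2 * i + 1, (v, u))):
                transitions[a, k] = b
                score = 1.0 / cost if self.costs else 1.0
                if afford_override and (a, b) in afford_override:
                    score = afford_override[(a, b)]
                afford[a, k] = score
                action_costs[a, k] = cost
        super().__init__(transitions, afford,
                         action_costs if self.costs else None)
        self._afford_override = dict(afford_override) if afford_override else None

    def action_endpoints(self, action: int) -> tuple[int, int]:
        """Directed traversal (source, target) encoded by an action index."""
        u, v = self.edges[action // 2]
        return (u, v) if action % 2 == 0 else (v, u)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for u, v in self.edges:
            w = self.costs.get((u, v), 1.0) if self.costs else 1.0
            g.add_edge(u, v, weight=w)
        return g


class GridEnvironment(_DiscreteEnvironment):
    """2D maze with state-invariant moves and boundary affordances.

    Rectilinear grids use (row, col) cells and 4 cardinal moves
    (N, E, S, W); hexagonal grids use axial coordinates (q, r) over a
    width x height parallelogram and the 6 axial unit moves.  Cells are
    enumerated row-major.  A move that would leave the grid has affordance
    0 and cannot be stepped.
    """

    _RECT_MOVES = ((-1, 0), (0, 1), (1, 0), (0, -1))  # N, E, S, W as (dr, dc)
    _HEX_MOVES = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))  # (dq, dr)

    def __init__(self, geometry: str, width: int, height: int):
        if geometry not in ("rect", "hex"):
            raise ValueError("geometry must be 'rect' or 'hex'")
        if width < 2 or height < 2:
            raise ValueError("grid must be at least 2x2")
        self.geometry = geometry
        self.width, self.height = width, height
        n_cells = width * height
        moves = self._RECT_MOVES if geometry == "rect" else self._HEX_MOVES
        n_a = len(moves)
        transitions = -np.ones((n_cells, n_a), dtype=np.int64)
        afford = np.zeros((n_cells, n_a))
        for r in range(height):
            for c in range(width):
                u = r * width + c
                for k, move in enumerate(moves):
                    if geometry == "rect":
                        r2, c2 = r + move[0], c + move[1]
                    else:  # axial: c plays q, r plays r
                        c2, r2 = c + move[0], r + move[1]
                    if 0 <= r2 < height and 0 <= c2 < width:
                        transitions[u, k] = r2 * width + c2
                        afford[u, k] = 1.0
        super().__init__(transitions, afford)

    def cell_of(self, node: int) -> tuple[int, int]:
        return divmod(node, self.width)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_o))
        for u in range(self.n_o):
            for _, v in self.neighbors_of(u):
                g.add_edge(u, v, weight=1.0)
        return g


# --------------------------------------------------------------------- #
# replay buffer


@dataclass
class ReplayBuffer:
    """Ordered exploration experience from one or more random walks.

    Stored as parallel index arrays (discrete environments); walk
    boundaries record where each walk starts in the arrays.
    """

    obs: np.ndarray
    act: np.ndarray
    nxt: np.ndarray
    walk_starts: np.ndarray
    seed: int | None = None
    n_o: int | None = None
    n_a: int | None = None

    def __len__(self) -> int:
        return len(self.obs)

    def __iter__(self):
        from .model import Transition
        n_o = self.n_o or int(max(self.obs.max(), self.nxt.max())) + 1
        n_a = self.n_a or int(self.act.max()) + 1
        for i, a, j in self.index_triples():
            o = np.zeros(n_o); o[i] = 1.0
            av = np.zeros(n_a); av[a] = 1.0
            o2 = np.zeros(n_o); o2[j] = 1.0
            yield Transition(o, av, o2)

    def index_triples(self) -> np.ndarray:
        return np.column_stack([self.obs, self.act, self.nxt])

    def check_chain(self) -> bool:
        """Consecutive transitions within a walk must link o_next -> o_t."""
        bounds = set(self.walk_starts.tolist())
        for t in range(1, len(self)):
            if t not in bounds and self.obs[t] != self.nxt[t - 1]:
                return False
        return True


def sample_exploration(env: _DiscreteEnvironment, n_walks: int, walk_len: int,
                       seed: int = 0,
                       holdout_edges: set[tuple[int, int]] | None = None,
                       ) -> ReplayBuffer:
    """Random-walk exploration: uniform choice among afforded actions.

    ``holdout_edges`` (unordered node pairs) are never traversed, which
    lets a grid learner be probed on edges absent from its experience.
    A walk with no admissible action is truncated.  Warns if some
    observation is never visited (the map cannot be learned for it).
    """
    rng = np.random.default_rng(seed)
    holdout = {tuple(sorted(e)) for e in holdout_edges} if holdout_edges else set()
    obs, act, nxt, starts = [], [], [], []
    for _ in range(n_walks):
        u = int(rng.integers(env.n_o))
        starts.append(len(obs))
        for _ in range(walk_len):
            options = [(k, v) for k, v in env.neighbors_of(u)
                       if tuple(sorted((u, v))) not in holdout]
            if not options:
                break
            k, v = options[int(rng.integers(len(options)))]
            obs.append(u); act.append(k); nxt.append(v)
            u = v
    buf = ReplayBuffer(np.array(obs, dtype=np.int64), np.array(act, dtype=np.int64),
                       np.array(nxt, dtype=np.int64), np.array(starts, dtype=np.int64),
                       seed=seed, n_o=env.n_o, n_a=env.n_a)
    visited = set(buf.obs.tolist()) | set(buf.nxt.tolist())
    if len(visited) < env.n_o:
        warnings.warn(
            f"{env.n_o - len(visited)} observation(s) never visited during "
            "exploration; the map cannot be learned for them", stacklevel=2)
    return buf


# --------------------------------------------------------------------- #
# graph generators


def generate_random_graph(n_nodes: int, deg_min: int = 2, deg_max: int = 5,
                          seed: int = 0, max_retries: int = 100,
                          ) -> GraphEnvironment:
    """Connected simple graph with every node degree in [deg_min, deg_max].

    Built from a uniform random spanning tree, then augmented with random
    edges until every node meets the minimum degree, rejecting additions
    that would exceed the maximum.
    """
    if n_nodes < 2:
        raise GenerationError("need at least 2 nodes")
    if deg_min > deg_max or deg_min < 1:
        raise GenerationError("invalid degree bounds")
    if deg_min > n_nodes - 1:
        raise GenerationError(
            f"deg_min={deg_min} impossible on a simple graph of {n_nodes} nodes")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        edges = _random_spanning_tree(n_nodes, rng)
        deg = np.zeros(n_nodes, dtype=int)
        adj = {tuple(sorted(e)) for e in edges}
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        if deg.max() > deg_max:
            continue
        # augment: connect each still-deficient node to a random partner
        # with spare capacity until every node reaches deg_min
        ok = True
        while deg.min() < deg_min:
            u = int(rng.choice(np.flatnonzero(deg < deg_min)))
            candidates = [v for v in range(n_nodes)
                          if v != u and deg[v] < deg_max
                          and tuple(sorted((u, v))) not in adj]
            if not candidates:
                ok = False
                break
            v = int(rng.choice(candidates))
            adj.add(tuple(sorted((u, v))))
            deg[u] += 1
            deg[v] += 1
        if ok:
            return GraphEnvironment(n_nodes, sorted(adj))
    raise GenerationError("could not realize the requested degree range")


def _random_spanning_tree(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    # Aldous-Broder style random tree via random node attachment order
    order = rng.permutation(n)
    edges = []
    for i in range(1, n):
        parent = order[int(rng.integers(i))]
        edges.append((int(order[i]), int(parent)))
    return edges


def generate_small_world(k_clusters: int, cluster_size: int,
                         topology: str = "chain", seed: int = 0,
                         ) -> GraphEnvironment:
    """Dense cliques joined by single bridge edges (chain or ring).

    Each cluster is a complete subgraph; exactly one edge joins
    consecutive clusters, with the gateway nodes drawn at random.
    """
    if k_clusters < 2 or cluster_size < 2:
        raise ValueError("need k_clusters >= 2 and cluster_size >= 2")
    if topology not in ("chain", "ring"):
        raise ValueError("topology must be 'chain' or 'ring'")
    rng = np.random.default_rng(seed)
    edges = []
    for c in range(k_clusters):
        base = c * cluster_size
        for i in range(cluster_size):
            for j in range(i + 1, cluster_size):
                edges.append((base + i, base + j))
    n_bridges = k_clusters if topology == "ring" else k_clusters - 1
    for b in range(n_bridges):
        c1, c2 = b, (b + 1) % k_clusters
        u = c1 * cluster_size + int(rng.integers(cluster_size))
        v = c2 * cluster_size + int(rng.integers(cluster_size))
        edges.append((u, v))
    return GraphEnvironment(k_clusters * cluster_size, edges)


def generate_challenge_graph(kind: str, seed: int = 0, *,
                             backbone_len: int = 6, n_pendants: int = 3,
                             pendant_len: int = 2,
                             ladder_width: int = 2, ladder_len: int = 4,
                             ) -> GraphEnvironment:
    """Structures that stress online planners.

    ``dead_end``: a cycle backbone with pendant chains hanging off random
    backbone nodes — exploration walks in and out of the dead ends.
    ``multi_path``: a width x length grid (ladder), which offers multiple
    vertex-disjoint shortest paths between opposite corners.
    """
    rng = np.random.default_rng(seed)
    if kind == "dead_end":
        if backbone_len < 3 or n_pendants < 1 or pendant_len < 1:
            raise ValueError("degenerate dead-end sizes")
        edges = [(i, (i + 1) % backbone_len) for i in range(backbone_len)]
        n = backbone_len
        anchors = rng.choice(backbone_len, size=n_pendants,
                             replace=n_pendants > backbone_len)
        for a in anchors:
            prev = int(a)
            for _ in range(pendant_len):
                edges.append((prev, n))
                prev = n
                n += 1
        return GraphEnvironment(n, edges)
    if kind == "multi_path":
        if ladder_width < 2 or ladder_len < 2:
            raise ValueError("degenerate ladder sizes")
        def node(r, c):
            return r * ladder_len + c
        edges = []
        for r in range(ladder_width):
            for c in range(ladder_len):
                if c + 1 < ladder_len:
                    edges.append((node(r, c), node(r, c + 1)))
                if r + 1 < ladder_width:
                    edges.append((node(r, c), node(r + 1, c)))
        return GraphEnvironment(ladder_width * ladder_len, edges)
    raise ValueError(f"unknown challenge kind {kind!r}")


def assign_edge_costs(g: GraphEnvironment, cost_values: Sequence[float] = (4, 5, 6, 7),
                      seed: int = 0) -> GraphEnvironment:
    """Weighted copy: each edge cost drawn uniformly from ``cost_values``.

    Both directed traversals share the edge cost, and the affordance of an
    action becomes the reciprocal of its cost.
    """
    if g.costs is not None:
        raise ValueError("graph already weighted")
    if any(c <= 0 for c in cost_values):
        raise ValueError("costs must be positive")
    rng = np.random.default_rng(seed)
    costs = {e: float(cost_values[int(rng.integers(len(cost_values)))])
             for e in g.edges}
    return GraphEnvironment(g.n_nodes, g.edges, costs=costs)


def add_virtual_goal(g: GraphEnvironment, terminal_nodes: Sequence[int],
                     rewards: Sequence[float]) -> GraphEnvironment:
    """Reduce "end in the best-rewarded terminal" to single-goal planning.

    Appends one virtual node with an edge from every terminal; the
    affordance of entering it from terminal i is reward_i / max(rewards),
    biasing the winner-take-all toward the richest exit.
    """
    if len(terminal_nodes) == 0 or len(terminal_nodes) != len(rewards):
        raise ValueError("terminals and rewards must be nonempty, same length")
    for t in terminal_nodes:
        if not 0 <= t < g.n_nodes:
            raise ValueError(f"unknown terminal node {t}")
    if min(rewards) < 0 or max(rewards) <= 0:
        raise ValueError("rewards must be nonnegative with a positive maximum")
    virtual = g.n_nodes
    edges = list(g.edges) + [(t, virtual) for t in terminal_nodes]
    top = max(rewards)
    override = {(int(t), virtual): r / top for t, r in zip(terminal_nodes, rewards)}
    return GraphEnvironment(g.n_nodes + 1, edges, costs=g.costs,
                            afford_override=override)


def generate_grid(geometry: str, width: int, height: int) -> GridEnvironment:
    """Convenience constructor for :class:`GridEnvironment`."""
    return GridEnvironment(geometry, width, height)


# --------------------------------------------------------------------- #
# edge-list text format


def write_edge_list(g: GraphEnvironment, path) -> None:
    """One edge per line: ``u<TAB>v[<TAB>cost]``, 0-based node ids."""
    with open(path, "w") as f:
        for u, v in g.edges:
            if g.costs:
                f.write(f"{u}\t{v}\t{g.costs[(u, v)]:g}\n")
            else:
                f.write(f"{u}\t{v}\n")


def read_edge_list(path) -> GraphEnvironment:
    """Read the plain-text edge-list format; validates simplicity."""
    edges, costs = [], {}
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            u, v = int(parts[0]), int(parts[1])
            e = tuple(sorted((u, v)))
            edges.append(e)
            if len(parts) > 2:
                costs[e] = float(parts[2])
    n_nodes = max(max(e) for e in edges) + 1
    return GraphEnvironment(n_nodes, edges, costs=costs or None)
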