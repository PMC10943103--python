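"""Optimal-path oracles (offline planners) used to score the learner.

Dijkstra's algorithm receives the full graph for free and computes a
provably minimum-cost path, so it lower-bounds anything the online planner
can do; all benchmark ratios are taken against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["OptimalPath", "dijkstra", "average_optimal"]


@dataclass
class OptimalPath:
    """A minimum-cost path: node sequence, edge count, summed cost."""

    nodes: list[int]
    length: int
    cost: float
    reachable: bool = True


def _as_graph(g) -> nx.Graph:
    return g if isinstance(g, nx.Graph) else g.to_networkx()


def dijkstra(g, start: int, goal: int) -> OptimalPath:
    """Minimum-cost path with deterministic lowest-node-id tie-breaking.

    Distances come from Dijkstra run backward from the goal; the path is
    then reconstructed greedily from the start, always taking the
    lowest-id neighbor that stays on a shortest path.
    """
    graph = _as_graph(g)
    if start not in graph or goal not in graph:
        raise ValueError("start or goal not in graph")
    if start == goal:
        return OptimalPath([start], 0, 0.0)
    dist = nx.single_source_dijkstra_path_length(graph, goal, weight="weight")
    if start not in dist:
        return OptimalPath([], 0, np.inf, reachable=False)
    nodes = [start]
    u = start
    while u != goal:
        u = min(v for v in graph.neighbors(u)
                if v in dist and np.isclose(
                    dist[v] + graph[u][v].get("weight", 1.0), dist[u]))
        nodes.append(u)
    cost = sum(graph[a][b].get("weight", 1.0) for a, b in zip(nodes, nodes[1:]))
    return OptimalPath(nodes, len(nodes) - 1, float(cost))


def average_optimal(g, n_pairs: int = 1000, seed: int = 0,
                    weighted: bool = False,
                    pairs=None) -> tuple[float, float]:
    """Mean and std of Dijkstra length (or cost) over random ordered pairs.

    Pairs are sampled uniformly with start != goal; an explicit pair list
    can be supplied instead to evaluate the same tasks as another planner.
    """
    graph = _as_graph(g)
    nodes = sorted(graph.nodes)
    if pairs is None:
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(n_pairs):
            i, j = rng.choice(len(nodes), size=2, replace=False)
            pairs.append((nodes[int(i)], nodes[int(j)]))
    vals = []
    for s, t in pairs:
        p = dijkstra(graph, s, t)
        if not p.reachable:
            raise ValueError(f"goal {t} unreachable from {s}")
        vals.append(p.cost if weighted else p.length)
    vals = np.asarray(vals, dtype=float)
    return float(vals.mean()), float(vals.std())
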