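"""Benchmark evaluation and representational-geometry analyses.

The evaluation harness scores the online planner against the Dijkstra
oracle over a seeded set of random start-goal pairs.  The geometry
analyses probe the structure a converged map should exhibit:

* action-embedding cosines: distinct actions stay near-orthogonal, while
  the two traversals of one edge become anti-aligned;
* cycle sums: action embeddings along any closed walk sum to roughly zero;
* distance scaling: state-space distance between two nodes grows like the
  square root of their graph distance (Pythagoras over near-orthogonal
  unit steps);
* parallelism score: the same action produces parallel state differences
  in different contexts, a signature of compositional structure;
* principal-component projection of the map for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .baselines import dijkstra
from .model import CMLModel
from .planning import plan_online

__all__ = [
    "PlanningStats",
    "evaluate_planner",
    "action_cosine_matrix",
    "cycle_embedding_norm",
    "distance_scaling",
    "parallelism_score",
    "map_projection",
]


@dataclass
class PlanningStats:
    """Aggregate planning performance against the optimal baseline.

    Step and cost statistics are over successful trials only; failures
    (step cap hit, no afforded action) count against ``success_rate``.
    """

    n_trials: int
    success_rate: float
    mean_steps: float
    std_steps: float
    mean_cost: float
    std_cost: float
    oracle_mean: float
    oracle_std: float

    @property
    def ratio(self) -> float:
        return self.mean_cost / self.oracle_mean

    @property
    def ratio_steps(self) -> float:
        return self.mean_steps / self.oracle_mean

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["ratio"] = self.ratio
        return d


def sample_pairs(n_nodes: int, n_pairs: int, seed: int) -> list[tuple[int, int]]:
    """Uniform random ordered (start, goal) pairs with start != goal."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_pairs):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        out.append((int(i), int(j)))
    return out


def evaluate_planner(model: CMLModel, env, n_trials: int = 1000, seed: int = 0,
                     max_steps: int = 64, forbid_repeat_action: bool = False,
                     use_w: bool = False, weighted: bool = False,
                     pairs=None) -> PlanningStats:
    """Score the planner on seeded random start-goal pairs vs. Dijkstra.

    ``weighted`` selects whether the oracle statistic is the summed edge
    cost (weighted graphs) or the edge count.
    """
    if pairs is None:
        pairs = sample_pairs(env.n_o, n_trials, seed)
    steps, costs, oracle = [], [], []
    n_success = 0
    for s, t in pairs:
        res = plan_online(model, env, s, t, max_steps=max_steps,
                          forbid_repeat_action=forbid_repeat_action,
                          use_w=use_w)
        opt = dijkstra(env, s, t)
        if res.reached:
            n_success += 1
            steps.append(res.n_steps)
            costs.append(res.total_cost)
            oracle.append(opt.cost if weighted else opt.length)
    steps = np.asarray(steps, dtype=float)
    costs = np.asarray(costs, dtype=float)
    oracle = np.asarray(oracle, dtype=float)
    return PlanningStats(
        n_trials=len(pairs),
        success_rate=n_success / len(pairs),
        mean_steps=float(steps.mean()) if len(steps) else np.nan,
        std_steps=float(steps.std()) if len(steps) else np.nan,
        mean_cost=float(costs.mean()) if len(costs) else np.nan,
        std_cost=float(costs.std()) if len(costs) else np.nan,
        oracle_mean=float(oracle.mean()) if len(oracle) else np.nan,
        oracle_std=float(oracle.std()) if len(oracle) else np.nan,
    )


def action_cosine_matrix(model: CMLModel) -> np.ndarray:
    """Pairwise cosine similarities of the action embeddings (columns of V)."""
    norms = np.linalg.norm(model.V, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero action embedding column; cosine undefined")
    vn = model.V / norms
    return vn.T @ vn


def cycle_embedding_norm(model: CMLModel, env, start: int,
                         actions: list[int]) -> float:
    """Norm of the summed action embeddings along a closed walk.

    Normalized by the mean action-embedding norm; an empty cycle gives 0.
    On a converged map the embeddings along any cycle cancel, so small
    values indicate the one-step predictions compose consistently.
    """
    node = env.reset(start)
    total = np.zeros(model.n_s)
    for a in actions:
        node = env.step(a)
        total += model.V[:, a]
    if node != start:
        raise ValueError("action sequence is not a closed walk")
    if not actions:
        return 0.0
    return float(np.linalg.norm(total) / np.linalg.norm(model.V, axis=0).mean())


def distance_scaling(model: CMLModel, env, n_pairs: int = 500,
                     seed: int = 0) -> tuple[pd.DataFrame, float]:
    """State-space distance vs. graph distance for sampled node pairs.

    Returns a per-distance table (graph distance, mean and std of
    ``|Q o_i - Q o_j|``) and the Pearson correlation between state-space
    distance and the square root of graph distance.
    """
    pairs = sample_pairs(env.n_o, n_pairs, seed)
    rows = []
    for i, j in pairs:
        d_graph = dijkstra(env, i, j).length
        d_state = float(np.linalg.norm(model.embed_node(i) - model.embed_node(j)))
        rows.append((d_graph, d_state))
    df = pd.DataFrame(rows, columns=["graph_distance", "state_distance"])
    table = (df.groupby("graph_distance")["state_distance"]
             .agg(["mean", "std"]).reset_index())
    r = float(np.corrcoef(np.sqrt(df["graph_distance"]), df["state_distance"])[0, 1])
    return table, r


def parallelism_score(model: CMLModel, pair_a: tuple[int, int],
                      pair_b: tuple[int, int]) -> float:
    """Cosine between the state differences of two observation pairs.

    Each pair (before, after) should relate two observations linked by the
    same action in different contexts; a score near 1 means the map
    represents that action as the same displacement everywhere.
    """
    da = model.embed_node(pair_a[1]) - model.embed_node(pair_a[0])
    db = model.embed_node(pair_b[1]) - model.embed_node(pair_b[0])
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise ValueError("zero state difference; parallelism undefined")
    return float(da @ db / (na * nb))


def map_projection(model: CMLModel, k: int = 2,
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Principal-component projection of the learned map.

    Returns (observation coordinates (n_o, k), action coordinates
    (n_a, k), fraction of variance explained by the top k components).
    Action embeddings are projected onto the same components as
    displacement vectors (no centering offset).
    """
    if k > model.n_s:
        raise ValueError("cannot request more components than state dimensions")
    pca = PCA(n_components=k)
    obs_coords = pca.fit_transform(model.Q.T)
    act_coords = model.V.T @ pca.components_.T
    return obs_coords, act_coords, float(pca.explained_variance_ratio_.sum())
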