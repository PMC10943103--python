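"""End-to-end experiment presets and the pipeline runner.

Each preset bundles the study conditions of one benchmark — environment
generator, exploration protocol, model hyperparameters, training schedule
and evaluation spec — into a serializable :class:`ExperimentConfig`.  The
runner executes generate -> explore -> train -> evaluate and optionally
writes artifacts (learning curve CSV, stats CSV, model checkpoint,
machine-readable summary).

Default hyperparameters by environment class: abstract graphs use
``n_s=1000`` with ``eta_q=0.1, eta_v=eta_w=0.01``; 2D grids use ``n_s=80``
with all rates 0.5; the continuous point mass uses its own module
(:mod:`cogmap.control`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import environments as envs
from .diagnostics import PlanningStats, evaluate_planner
from .model import CMLModel, save_checkpoint

__all__ = ["ExperimentConfig", "run_experiment", "make_environment",
           "choose_grid_holdout", "PRESETS", "preset_config"]


def subseed(seed: int, k: int) -> int:
    """Derive the k-th stream seed from a master seed (stays below 2^31)."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one benchmark run bit-for-bit."""

    name: str
    env_kind: str                      # random_graph | small_world | dead_end | multi_path | grid
    env_params: dict = field(default_factory=dict)
    cost_values: tuple | None = None   # edge costs drawn uniformly, e.g. (4, 5, 6, 7)
    n_s: int = 1000
    eta_q: float = 0.1
    eta_v: float = 0.01
    eta_w: float = 0.01
    normalize_v: bool = False
    n_walks: int = 200
    walk_len: int = 32
    n_holdout: int = 0                 # grid generalization: edges hidden from exploration
    rounds: int = 10
    shuffle_replay: bool = False
    convergence_tol: float | None = None  # resample exploration until the
    # final mean squared prediction error falls below this (learnability
    # screen for minimal walk sets; see docs/methods.md)
    n_trials: int = 1000
    max_steps: int | None = None       # None -> 4 x graph diameter
    forbid_repeat_action: bool = False
    use_w: bool = False
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("cost_values") is not None:
            data["cost_values"] = tuple(data["cost_values"])
        return cls(**data)


def make_environment(cfg: ExperimentConfig):
    """Instantiate the environment a config describes (seeded)."""
    p = dict(cfg.env_params)
    env_seed = subseed(cfg.seed, 0)
    if cfg.env_kind == "random_graph":
        env = envs.generate_random_graph(seed=env_seed, **p)
    elif cfg.env_kind == "small_world":
        env = envs.generate_small_world(seed=env_seed, **p)
    elif cfg.env_kind in ("dead_end", "multi_path"):
        env = envs.generate_challenge_graph(cfg.env_kind, seed=env_seed, **p)
    elif cfg.env_kind == "grid":
        env = envs.generate_grid(**p)
    else:
        raise ValueError(f"unknown env_kind {cfg.env_kind!r}")
    if cfg.cost_values is not None:
        env = envs.assign_edge_costs(env, cfg.cost_values, seed=subseed(cfg.seed, 1))
    return env


def choose_grid_holdout(env, n_holdout: int, n_walks: int, walk_len: int,
                        seed: int, max_attempts: int = 500):
    """Seeded held-out edge set plus an exploration buffer that avoids it.

    Draws holdout sets and walk seeds until the remaining edge set stays
    connected, the walks try every action at least once, and the explored
    transition graph is itself connected — otherwise the relative position
    of an unexplored region of the map is unconstrained and cannot be
    learned.  Returns ``(holdout_edges, buffer)``.
    """
    import networkx as nx
    rng = np.random.default_rng(seed)
    all_edges = sorted({tuple(sorted((u, v)))
                        for u in range(env.n_o) for _, v in env.neighbors_of(u)})
    for attempt in range(max_attempts):
        idx = rng.choice(len(all_edges), size=n_holdout, replace=False)
        holdout = {all_edges[int(i)] for i in idx}
        g = env.to_networkx()
        g.remove_edges_from(holdout)
        if not nx.is_connected(g):
            continue
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            buf = envs.sample_exploration(env, n_walks, walk_len,
                                          seed=subseed(seed, attempt + 1),
                                          holdout_edges=holdout)
        if len(buf) == 0:
            continue
        explored = nx.Graph(zip(buf.obs.tolist(), buf.nxt.tolist()))
        if (explored.number_of_nodes() == env.n_o
                and nx.is_connected(explored)
                and len(set(buf.act.tolist())) == env.n_a):
            return holdout, buf
    raise envs.GenerationError("no learnable holdout configuration found")


def _default_max_steps(env) -> int:
    import networkx as nx
    return 4 * nx.diameter(env.to_networkx())


def run_experiment(cfg: ExperimentConfig, out_dir=None):
    """generate env -> sample exploration -> train -> evaluate.

    Returns a dict with the environment, trained model, learning curve,
    planning stats and (for grids) the held-out edges.  If ``out_dir`` is
    given, writes ``learning_curve.csv``, ``stats.csv``, ``model.npz``,
    ``config.yaml`` and ``summary.json`` there.
    """
    env = make_environment(cfg)
    holdout = None
    # Minimal exploration sets are not all learnable: a small fraction of
    # walk draws makes the replay dynamics stall short of convergence.
    # Resample (deterministically) until training converges.
    for attempt in range(25):
        explore_seed = subseed(cfg.seed, 2 + 31 * attempt)
        if cfg.n_holdout > 0:
            holdout, buf = choose_grid_holdout(env, cfg.n_holdout, cfg.n_walks,
                                               cfg.walk_len, seed=explore_seed)
        else:
            buf = envs.sample_exploration(env, cfg.n_walks, cfg.walk_len,
                                          seed=explore_seed)
        model = CMLModel(n_o=env.n_o, n_a=env.n_a, n_s=cfg.n_s,
                         eta_q=cfg.eta_q, eta_v=cfg.eta_v, eta_w=cfg.eta_w,
                         normalize_v=cfg.normalize_v,
                         rng_seed=subseed(cfg.seed, 3))
        curve = train(model, buf, cfg.rounds,
                      shuffle_seed=subseed(cfg.seed, 4) if cfg.shuffle_replay
                      else None)
        if cfg.convergence_tol is None or curve[-1] < cfg.convergence_tol:
            break
    else:
        raise envs.GenerationError(
            "no learnable exploration found within the attempt budget")
    max_steps = cfg.max_steps if cfg.max_steps is not None else _default_max_steps(env)
    stats = evaluate_planner(model, env, n_trials=cfg.n_trials,
                             seed=subseed(cfg.seed, 5), max_steps=max_steps,
                             forbid_repeat_action=cfg.forbid_repeat_action,
                             use_w=cfg.use_w, weighted=cfg.cost_values is not None)
    result = {"config": cfg, "env": env, "model": model, "buffer": buf,
              "learning_curve": curve, "stats": stats, "holdout": holdout}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"sweep": np.arange(1, len(curve) + 1),
                      "mean_sq_prediction_error": curve}
                     ).to_csv(out / "learning_curve.csv", index=False)
        pd.DataFrame([stats.as_dict()]).to_csv(out / "stats.csv", index=False)
        save_checkpoint(model, out / "model.npz")
        cfg.to_yaml(out / "config.yaml")
        (out / "summary.json").write_text(json.dumps(stats.as_dict(), indent=2))
    return result


def train(model: CMLModel, buf, rounds: int, shuffle_seed: int | None = None
          ) -> np.ndarray:
    """Replay training; optionally reshuffles the transition order each sweep."""
    if shuffle_seed is None:
        return model.train_on_replay(buf, rounds=rounds)
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if len(buf) == 0:
        raise ValueError("replay buffer is empty")
    rng = np.random.default_rng(shuffle_seed)
    triples = buf.index_triples()
    curve = np.empty(rounds)
    for r in range(rounds):
        total = 0.0
        for k in rng.permutation(len(triples)):
            i, a, j = triples[k]
            total += model._update_indices(i, a, j)
        curve[r] = total / len(triples)
    return curve


# --------------------------------------------------------------------- #
# presets: the study conditions of each benchmark


def _random32(seed):
    return ExperimentConfig(
        name="random32", env_kind="random_graph",
        env_params={"n_nodes": 32, "deg_min": 2, "deg_max": 5},
        max_steps=64, seed=seed)


def _weighted32(seed):
    cfg = _random32(seed)
    return dataclasses.replace(cfg, name="weighted32", cost_values=(4, 5, 6, 7),
                               forbid_repeat_action=True)


def _small_world(seed):
    return ExperimentConfig(
        name="small_world", env_kind="small_world",
        env_params={"k_clusters": 4, "cluster_size": 6, "topology": "chain"},
        max_steps=64, seed=seed)


def _dead_end(seed):
    return ExperimentConfig(
        name="dead_end", env_kind="dead_end",
        env_params={"backbone_len": 8, "n_pendants": 4, "pendant_len": 2},
        max_steps=64, seed=seed)


def _multi_path(seed):
    return ExperimentConfig(
        name="multi_path", env_kind="multi_path",
        env_params={"ladder_width": 3, "ladder_len": 4},
        max_steps=64, seed=seed)


def _grid4x4(seed):
    return ExperimentConfig(
        name="grid4x4", env_kind="grid",
        env_params={"geometry": "rect", "width": 4, "height": 4},
        n_s=80, eta_q=0.5, eta_v=0.5, eta_w=0.5, normalize_v=True,
        n_walks=22, walk_len=3, n_holdout=4,
        rounds=300, convergence_tol=1e-2,
        n_trials=240, max_steps=32, seed=seed)


PRESETS = {
    "random32": _random32,
    "weighted32": _weighted32,
    "small_world": _small_world,
    "dead_end": _dead_end,
    "multi_path": _multi_path,
    "grid4x4": _grid4x4,
}


def preset_config(name: str, seed: int) -> ExperimentConfig:
    """Config of a named benchmark preset for a given master seed."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](seed)
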