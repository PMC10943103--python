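"""Learn a cognitive map of a 32-node random graph and plan with it.

Builds the standard benchmark: a random graph whose node degrees lie in
[2, 5], explored by 200 random walks of length 32, replayed for 10 rounds
with a 1000-dimensional state space.  The trained online planner is then
scored on 1000 random start-goal pairs against Dijkstra, which sees the
whole graph for free.
"""

import numpy as np

from cogmap import (CMLModel, evaluate_planner, generate_random_graph,
                    plan_online, sample_exploration)

env = generate_random_graph(32, deg_min=2, deg_max=5, seed=1)
print(f"graph: {env.n_o} nodes, {len(env.edges)} edges, {env.n_a} actions")

buffer = sample_exploration(env, n_walks=200, walk_len=32, seed=2)
model = CMLModel(n_o=env.n_o, n_a=env.n_a, n_s=1000, rng_seed=3)
curve = model.train_on_replay(buffer, rounds=10)
print(f"prediction error per sweep: first {curve[0]:.2f} -> last {curve[-1]:.5f}")

stats = evaluate_planner(model, env, n_trials=1000, seed=4, max_steps=64)
print(f"planner: mean {stats.mean_steps:.3f} steps (std {stats.std_steps:.3f}), "
      f"success rate {stats.success_rate:.3f}")
print(f"Dijkstra: mean {stats.oracle_mean:.3f} steps (std {stats.oracle_std:.3f})")
print(f"ratio online/offline = {stats.ratio:.3f} "
      "(1.0 would match the optimal offline planner)")

# one concrete episode
res = plan_online(model, env, 0, env.n_o - 1, max_steps=64)
print(f"\nexample episode 0 -> {env.n_o - 1}: "
      f"{' -> '.join(map(str, res.observations))} ({res.n_steps} steps)")
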