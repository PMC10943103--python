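"""2D-maze navigation with generalization to never-explored edges.

A 4x4 grid with four state-invariant actions (N, E, S, W).  Exploration
is deliberately minimal — 22 walks of length 3 — and a seeded set of four
edges is held out entirely.  Because the same action code means the same
move everywhere, the learner infers the displacement of held-out edges
from the lattice structure and plans optimally across them.
"""

import numpy as np

from cogmap import dijkstra, map_projection, parallelism_score, plan_online
from cogmap.experiments import preset_config, run_experiment

result = run_experiment(preset_config("grid4x4", seed=0))
env, model, holdout = result["env"], result["model"], result["holdout"]
print(f"held-out edges (never explored): {sorted(holdout)}")
print(f"final prediction error: {result['learning_curve'][-1]:.6f}")

n_optimal, n_total, holdout_plans = 0, 0, 0
for s in range(env.n_o):
    for t in range(env.n_o):
        if s == t:
            continue
        r = plan_online(model, env, s, t, max_steps=32)
        n_total += 1
        if r.reached and r.n_steps == dijkstra(env, s, t).length:
            n_optimal += 1
            if any(tuple(sorted(e)) in holdout
                   for e in zip(r.observations, r.observations[1:])):
                holdout_plans += 1
print(f"optimal plans: {n_optimal}/{n_total}; "
      f"{holdout_plans} of them traverse a held-out edge")

_, _, var2 = map_projection(model, 2)
score = parallelism_score(model, (0, 1), (10, 11))  # 'east' in two contexts
print(f"top-2 principal components carry {100 * var2:.1f}% of map variance "
      "(the map became an almost perfect plane)")
print(f"parallelism score of the same action in two contexts: {score:.3f}")
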