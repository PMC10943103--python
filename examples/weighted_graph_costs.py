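"""Least-cost planning: edge costs enter through the affordance channel.

Each edge of the benchmark graph gets an integer cost from {4, 5, 6, 7};
the affordance of an action becomes 1/cost, so the winner-take-all favors
cheap edges at comparable utility.  Re-selecting the same action within a
trial is disallowed to avoid loops.  Also shows the virtual-goal
reduction: "end in the best-rewarded terminal" becomes ordinary
single-goal planning.
"""

from cogmap import (CMLModel, GraphEnvironment, add_virtual_goal,
                    assign_edge_costs, dijkstra, evaluate_planner,
                    generate_random_graph, plan_online, sample_exploration)

env = generate_random_graph(32, 2, 5, seed=1)
weighted = assign_edge_costs(env, (4, 5, 6, 7), seed=9)

buffer = sample_exploration(weighted, 200, 32, seed=2)
model = CMLModel(n_o=env.n_o, n_a=env.n_a, n_s=1000, rng_seed=3)
model.train_on_replay(buffer, rounds=10)

stats = evaluate_planner(model, weighted, n_trials=1000, seed=4, max_steps=64,
                         forbid_repeat_action=True, weighted=True)
print(f"planned mean cost {stats.mean_cost:.2f} vs Dijkstra optimum "
      f"{stats.oracle_mean:.2f} (ratio {stats.ratio:.3f}, "
      f"success {stats.success_rate:.3f})")

# reward seeking via a virtual goal: 2-step decision tree, 4 leaves
tree = GraphEnvironment(7, [(0, 1), (0, 2), (1, 3), (1, 4), (2, 5), (2, 6)])
rewards = [1.0, 1.0, 8.0, 1.0]          # leaf 5 is the jackpot
aug = add_virtual_goal(tree, [3, 4, 5, 6], rewards)
buf = sample_exploration(aug, 60, 8, seed=5)
m2 = CMLModel(n_o=aug.n_o, n_a=aug.n_a, n_s=200, rng_seed=6)
m2.train_on_replay(buf, rounds=20)
# entry affordances into the virtual node are proportional to the leaf
# rewards, so low-reward exits are suppressed; the per-episode repeat ban
# keeps the planner moving until it finds the favored exit
res = plan_online(m2, aug, 0, aug.n_o - 1, max_steps=12,
                  forbid_repeat_action=True)
exit_leaf = res.observations[-2]
print(f"decision tree: path {res.observations} "
      f"(exited through leaf {exit_leaf}, reward "
      f"{rewards[[3, 4, 5, 6].index(exit_leaf)]})")
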