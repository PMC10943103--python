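"""Goal reaching that was never trained: motor babbling on a point mass.

A damped point mass is driven by 8 compass-direction forces.  Training is
pure motor babbling — random actions, learning only next-observation
prediction.  Afterwards the planner is given a target observation that
differs from the current one only in position, and goal-directed movement
emerges from the learned map.
"""

from cogmap.control import pointmass_goal_reaching

for seed in range(3):
    initial, final, res = pointmass_goal_reaching(seed=seed, goal_xy=(5.0, 0.0))
    print(f"seed {seed}: distance to goal {initial:.2f} -> {final:.3f} "
          f"after {res.n_steps} actions "
          f"({100 * final / initial:.1f}% of initial; below 10% counts as reached)")
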