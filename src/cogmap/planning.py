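"""Online planning with a learned cognitive map.

At every step the planner forms the goal direction
``d_t = Q o* - Q o_t``, scores all actions by the scalar product of their
embeddings with that direction, gates the scores by the environment's
affordances, and executes the winner.  This produces the next action in
constant time — no path is ever computed ahead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CMLModel, NoAffordedActionError, Transition, select_action

__all__ = ["PlanResult", "plan_online"]


@dataclass
class PlanResult:
    """Trace of one planning episode."""

    start_obs: int
    goal_obs: int
    actions: list[int]
    observations: list[int]
    reached: bool
    total_cost: float
    # per-step diagnostics
    chosen_utilities: list[float] = field(default_factory=list)
    n_afforded: list[int] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.actions)

    def trace_frame(self) -> pd.DataFrame:
        """Plan trace as a table (one row per executed step)."""
        return pd.DataFrame({
            "step": np.arange(self.n_steps),
            "node_from": self.observations[:-1],
            "action_index": self.actions,
            "node_to": self.observations[1:],
            "utility_of_chosen": self.chosen_utilities,
            "n_afforded": self.n_afforded,
        })


def plan_online(model: CMLModel, env, start_obs: int, goal_obs: int,
                max_steps: int = 64, learn_during_planning: bool = False,
                forbid_repeat_action: bool = False,
                use_w: bool = False) -> PlanResult:
    """Run one goal-directed episode; returns the action/observation trace.

    ``forbid_repeat_action`` bans re-selecting an action already used in
    this episode (useful on weighted graphs, where greedy cost gating can
    otherwise loop).  ``learn_during_planning`` keeps the delta rules
    active on every experienced transition.  Episodes that exhaust
    ``max_steps`` or run out of afforded actions report ``reached=False``.
    """
    obs = env.reset(start_obs)
    goal_vec = env.observation_vector(goal_obs)
    used = np.zeros(env.n_a, dtype=bool)
    result = PlanResult(start_obs, goal_obs, [], [obs], False, 0.0)
    if env.is_goal(obs, goal_obs):
        result.reached = True
        return result
    for _ in range(max_steps):
        o_vec = env.observation_vector(obs)
        d_t = model.embed_observation(goal_vec) - model.embed_observation(o_vec)
        u_t = model.compute_utilities(d_t, use_w=use_w)
        g_t = env.affordances()
        if forbid_repeat_action:
            g_t = g_t.copy()
            g_t[used] = 0.0
        try:
            a_code = select_action(u_t, g_t)
        except NoAffordedActionError:
            break
        a = int(np.argmax(a_code))
        cost = env.action_cost(obs, a)
        nxt = env.step(a)
        if learn_during_planning:
            model.apply_plasticity(
                Transition(o_vec, a_code, env.observation_vector(nxt)))
        used[a] = True
        result.actions.append(a)
        result.observations.append(nxt)
        result.chosen_utilities.append(float(u_t[a]))
        result.n_afforded.append(int(np.count_nonzero(g_t > 0)))
        result.total_cost += cost
        obs = nxt
        if env.is_goal(obs, goal_obs):
            result.reached = True
            break
    return result
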