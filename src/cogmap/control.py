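"""Continuous-observation extension: motor control from motor babbling.

For body control the observation is a real-valued feature vector (for a
quadruped: torso pose, joint angles and velocities; here demonstrated on a
built-in damped point mass).  The same predictive-coding rules apply; the
pieces specific to control are:

* action remapping: the one-hot action index selects one of ``2**n_joints``
  sign patterns of per-joint torques;
* target construction: a goal observation copies the current observation
  and overwrites only the fields one cares about (e.g. torso x, y), so
  planning only tries to change those;
* joint-limit affordances: composite actions that push a joint toward a
  nearby limit are scored down;
* decoder regularization: Q^T is nudged to reconstruct the observation so
  that planning-relevant fields cannot collapse out of the state code.

Training is pure motor babbling — random actions — after which goal
reaching emerges from the learned map without any goal-directed training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CMLModel, Transition, select_action

__all__ = [
    "ANT_OBSERVATION_FIELDS",
    "remap_action",
    "make_target_observation",
    "relative_target_transform",
    "reconstruction_regularize",
    "joint_limit_affordance",
    "babbling_affordance_sampler",
    "PointMassEnv",
    "train_pointmass_by_babbling",
    "pointmass_goal_reaching",
]

#: Named schema of the 29-component quadruped ("ant") observation: torso
#: position, quaternion orientation, 8 joint angles, then velocities.
ANT_OBSERVATION_FIELDS = (
    "torso_x", "torso_y", "torso_z",
    "quat_x", "quat_y", "quat_z", "quat_w",
    "hip_fl", "knee_fl", "hip_fr", "knee_fr",
    "hip_bl", "knee_bl", "hip_br", "knee_br",
    "vel_x", "vel_y", "vel_z",
    "angvel_x", "angvel_y", "angvel_z",
    "angvel_hip_fl", "angvel_knee_fl", "angvel_hip_fr", "angvel_knee_fr",
    "angvel_hip_bl", "angvel_knee_bl", "angvel_hip_br", "angvel_knee_br",
)


def remap_action(one_hot_index: int, n_joints: int, tau: float = 0.1) -> np.ndarray:
    """Torque pattern encoded by an action index.

    The index's binary expansion selects each joint's torque sign: bit j
    set means +tau on joint j, clear means -tau.  With 8 joints this
    yields the full set of 2**8 = 256 composite actions.
    """
    if not 0 <= one_hot_index < 2 ** n_joints:
        raise ValueError(f"index {one_hot_index} out of range for {n_joints} joints")
    bits = (one_hot_index >> np.arange(n_joints)) & 1
    return np.where(bits == 1, tau, -tau).astype(float)


def action_sign_table(n_joints: int) -> np.ndarray:
    """(2**n_joints, n_joints) matrix of torque signs, one row per action."""
    idx = np.arange(2 ** n_joints)
    return np.where(((idx[:, None] >> np.arange(n_joints)) & 1) == 1, 1.0, -1.0)


def make_target_observation(current: np.ndarray,
                            target_fields: dict,
                            schema: tuple[str, ...] | None = None) -> np.ndarray:
    """Goal observation: copy of ``current`` with selected fields replaced.

    ``target_fields`` maps field names (with ``schema``) or integer
    indices to desired values; all remaining fields keep their current
    values, so the planner is only asked to change what is specified.
    """
    out = np.asarray(current, dtype=float).copy()
    for key, value in target_fields.items():
        if isinstance(key, str):
            if schema is None or key not in schema:
                raise KeyError(f"unknown field name {key!r}")
            key = schema.index(key)
        if not 0 <= key < out.shape[0]:
            raise KeyError(f"field index {key} out of range")
        out[key] = float(value)
    return out


def relative_target_transform(agent_position: np.ndarray, agent_heading: float,
                              absolute_target: np.ndarray) -> np.ndarray:
    """Express a world-frame target in the agent's heading frame.

    The vector to the target is written in polar form, the agent's own
    heading angle is subtracted, and the rotated vector is re-attached to
    the agent position.  With heading 0 this is the identity.
    """
    agent_position = np.asarray(agent_position, dtype=float)
    v = np.asarray(absolute_target, dtype=float) - agent_position
    r = np.hypot(v[0], v[1])
    phi = np.arctan2(v[1], v[0]) - agent_heading
    return agent_position + r * np.array([np.cos(phi), np.sin(phi)])


def reconstruction_regularize(model: CMLModel, o: np.ndarray,
                              eta_r: float = 1e-4) -> float:
    """Delta-rule step pushing ``Q^T (Q o)`` toward ``o``.

    Treats Q^T as a decoder of the state code; the update keeps every
    observation field represented in state space, so planning-relevant
    fields (like position) cannot be traded away for easier-to-predict
    ones.  Returns the squared reconstruction error before the update.
    """
    o = np.asarray(o, dtype=float)
    s = model.Q @ o
    err = o - model.Q.T @ s
    model.Q += eta_r * np.outer(s, err)
    return float(err @ err)


def joint_limit_affordance(angles: np.ndarray, limits_low: np.ndarray,
                           limits_high: np.ndarray, sign_table: np.ndarray,
                           ramp: float = 0.1) -> np.ndarray:
    """Affordances of composite actions from per-joint distance to limits.

    For each joint, the direction approaching a limit is scored by the
    normalized distance to that limit through a linear ramp (score 1
    beyond ``ramp`` of the range, falling to 0 at the limit); the
    direction moving away always scores 1.  A composite action's
    affordance is the mean of its joints' directional scores.
    """
    angles = np.asarray(angles, dtype=float)
    lo = np.asarray(limits_low, dtype=float)
    hi = np.asarray(limits_high, dtype=float)
    span = hi - lo
    if np.any(span <= 0):
        raise ValueError("limits_low must be strictly below limits_high")
    clipped = np.clip(angles, lo, hi)
    if np.any(clipped != angles):
        import warnings
        warnings.warn("joint angle outside limits; clamped", stacklevel=2)
    up_room = (hi - clipped) / span      # normalized distance to upper limit
    down_room = (clipped - lo) / span
    up_score = np.clip(up_room / ramp, 0.0, 1.0)
    down_score = np.clip(down_room / ramp, 0.0, 1.0)
    per_joint = np.where(sign_table > 0, up_score[None, :], down_score[None, :])
    return per_joint.mean(axis=1)


def babbling_affordance_sampler(affordances: np.ndarray,
                                rng: np.random.Generator) -> int:
    """Sample an exploration action proportionally to its affordance.

    Biases motor babbling away from actions that would drive joints into
    their limits.
    """
    g = np.asarray(affordances, dtype=float)
    total = g.sum()
    if total <= 0:
        raise ValueError("no action with positive affordance")
    return int(rng.choice(len(g), p=g / total))


# --------------------------------------------------------------------- #
# point-mass surrogate environment


@dataclass
class PointMassEnv:
    """Damped point mass on a plane driven by 8 compass-direction forces.

    Observation: ``(x, y, vx, vy)``.  Each of the 8 actions applies a
    constant force of magnitude ``force`` in one compass direction for
    ``repeats`` Euler steps of length ``dt``.  A desk-scale stand-in for a
    physics simulator: deterministic, with the same environment protocol
    (reset / step / affordances) the planner uses for mazes and graphs.
    """

    mass: float = 1.0
    damping: float = 3.0
    dt: float = 0.1
    force: float = 1.0
    repeats: int = 5
    goal_radius: float = 0.25
    n_o: int = 4
    n_a: int = 8
    state: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self) -> None:
        angles = np.arange(8) * (2 * np.pi / 8)
        self._forces = self.force * np.column_stack([np.cos(angles), np.sin(angles)])

    def reset(self, obs: np.ndarray | None = None) -> np.ndarray:
        self.state = (np.zeros(4) if obs is None
                      else np.asarray(obs, dtype=float).copy())
        return self.state.copy()

    def step(self, action: int) -> np.ndarray:
        f = self._forces[action]
        x, y, vx, vy = self.state
        for _ in range(self.repeats):
            ax = (f[0] - self.damping * vx) / self.mass
            ay = (f[1] - self.damping * vy) / self.mass
            vx += self.dt * ax
            vy += self.dt * ay
            x += self.dt * vx
            y += self.dt * vy
        self.state = np.array([x, y, vx, vy])
        return self.state.copy()

    def affordances(self) -> np.ndarray:
        return np.ones(self.n_a)

    def observation_vector(self, obs: np.ndarray) -> np.ndarray:
        return np.asarray(obs, dtype=float)

    def is_goal(self, obs: np.ndarray, goal: np.ndarray) -> bool:
        return float(np.hypot(*(np.asarray(obs)[:2] - np.asarray(goal)[:2]))) \
            < self.goal_radius

    def action_cost(self, obs, action: int) -> float:
        return 1.0


def train_pointmass_by_babbling(env: PointMassEnv, model: CMLModel,
                                n_walks: int = 150, walk_len: int = 30,
                                seed: int = 0, eta_r: float = 1e-4,
                                ) -> np.ndarray:
    """Motor babbling: random actions, learning only from prediction error.

    Returns the per-transition squared prediction error (learning curve).
    The decoder regularization runs on every visited observation.
    """
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_walks):
        o = env.reset(np.zeros(4))
        for _ in range(walk_len):
            a = int(rng.integers(env.n_a))
            a_code = np.zeros(env.n_a)
            a_code[a] = 1.0
            o_next = env.step(a)
            errors.append(model.apply_plasticity(Transition(o, a_code, o_next)))
            reconstruction_regularize(model, o_next, eta_r=eta_r)
            o = o_next
    return np.asarray(errors)


def pointmass_goal_reaching(seed: int = 0, goal_xy: tuple[float, float] = (5.0, 0.0),
                            n_s: int = 256, eta_q: float = 0.005,
                            eta_v: float = 0.001, max_steps: int = 200,
                            ) -> tuple[float, float, "PlanResultLike"]:
    """Babbling-only training, then one goal-reaching episode from rest.

    Returns ``(initial_distance, final_distance, plan_result)``.  Goal
    reaching is never trained — it emerges as generalization from the
    self-supervised map.
    """
    from .planning import plan_online

    env = PointMassEnv()
    model = CMLModel.init_continuous(env.n_o, env.n_a, n_s,
                                     eta_q=eta_q, eta_v=eta_v, rng_seed=seed)
    train_pointmass_by_babbling(env, model, seed=seed + 1)
    start = env.reset(np.zeros(4))
    goal = make_target_observation(start, {0: goal_xy[0], 1: goal_xy[1]})
    result = plan_online(model, env, start, goal, max_steps=max_steps)
    initial = float(np.hypot(goal_xy[0], goal_xy[1]))
    final = float(np.hypot(*(env.state[:2] - goal[:2])))
    return initial, final, result
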