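# Methods

## The model

A cognitive map learner maintains three weight matrices: an observation
embedding `Q` (n_s × n_o), an action embedding `V` (n_s × n_a), and a
readout `W` (n_a × n_s).  Observations `o_t` and actions `a_t` — one-hot
vectors in discrete problem spaces, real feature vectors in continuous
ones — are mapped into a common state space of dimension n_s:

    s_t       = Q o_t
    s_hat_t+1 = s_t + V a_t                (one-step prediction)

Learning is purely self-supervised next-observation prediction through
error-gated delta rules, applied per experienced transition
(o_t, a_t, o_t+1):

    err = s_t+1 − s_hat_t+1
    ΔV  = η_v · err · a_tᵀ
    ΔQ  = −η_q · err · o_t+1ᵀ
    ΔW  = η_w · (a_t − W Δs) Δsᵀ / ‖Δs‖²,   Δs = s_t+1 − s_t

The prediction error is computed from the pre-update matrices and gates
all three updates.  When the prediction is consistent (`Q o_t+1 ≈ Q o_t +
V a_t` for every experienced transition), the map's geometry supports
planning: the usefulness of action `a` for reaching goal `o*` from `o_t`
is the scalar product of its embedding with the goal direction,

    u_t(a) = (Q o* − Q o_t)ᵀ (V a),

computed for all actions at once as `u_t = Vᵀ d_t` (or `u_t = W d_t` with
the learned readout).  Planning is online: at each step the utilities are
gated elementwise by the environment's affordances `g_t` (0 for an
unavailable action, 1 for a free one, 1/cost on weighted graphs) and the
highest-eligibility action is executed (winner-take-all, ties to the
lowest index).  No path is ever computed ahead; a goal change costs
nothing.

### The W readout

`W` replaces the transpose `Vᵀ` where weight transport is implausible or
inconvenient.  We train it to recover the executed action from the
observed state difference.  Two facts about this readout, established
empirically in the test suite:

* The raw delta rule `ΔW = η_w (a_t − W Δs) Δsᵀ` has effective gain
  `η_w‖Δs‖²`, which at the discrete-mode initialization (Q entries unit
  variance, n_s = 1000) is ≈ 20 — far beyond the stability bound of 2 —
  and diverges.  The default therefore normalizes the update by `‖Δs‖²`
  (normalized least-mean-squares); the raw rule remains available
  (`w_update="raw"`).
* A linear `W` cannot satisfy both directions of an edge: the forward and
  backward traversals impose `W(Δs) = a_fwd` and `W(−Δs) = a_bwd`, which
  a linear map can only satisfy as `W Δs = (a_fwd − a_bwd)/2`.  The
  converged readout consequently identifies the executed action perfectly
  from one-step state differences (top-1 accuracy ≈ 1.0 in our tests),
  but its utility rankings on *multi-step* goal directions agree with the
  `Vᵀ` route on only ~80 % of planning steps.  Planning quality with the
  `W` route is measurably worse, so evaluation defaults to `use_w=False`.

## Hyperparameters

| setting | abstract graphs | 2D grids | point mass |
|---|---|---|---|
| n_s | 1000 | 80 | 256 |
| η_q | 0.1 | 0.5 | 0.005 |
| η_v = η_w | 0.01 | 0.5 | 0.001 |
| init σ(Q), σ(V, W) | 1, 0.1 | 1, 0.1 | 0.1, 1 (V) |
| V column normalization | off | on | off |
| replay sweeps | 10 | 300 | single pass |

Abstract-graph settings follow the benchmark protocol (200 random walks
of length 32, replayed 10 times).  The large state dimension matters:
random Gaussian columns of `V` are then nearly orthogonal (off-diagonal
cosines < 0.15) and nearly equal in norm, which is what makes utilities
comparable across actions.

At the grid's small state dimension (n_s = 80) the implicit
normalization of `V` columns no longer holds, so explicit renormalization
to unit length after each update is enabled there.  Grid training uses
300 replay sweeps of its small buffer (66 transitions): with learning
rates of 0.5 the prediction error reaches its floor well within that
budget, and the extra sweeps cost milliseconds.

## Environments

* **Random graphs**: a uniform random spanning tree is augmented with
  random edges until every node's degree reaches the minimum, rejecting
  any addition that would exceed the maximum.  With degrees in [2, 5] and
  32 nodes this yields sparse graphs (mean degree ≈ 2.8) whose mean
  shortest path over random pairs is ≈ 3.4 edges.  Every undirected edge
  contributes two actions, one per traversal direction.
* **Weighted graphs**: integer edge costs drawn uniformly from
  {4, 5, 6, 7}; the affordance of an action is the reciprocal of its edge
  cost, so the winner-take-all prefers cheap edges at equal utility.
  Because a greedy planner can loop under cost gating, re-selecting the
  same action within one episode is disallowed there.
* **Small-world / dead-end / multi-path challenge graphs**: parametric
  generators (cliques joined by single bridges; a cycle backbone with
  pendant chains; a w × l ladder with vertex-disjoint equal-length
  routes).
* **2D grids**: rectilinear (4 cardinal moves) or hexagonal (6 axial
  moves) with *state-invariant* action codes — the same one-hot means
  "move east" in every cell.  Affordances are 1 except for moves off the
  boundary.  State-invariance is what permits generalization to edges
  never traversed during exploration.
* **Point mass**: a damped unit mass on the plane driven by 8
  compass-direction forces (magnitude 1, damping 3, Euler step 0.1, each
  action applied for 5 integrator steps).  Observation (x, y, vx, vy).
  This is a synthetic desk-scale stand-in for a legged-robot simulator:
  it preserves the structure of the control problem (continuous
  observations, composite force actions, babbling-only training) while
  keeping the dynamics linear and fast.

## Exploration and learnability

Exploration is uniform random walking over afforded actions.  For the
grid-generalization study, a seeded set of held-out edges is excluded
from exploration and later probed during planning.  A walk set is
accepted only if it is *learnable*:

1. the remaining (non-held-out) edge set is connected;
2. every action occurs at least once;
3. the explored transition graph is connected — otherwise the relative
   position of an explored island in the map is mathematically
   unconstrained;
4. replay training on the candidate buffer converges (final mean squared
   prediction error below 10⁻²).

Condition 4 deserves explanation.  The per-transition update changes the
embedding of the *next* observation and of the executed action but not of
the current observation; the resulting joint dynamics are not a gradient
flow, and for a small fraction of minimal walk sets they stall in a
persistent oscillation with a bounded error floor instead of converging —
deterministically so: for a fixed buffer the outcome is the same across
weight initializations, state dimensions, learning-rate schedules and
replay orders.  On such a half-learned map greedy planning fails badly,
while on every converged map we have examined it is optimal.  The
experiment pipeline therefore treats non-convergence as a learnability
failure of the walk set, like an unvisited cell, and redraws the
exploration seed (deterministically, bounded attempts).  The screen uses
only the training error — a quantity the learner itself observes — never
planning performance.

## Evaluation

Planning is evaluated on seeded uniform random ordered start ≠ goal
pairs; every pair is also solved by Dijkstra (which receives the whole
graph for free) as the optimal baseline.  Episodes are capped at 4×
graph diameter (64 steps for the 32-node benchmark); episodes that hit
the cap or run out of afforded actions count as failures, are excluded
from mean path statistics, and are reported through the success rate.
Evaluation keeps plasticity off; learning during planning is available
but not used in benchmarks.

With these conditions the trained planner solves the 32-node benchmark
at a mean path length within a few percent of the Dijkstra mean
(ensemble values ≈ 3.5 vs ≈ 3.4 over graph draws), and the challenge
graphs exactly optimally.  On weighted graphs the cost integration is
deliberately greedy and local (costs enter only through affordance
gating), which leaves a cost overhead of ≈ 6–10 % over the optimum; this
is inherent to the method, not a training deficiency.

Deterministic greedy planning can enter a two-node oscillation on
unweighted graphs (≈ 1–5 % of trials, graph-dependent).  We keep those
as failures under the default protocol rather than adding an anti-loop
device, since the benchmark protocol for unweighted graphs specifies no
repeat-action ban; the weighted protocol's per-episode ban removes
loops there.

## Geometry diagnostics

* Action cosine matrix: distinct actions should stay near-orthogonal;
  the two traversals of the same edge anti-align (their embeddings must
  sum to ≈ 0 by cycle consistency).
* Cycle sums: the summed action embeddings along any closed walk,
  normalized by the mean action norm; ≈ 0 after convergence.
* Distance scaling: over near-orthogonal unit steps, k-step displacements
  have norm ≈ √k, so state-space distance should correlate with the
  square root of graph distance (r > 0.9 after training).
* Parallelism score: cosine between the state differences produced by
  the same action in two contexts; ≈ 1 on a compositional map.
* Map projection: principal components of the Q columns (actions
  projected as displacement vectors).  For a learned 2D maze the top two
  components carry > 80 % of the variance.  PCA is used instead of a
  stochastic nonlinear embedding so that diagnostics are deterministic.

## Continuous control

The continuous pathway implements the full quadruped tooling — the
29-field observation schema, index-to-torque action remapping (2^8
composite actions of ±0.1 per joint), target observations that overwrite
only the commanded fields, heading-relative target transformation,
joint-limit affordances (linear ramp over the last 10 % of the joint
range, averaged across joints per composite action), affordance-biased
babbling, and decoder regularization pushing `Qᵀ(Q o) → o` so that
planning-relevant fields stay represented — but exercises it on the
built-in point mass, since no physics simulator is bundled.  Babbling
uses 150 episodes of 30 random actions; the reported behavior (goal
reached to within 10 % of the initial distance, across seeds, without
any goal-directed training) is the point-mass restatement of the claim
that goal-directed control emerges from self-supervised prediction
alone.  Numbers from a physical quadruped simulation are out of scope.

## Numerical choices and degenerate inputs

* Winner-take-all excludes zero-affordance actions outright (their
  eligibility is −∞, not 0) so that a negative-utility afforded action is
  never beaten by an unavailable one; ties resolve to the lowest index,
  an arbitrary but documented convention.
* Generators validate infeasible parameter sets (e.g. minimum degree 2
  on two nodes) and raise rather than retry forever; bounded retries
  cover stochastic infeasibility.
* Quantization maps each matrix uniformly onto 2^bits levels spanning
  its own [min, max]; 8 bits leaves benchmark planning essentially
  unchanged (≤ 5 % mean-length increase), relevant for fixed-precision
  in-memory-computing substrates.
* No exact float equality is asserted anywhere in the geometry tests;
  closure and orthogonality checks use the relative tolerances stated in
  the test suite.

## Known limitations

* Greedy cost integration is local; it cannot trade a cheap detour now
  against an expensive region later.
* The linear readout `W` cannot represent both traversal directions of
  an edge exactly (see above); `Vᵀ` utilities are the default.
* A small fraction of minimal exploration sets (22 × 3 walks) are
  unlearnable in the strong sense described under "learnability"; the
  generator screens them out rather than pretending all walk sets are
  equivalent.
* The point mass is a linear system; conclusions about learning speed or
  map structure do not transfer quantitatively to articulated bodies.
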