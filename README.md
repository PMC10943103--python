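# cogmap

Cognitive map learning for online planning: a NumPy implementation of a
neural planning model that learns a high-dimensional map of a problem
space purely by predicting its next observation, then reaches arbitrary
goals by always taking the action whose embedding points most toward the
goal.

The package is aimed at computational neuroscientists and neuromorphic
engineers who want a small, fully inspectable model of how local synaptic
plasticity alone — no reward signal, no backpropagation, no stored
trajectories — can produce flexible, goal-directed planning, plus the
benchmarking and geometry-analysis tooling to study it.

## The model

Observations `o_t` and actions `a_t` (one-hot for discrete spaces) are
embedded into a common state space S of dimension `n_s` by two linear
maps, and learning reduces the one-step prediction error:

    s_t = Q o_t,        ŝ_{t+1} = s_t + V a_t
    ΔV  =  η_v (s_{t+1} − ŝ_{t+1}) a_tᵀ
    ΔQ  = −η_q (s_{t+1} − ŝ_{t+1}) o_{t+1}ᵀ

Once `Q o_{t+1} ≈ Q o_t + V a_t` holds for experienced transitions, the
utility of action `a` for reaching goal `o*` is the scalar product

    u_t(a) = (Q o* − Q o_t)ᵀ (V a),

and planning is a loop: compute `u_t = Vᵀ d_t`, gate elementwise by the
environment's affordances `g_t` (0 = unavailable, 1/cost on weighted
graphs), execute the winner-take-all action, repeat.  Each step costs one
matrix-vector product; no path is ever computed ahead, so goals can
change at any time for free.  A third matrix `W` can be trained by the
same kind of delta rule to replace the transpose `Vᵀ`.  Details,
parameter tables and known limitations are in `docs/methods.md`.

## Worked example

`examples/random_graph_planning.py` builds the standard benchmark — a
32-node random graph with node degrees in [2, 5], two actions per edge,
explored by 200 random walks of length 32 and replayed for 10 rounds
with `n_s = 1000`:

```
graph: 32 nodes, 44 edges, 88 actions
prediction error per sweep: first 52.64 -> last 0.00005
planner: mean 3.462 steps (std 1.421), success rate 0.948
Dijkstra: mean 3.267 steps (std 1.217)
ratio online/offline = 1.060 (1.0 would match the optimal offline planner)

example episode 0 -> 31: 0 -> 18 -> 8 -> 31 (3 steps)
```

The learned map plans within a few percent of Dijkstra — which receives
the entire graph for free — while choosing each action in constant time.
The failures (here ~5 % of trials) are deterministic greedy oscillations
between two nodes; they are counted as failures, not truncated paths.

The other examples each demonstrate one capability and print what the
numbers mean: `weighted_graph_costs.py` (least-cost planning through
reciprocal-cost affordances, and reward seeking via a virtual goal
node), `grid_generalization.py` (a 4×4 maze learned from 22 three-step
walks, planned optimally across edges never seen in training),
`map_geometry.py` (orthogonality, cycle sums, √-distance scaling),
`pointmass_control.py` (goal reaching that emerges from motor babbling
alone).  A thin CLI exposes the same pipelines:

```
cogmap run-preset random32 --seed 1
cogmap generate-env random_graph --out graph.tsv --seed 0
```

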