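"""Inspect the geometry of a learned cognitive map.

After training on the random-graph benchmark the map should show:
near-orthogonal action embeddings (except the two traversals of one edge,
which anti-align), cycle sums near zero, and state-space distances that
grow like the square root of graph distance.
"""

import numpy as np

from cogmap import (CMLModel, action_cosine_matrix, cycle_embedding_norm,
                    distance_scaling, generate_random_graph,
                    sample_exploration)

env = generate_random_graph(32, 2, 5, seed=1)
buffer = sample_exploration(env, 200, 32, seed=2)
model = CMLModel(n_o=env.n_o, n_a=env.n_a, n_s=1000, rng_seed=3)
model.train_on_replay(buffer, rounds=10)

cos = action_cosine_matrix(model)
off = cos[~np.eye(env.n_a, dtype=bool)]
print(f"action cosines: median |off-diagonal| {np.median(np.abs(off)):.3f}")

# forward and backward traversal of edge 0 should anti-align
print(f"cos(forward, backward) of one edge: {cos[0, 1]:.3f}")

# a 2-cycle: traverse one edge and come back
u, v = env.edges[0]
fwd = [k for k, w in env.neighbors_of(u) if w == v][0]
back = [k for k, w in env.neighbors_of(v) if w == u][0]
print(f"2-cycle embedding norm (relative): "
      f"{cycle_embedding_norm(model, env, u, [fwd, back]):.3f}")

table, r = distance_scaling(model, env, n_pairs=500, seed=4)
print(f"correlation of state distance with sqrt(graph distance): r = {r:.3f}")
print(table.to_string(index=False))
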