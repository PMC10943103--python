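import numpy as np
import pytest

from cogmap import (CMLModel, GraphEnvironment, generate_random_graph,
                    sample_exploration)


@pytest.fixture(scope="session")
def cycle4_env():
    """4-node cycle graph: 0-1-2-3-0."""
    return GraphEnvironment(4, [(0, 1), (1, 2), (2, 3), (0, 3)])


@pytest.fixture(scope="session")
def trained_cycle4(cycle4_env):
    """Model trained to convergence on the fully explored 4-cycle."""
    buf = sample_exploration(cycle4_env, 40, 16, seed=1)
    model = CMLModel(n_o=4, n_a=8, n_s=200, rng_seed=2)
    model.train_on_replay(buf, rounds=30)
    return model


@pytest.fixture(scope="session")
def small_benchmark():
    """A trained 16-node random-graph model (desk-scale stand-in for the
    32-node benchmark; keeps the unit-test suite fast)."""
    env = generate_random_graph(16, 2, 5, seed=3)
    buf = sample_exploration(env, 100, 32, seed=4)
    model = CMLModel(n_o=env.n_o, n_a=env.n_a, n_s=500, rng_seed=5)
    curve = model.train_on_replay(buf, rounds=10)
    return env, buf, model, curve
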