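"""Unit tests for the core learner: embeddings, plasticity, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogmap import CMLModel, Transition, select_action, quantize_weights
from cogmap.model import NoAffordedActionError, load_checkpoint, save_checkpoint


def tiny_model(**kw):
    kw.setdefault("n_o", 2)
    kw.setdefault("n_a", 2)
    kw.setdefault("n_s", 2)
    return CMLModel(**kw)


class TestEmbedding:
    def test_identity_embedding_selects_one_hot_entry(self):
        m = tiny_model()
        m.Q = np.eye(2)
        assert np.allclose(m.embed_observation([0, 1]), [0, 1])

    def test_one_hot_selects_column(self):
        m = tiny_model()
        assert np.allclose(m.embed_observation([0, 1]), m.Q[:, 1])
        assert np.allclose(m.embed_node(1), m.Q[:, 1])

    def test_general_matrix_vector_product(self):
        m = tiny_model()
        m.Q = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert np.allclose(m.embed_observation([0.5, 0.5]), [1.5, 3.5])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            tiny_model().embed_observation([1, 0, 0])


class TestPrediction:
    def test_zero_action_embedding_predicts_no_change(self):
        m = tiny_model()
        m.V = np.zeros((2, 2))
        s = np.array([3.0, -1.0])
        assert np.allclose(m.predict_next_state(s, [1, 0]), s)

    def test_one_hot_action_adds_column(self):
        m = tiny_model()
        s = np.zeros(2)
        assert np.allclose(m.predict_next_state(s, [0, 1]), m.V[:, 1])

    def test_hand_computed_example(self):
        m = tiny_model()
        m.V = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(m.predict_next_state([1, 0], [1, 0]), [1, 1])


class TestPlasticity:
    def test_perfect_prediction_leaves_q_and_v_unchanged(self):
        m = tiny_model()
        m.Q = np.eye(2)
        m.V = np.array([[-1.0, 0.0], [1.0, 0.0]])  # V a = exactly s1 - s0
        q0, v0 = m.Q.copy(), m.V.copy()
        m.apply_plasticity(Transition([1, 0], [1, 0], [0, 1]))
        assert np.allclose(m.Q, q0)
        assert np.allclose(m.V, v0)

    def test_zero_learning_rate_freezes_v(self):
        m = tiny_model(eta_v=0.0)
        v0 = m.V.copy()
        m.apply_plasticity(Transition([1, 0], [1, 0], [0, 1]))
        assert np.allclose(m.V, v0)

    def test_single_step_delta_rule_hand_computation(self):
        # Q = I, V = 0: prediction error is (0,1) - (1,0) = (-1,1)
        m = tiny_model(eta_v=0.01)
        m.Q = np.eye(2)
        m.V = np.zeros((2, 2))
        m.W = np.zeros((2, 2))
        q_before = m.Q.copy()
        m.apply_plasticity(Transition([1, 0], [1, 0], [0, 1]))
        assert np.allclose(m.V[:, 0], [-0.01, 0.01])
        assert np.allclose(m.V[:, 1], 0.0)
        # Q update pushes the *next* observation's column opposite the error
        assert np.allclose(m.Q[:, 1], q_before[:, 1] - m.eta_q * np.array([-1, 1]))

    def test_fast_path_matches_dense_rule(self):
        dense = CMLModel(n_o=5, n_a=6, n_s=40, rng_seed=9)
        fast = dense.copy()
        o, a, o2 = np.zeros(5), np.zeros(6), np.zeros(5)
        o[1] = a[4] = o2[3] = 1.0
        dense.apply_plasticity(Transition(o, a, o2))
        fast._update_indices(1, 4, 3)
        assert np.allclose(dense.Q, fast.Q)
        assert np.allclose(dense.V, fast.V)
        assert np.allclose(dense.W, fast.W)

    def test_repeated_transition_error_decreases_monotonically(self):
        m = CMLModel(n_o=2, n_a=2, n_s=50, eta_q=0.05, eta_v=0.05, rng_seed=0)
        tr = Transition([1, 0], [1, 0], [0, 1])
        errs = [m.apply_plasticity(tr) for _ in range(200)]
        assert errs[-1] < 1e-6
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_normalize_v_keeps_unit_columns(self):
        m = CMLModel(n_o=3, n_a=3, n_s=30, normalize_v=True, rng_seed=1)
        m.apply_plasticity(Transition([1, 0, 0], [0, 1, 0], [0, 0, 1]))
        assert np.allclose(np.linalg.norm(m.V, axis=0), 1.0)


class TestTrainOnReplay:
    def test_zero_rounds_rejected(self, small_benchmark):
        _, buf, _, _ = small_benchmark
        with pytest.raises(ValueError, match="rounds"):
            CMLModel(n_o=16, n_a=buf.act.max() + 1, n_s=10).train_on_replay(buf, 0)

    def test_empty_buffer_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tiny_model().train_on_replay([], rounds=1)

    def test_benchmark_error_descends(self, small_benchmark):
        _, _, _, curve = small_benchmark
        assert curve[-1] < curve[0]

    def test_error_non_increasing_at_small_rate(self, small_benchmark):
        env, buf, _, _ = small_benchmark
        m = CMLModel(n_o=env.n_o, n_a=env.n_a, n_s=500,
                     eta_q=0.01, eta_v=0.001, rng_seed=11)
        curve = m.train_on_replay(buf, rounds=20)
        assert all(b <= a * 1.001 for a, b in zip(curve, curve[1:]))


class TestActionSelection:
    def test_unique_maximum(self):
        a = select_action(np.array([0.2, 0.9, 0.1]), np.ones(3))
        assert np.array_equal(a, [0, 1, 0])

    def test_tie_broken_by_lowest_index(self):
        a = select_action(np.array([0.9, 0.9, 0.1]), np.ones(3))
        assert np.array_equal(a, [1, 0, 0])

    def test_gating_masks_larger_utility(self):
        a = select_action(np.array([5.0, 1.0]), np.array([0.0, 1.0]))
        assert np.array_equal(a, [0, 1])

    def test_all_zero_affordance_raises(self):
        with pytest.raises(NoAffordedActionError):
            select_action(np.array([1.0, 2.0]), np.zeros(2))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=8))
    def test_wta_is_deterministic_one_hot(self, utilities):
        u = np.array(utilities)
        g = np.ones_like(u)
        a1, a2 = select_action(u, g), select_action(u, g)
        assert np.array_equal(a1, a2)
        assert a1.sum() == 1 and set(np.unique(a1)) <= {0.0, 1.0}


class TestQuantization:
    def test_many_bits_preserve_weights(self, small_benchmark):
        _, _, model, _ = small_benchmark
        q = quantize_weights(model, 24)
        assert np.allclose(q.V, model.V, atol=1e-4)

    def test_one_bit_snaps_to_extremes(self):
        m = tiny_model()
        m.Q = np.array([[0.0, 0.3], [0.8, 1.0]])
        q = quantize_weights(m, 1)
        assert set(np.unique(q.Q)) <= {0.0, 1.0}

    def test_invalid_bits_rejected(self):
        with pytest.raises(ValueError):
            quantize_weights(tiny_model(), 0)


class TestCheckpoint:
    def test_round_trip_is_bit_exact(self, tmp_path, small_benchmark):
        _, _, model, _ = small_benchmark
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert np.array_equal(loaded.Q, model.Q)
        assert np.array_equal(loaded.V, model.V)
        assert np.array_equal(loaded.W, model.W)
        assert loaded.n_s == model.n_s and loaded.eta_q == model.eta_q
        assert loaded.w_update == model.w_update


class TestInitialization:
    def test_gaussian_init_columns_near_orthogonal_at_high_dim(self):
        # random high-dimensional vectors are nearly orthogonal
        m = CMLModel(n_o=32, n_a=88, n_s=1000, rng_seed=42)
        vn = m.V / np.linalg.norm(m.V, axis=0)
        cos = vn.T @ vn
        off = cos[~np.eye(88, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_seeded_init_reproducible(self):
        a = CMLModel(n_o=4, n_a=4, n_s=16, rng_seed=7)
        b = CMLModel(n_o=4, n_a=4, n_s=16, rng_seed=7)
        assert np.array_equal(a.Q, b.Q) and np.array_equal(a.V, b.V)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            CMLModel(n_o=0, n_a=2, n_s=2)
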