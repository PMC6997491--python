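"""Classifier mechanics: weights, batching, schedule, stopping, learning."""

import numpy as np
import pytest

from somnistage import (
    EarlyStopper,
    LSTMClassifier,
    ModelConfig,
    TrainConfig,
    build_model,
    class_weights,
    learning_rate,
    make_minibatches,
    train,
)
from somnistage.model import DivergenceError, softmax


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        assert np.allclose(class_weights([20, 20, 20, 20, 20]), 1.0)

    def test_inverse_frequency_formula(self):
        w = class_weights([10, 10, 10, 10, 60])
        assert np.allclose(w, [2.0, 2.0, 2.0, 2.0, 1 / 3])

    def test_absent_class_gets_zero_weight(self):
        w = class_weights([10, 0, 10, 10, 10])
        assert w[1] == 0.0 and np.all(w[[0, 2, 3, 4]] > 0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            class_weights([0, 0, 0, 0, 0])


class TestMakeMinibatches:
    def test_ten_samples_batch4_gives_two_batches(self):
        batches = make_minibatches({"s": np.arange(10)}, 4, group_size=1, seed=0)
        assert len(batches) == 2
        assert all(len(b) == 4 for b in batches)
        used = np.concatenate(batches)
        assert len(np.unique(used)) == 8  # 2 samples discarded

    def test_exact_multiple_discards_nothing(self):
        subj = {0: np.arange(6), 1: np.arange(6, 12)}
        batches = make_minibatches(subj, 4, group_size=2, seed=3)
        used = np.sort(np.concatenate(batches))
        assert np.array_equal(used, np.arange(12))

    def test_deterministic_under_seed(self):
        subj = {i: np.arange(i * 7, (i + 1) * 7) for i in range(5)}
        a = make_minibatches(subj, 8, group_size=2, seed=11)
        b = make_minibatches(subj, 8, group_size=2, seed=11)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert len(a) == len(b)

    def test_batches_partition_retained_samples(self):
        subj = {i: np.arange(i * 13, (i + 1) * 13) for i in range(4)}
        B = 8
        batches = make_minibatches(subj, B, group_size=3, seed=5)
        used = np.concatenate(batches)
        assert len(used) == len(np.unique(used))
        assert 52 - len(used) < B  # discarded count < batch size


class TestLearningRateSchedule:
    def test_trace_matches_closed_form(self):
        cfg = TrainConfig()
        for e in range(200):
            expected = max(1e-3 * 10.0 ** (-(e // 50)), 1e-6)
            assert learning_rate(e, cfg) == pytest.approx(expected)

    def test_key_epochs(self):
        cfg = TrainConfig()
        assert learning_rate(0, cfg) == pytest.approx(1e-3)
        assert learning_rate(50, cfg) == pytest.approx(1e-4)
        assert learning_rate(150, cfg) == pytest.approx(1e-6)
        assert learning_rate(199, cfg) == pytest.approx(1e-6)


class TestEarlyStopper:
    def test_plateau_stops_after_five_flat_differences(self):
        stop = EarlyStopper(tol=1e-5, patience=5)
        costs = [1.0] + [1.0] * 5
        decisions = [stop.update(c) for c in costs]
        assert decisions == [False] * 5 + [True]
        assert stop.reason == "plateau"

    def test_rise_stops_after_five_increases(self):
        stop = EarlyStopper(tol=1e-5, patience=5)
        costs = [1.0, 1.1, 1.2, 1.3, 1.4, 1.5]
        decisions = [stop.update(c) for c in costs]
        assert decisions[-1] and stop.reason == "rise"

    def test_decreasing_costs_never_stop(self):
        stop = EarlyStopper()
        assert not any(stop.update(1.0 - 0.01 * k) for k in range(20))


class TestModel:
    def test_softmax_output_sums_to_one(self, rng):
        m = build_model(ModelConfig(n_cells=8, mode=1), seed=0)
        p = m.predict_proba(rng.random((3, 32, 128)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_same_seed_same_initial_logits(self, rng):
        X = rng.random((2, 32, 128)).astype(np.float32)
        a = build_model(ModelConfig(n_cells=8, mode=1), seed=7).predict_proba(X)
        b = build_model(ModelConfig(n_cells=8, mode=1), seed=7).predict_proba(X)
        assert np.array_equal(a, b)

    def test_mode3_shape_validation(self, rng):
        m = build_model(ModelConfig(n_cells=8, mode=3), seed=0)
        m.predict_proba(rng.random((1, 96, 128)))  # accepted
        with pytest.raises(ValueError, match="96"):
            m.predict_proba(rng.random((1, 97, 128)))

    def test_uniform_logits_tie_breaks_to_class_0(self):
        assert int(np.argmax(softmax(np.zeros(5)))) == 0

    def test_batch_prediction_equals_per_sample(self, rng):
        m = build_model(ModelConfig(n_cells=8, mode=1), seed=1)
        X = rng.random((5, 32, 128)).astype(np.float32)
        batch = m.predict(X)
        singles = np.array([m.predict(X[i : i + 1])[0] for i in range(5)])
        assert np.array_equal(batch, singles)

    def test_doubling_weights_doubles_cost(self, rng):
        m = build_model(ModelConfig(n_cells=8, mode=1), seed=2)
        X = rng.random((6, 32, 128)).astype(np.float32)
        y = np.array([0, 1, 2, 3, 4, 0])
        w = class_weights(np.bincount(y, minlength=5))
        l1, _ = m.loss_and_grads(X, y, w)
        l2, _ = m.loss_and_grads(X, y, 2 * w)
        assert l2 == pytest.approx(2 * l1, rel=1e-6)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        m = build_model(ModelConfig(n_cells=8, mode=2), seed=3)
        X = rng.random((2, 64, 128)).astype(np.float32)
        m.save(tmp_path / "m.npz")
        back = LSTMClassifier.load(tmp_path / "m.npz")
        assert back.config.mode == 2
        assert np.array_equal(back.predict_proba(X), m.predict_proba(X))

    def test_gradients_match_finite_differences(self, rng):
        """BPTT oracle: numerical gradient on a tiny model."""
        m = build_model(ModelConfig(n_cells=4, n_inputs=6, mode=1), seed=4)
        X = rng.random((3, 32, 6)).astype(np.float64)
        y = np.array([0, 2, 4])
        w = np.ones(5)
        _, grads = m.loss_and_grads(X, y, w)
        eps = 1e-4
        for name in ("Wx", "Wh", "b", "Wy", "by"):
            param = getattr(m, name)
            flat_idx = (np.array([0]), ) if param.ndim == 1 else (np.array([0]), np.array([1]))
            idx = tuple(i[0] for i in flat_idx)
            orig = param[idx]
            param[idx] = orig + eps
            lp, _ = m.loss_and_grads(X, y, w)
            param[idx] = orig - eps
            lm, _ = m.loss_and_grads(X, y, w)
            param[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, rel=5e-2, abs=1e-5)


class TestTraining:
    def _toy_problem(self, rng, n=120):
        """Two linearly separable synthetic sequence classes."""
        X = rng.normal(0, 0.1, (n, 32, 128)).astype(np.float32)
        y = (np.arange(n) % 2).astype(int)
        X[y == 1, :, :16] += 1.0
        X[y == 0, :, 16:32] += 1.0
        return X, y * 2  # labels 0 and 2 keep the five-class contract

    def test_cost_strictly_decreases_on_separable_data(self, rng):
        X, y = self._toy_problem(rng)
        cfg = TrainConfig(max_epochs=5, batch_size=30, seed=0)
        m = build_model(ModelConfig(n_cells=16, mode=1), seed=0)
        batches = make_minibatches({0: np.arange(len(X))}, 30, 1, seed=0)
        trace = train(m, X, y, batches, X[:40], y[:40], cfg)
        diffs = np.diff(trace.train_costs)
        assert np.all(diffs < 0)

    def test_plateau_stopping_fires(self, rng):
        X, y = self._toy_problem(rng, n=60)
        cfg = TrainConfig(max_epochs=50, batch_size=30, seed=0,
                          plateau_tol=10.0)  # any difference counts as flat
        m = build_model(ModelConfig(n_cells=8, mode=1), seed=0)
        batches = make_minibatches({0: np.arange(len(X))}, 30, 1, seed=0)
        trace = train(m, X, y, batches, X[:20], y[:20], cfg)
        assert trace.stop_reason == "plateau"
        assert len(trace.train_costs) == 6  # five flat differences need six epochs

    def test_divergence_aborts_with_diagnostic(self, rng):
        m = build_model(ModelConfig(n_cells=4, mode=1), seed=0)
        X = np.full((2, 32, 128), np.nan, dtype=np.float32)
        with pytest.raises(DivergenceError):
            m.loss_and_grads(X, np.array([0, 1]), np.ones(5))
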