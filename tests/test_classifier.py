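"""Reference softmax classifier: probabilities, loss, training, evaluation."""

import numpy as np
import pytest

from endospectra.classifier import (
    SoftmaxModel,
    TrainConfig,
    cross_entropy,
    evaluate,
    softmax_probs,
    train,
)
from endospectra.classifier import _gradients  # gradient oracle check


def blobs(seed=0, n_per_class=100, sep=6.0):
    """Two linearly separable Gaussian clusters in 2-D."""
    rng = np.random.default_rng(seed)
    a = rng.normal([0.0, 0.0], 1.0, (n_per_class, 2))
    b = rng.normal([sep, sep], 1.0, (n_per_class, 2))
    x = np.vstack([a, b])
    y = np.repeat([0, 1], n_per_class)
    return x, y


class TestSoftmax:
    def test_zero_parameters_give_uniform(self):
        model = SoftmaxModel(np.zeros((5, 3)), np.zeros(5), [str(i) for i in range(5)])
        np.testing.assert_allclose(softmax_probs(model, np.ones(3)), 0.2)

    def test_extreme_logits_do_not_overflow(self):
        model = SoftmaxModel(np.array([[1000.0], [0.0]]), np.zeros(2), ["a", "b"])
        p = softmax_probs(model, np.array([1.0]))
        assert np.all(np.isfinite(p))
        np.testing.assert_allclose(p, [1.0, 0.0], atol=1e-12)

    def test_matches_extended_precision_oracle(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 5, 7)
        model = SoftmaxModel(np.eye(7), np.zeros(7), [str(i) for i in range(7)])
        p = softmax_probs(model, z)
        e = np.exp(np.longdouble(z))
        np.testing.assert_allclose(p, (e / e.sum()).astype(float), rtol=1e-12)

    def test_shift_invariance_and_normalization(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=4)
        m1 = SoftmaxModel(np.eye(4), np.zeros(4), list("abcd"))
        m2 = SoftmaxModel(np.eye(4), np.full(4, 3.7), list("abcd"))
        np.testing.assert_allclose(softmax_probs(m1, z), softmax_probs(m2, z), atol=1e-12)
        assert softmax_probs(m1, z).sum() == pytest.approx(1.0, abs=1e-9)

    def test_feature_mismatch(self):
        model = SoftmaxModel(np.zeros((2, 3)), np.zeros(2), ["a", "b"])
        with pytest.raises(ValueError):
            softmax_probs(model, np.ones(4))


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        assert cross_entropy(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 0.0

    def test_uniform_prediction_is_log_c(self):
        for c in (2, 5, 8):
            p = np.full(c, 1.0 / c)
            y = np.eye(c)[0]
            assert cross_entropy(p, y) == pytest.approx(np.log(c))

    def test_matches_per_sample_loop(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(size=(6, 4))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        labels = np.eye(4)[rng.integers(0, 4, 6)]
        acc = sum(-np.log(probs[i][labels[i].argmax()]) for i in range(6)) / 6
        assert cross_entropy(probs, labels) == pytest.approx(acc)

    def test_zero_probability_floored(self):
        p = np.array([0.0, 1.0])
        y = np.array([1.0, 0.0])
        assert cross_entropy(p, y) == pytest.approx(-np.log(1e-12))


class TestTraining:
    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(10, 4)), rng.integers(0, 3, 10)
        one_hot = np.eye(3)[y]
        model = SoftmaxModel(rng.normal(0, 0.1, (3, 4)), rng.normal(0, 0.1, 3),
                             ["a", "b", "c"])
        gw, gb = _gradients(model, x, one_hot)

        def loss_at(w, b):
            m = SoftmaxModel(w, b, model.classes)
            return cross_entropy(
                np.exp(np.clip(x @ w.T + b, -500, 500))
                / np.exp(np.clip(x @ w.T + b, -500, 500)).sum(axis=1, keepdims=True),
                one_hot,
            )

        eps = 1e-6
        for idx in [(0, 0), (1, 2), (2, 3)]:
            w_hi, w_lo = model.weights.copy(), model.weights.copy()
            w_hi[idx] += eps
            w_lo[idx] -= eps
            fd = (loss_at(w_hi, model.bias) - loss_at(w_lo, model.bias)) / (2 * eps)
            assert gw[idx] == pytest.approx(fd, abs=1e-5)
        for j in range(3):
            b_hi, b_lo = model.bias.copy(), model.bias.copy()
            b_hi[j] += eps
            b_lo[j] -= eps
            fd = (loss_at(model.weights, b_hi) - loss_at(model.weights, b_lo)) / (2 * eps)
            assert gb[j] == pytest.approx(fd, abs=1e-5)

    def test_separable_blobs_reach_full_training_accuracy(self):
        x, y = blobs(seed=0, n_per_class=100)
        cfg = TrainConfig(epochs=50, batch_size=64, learning_rate=1e-2, seed=7)
        model = train(x, y, cfg)
        cm = evaluate(model, x, y)
        assert np.trace(cm.counts) == len(y)  # diagonal confusion matrix
        assert np.all(cm.counts == np.diag([100, 100]))

    def test_zero_learning_rate_leaves_parameters_untouched(self):
        x, y = blobs(seed=1, n_per_class=20)
        model = train(x, y, TrainConfig(epochs=3, learning_rate=0.0, seed=0))
        assert np.all(model.weights == 0.0) and np.all(model.bias == 0.0)

    def test_full_batch_loss_monotone_on_convex_problem(self):
        # training is deterministic given the seed, so the loss after n
        # epochs is read off by retraining from scratch for each n
        x, y = blobs(seed=2, n_per_class=50)
        one_hot = np.eye(2)[y]

        def loss_after(epochs):
            if epochs == 0:
                return np.log(2.0)
            cfg = TrainConfig(epochs=epochs, batch_size=len(y),
                              learning_rate=1e-3, seed=0)
            model = train(x, y, cfg)
            return cross_entropy(softmax_probs(model, x), one_hot)

        losses = [loss_after(n) for n in (0, 1, 2, 5, 10, 20, 40)]
        assert np.all(np.diff(losses) <= 1e-12)

    def test_seeded_reproducibility(self):
        x, y = blobs(seed=3, n_per_class=30)
        cfg = TrainConfig(epochs=5, seed=11)
        m1, m2 = train(x, y, cfg), train(x, y, cfg)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.bias, m2.bias)
        cm1, cm2 = evaluate(m1, x, y), evaluate(m2, x, y)
        np.testing.assert_array_equal(cm1.counts, cm2.counts)

    def test_single_class_rejected(self):
        x = np.zeros((5, 2))
        with pytest.raises(ValueError):
            train(x, np.zeros(5, dtype=int))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(beta1=1.0)
        with pytest.raises(ValueError):
            TrainConfig(epsilon=0.0)


class TestEvaluate:
    def test_empty_dataset_rejected(self):
        model = SoftmaxModel(np.zeros((2, 2)), np.zeros(2), ["a", "b"])
        with pytest.raises(ValueError):
            evaluate(model, np.zeros((0, 2)), np.zeros(0, dtype=int))

    def test_duplicated_dataset_doubles_counts(self):
        x, y = blobs(seed=4, n_per_class=25)
        model = train(x, y, TrainConfig(epochs=10, learning_rate=1e-2, seed=0))
        cm1 = evaluate(model, x, y)
        cm2 = evaluate(model, np.vstack([x, x]), np.concatenate([y, y]))
        np.testing.assert_array_equal(cm2.counts, 2 * cm1.counts)
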