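"""Reference multinomial logistic-regression classifier.

A single linear layer Z = W X + b followed by softmax, trained with
cross-entropy loss and a moment-based gradient update

    m_t = b1 m_{t-1} + (1 - b1) g
    v_t = b2 v_{t-1} + (1 - b2) g^2
    theta_t = theta_{t-1} - eta m_t / (sqrt(v_t) + eps)

i.e. Adam-style first/second moment accumulation *without* the usual
bias-correction terms (switchable); setting b1 = b2 = 0 degenerates to
sign-normalized SGD.  Intended as a desk-scale demonstrator over
flattened grayscale frames, not a competitive image classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classification import ConfusionMatrix

logger = logging.getLogger(__name__)

__all__ = ["SoftmaxModel", "TrainConfig", "softmax_probs", "cross_entropy",
           "train", "evaluate", "images_to_features"]

_PROB_FLOOR = 1e-12


@dataclass
class SoftmaxModel:
    weights: np.ndarray  # classes x features
    bias: np.ndarray  # classes
    classes: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.shape[0] != len(self.classes) or self.bias.shape != (len(self.classes),):
            raise ValueError("weight/bias shapes inconsistent with class count")

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 64
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    bias_correction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("moment coefficients must lie in [0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _logits(model: SoftmaxModel, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {x.shape[1]}")
    return x @ model.weights.T + model.bias


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)  # overflow-safe
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_probs(model: SoftmaxModel, x: np.ndarray) -> np.ndarray:
    """Class-probability vector(s) for feature vector(s) ``x``."""
    p = _softmax(_logits(model, x))
    return p[0] if np.asarray(x).ndim == 1 else p


def cross_entropy(probs: np.ndarray, one_hot: np.ndarray) -> float:
    """Mean negative log-probability of the true class.

    Probabilities below 1e-12 are floored before the log (logged), so a
    confidently wrong prediction yields a large finite loss.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    one_hot = np.atleast_2d(np.asarray(one_hot, dtype=float))
    if probs.shape != one_hot.shape:
        raise ValueError("probability and label shapes differ")
    p_true = np.sum(probs * one_hot, axis=1)
    n_floored = int(np.sum(p_true < _PROB_FLOOR))
    if n_floored:
        logger.debug("cross_entropy floored %d probabilities at %g", n_floored, _PROB_FLOOR)
    return float(np.mean(-np.log(np.maximum(p_true, _PROB_FLOOR))))


def _gradients(model: SoftmaxModel, x: np.ndarray, one_hot: np.ndarray):
    """Mean cross-entropy gradients: dW = (p - y)^T x / n, db = mean(p - y)."""
    p = _softmax(_logits(model, x))
    delta = (p - one_hot) / x.shape[0]
    return delta.T @ x, delta.sum(axis=0)


def train(features: np.ndarray, labels: np.ndarray, cfg: TrainConfig | None = None,
          classes: list[str] | None = None) -> SoftmaxModel:
    """Train from zero-initialized parameters with seeded mini-batches.

    ``labels`` are integer class indices.  The same configuration and
    data reproduce the parameter trajectory bit for bit.
    """
    cfg = TrainConfig() if cfg is None else cfg
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or y.shape != (x.shape[0],):
        raise ValueError("features must be n x d with one label per row")
    uniq = np.unique(y)
    n_classes = int(uniq.max()) + 1 if classes is None else len(classes)
    if uniq.size < 2:
        raise ValueError("training needs at least two classes")
    class_names = classes if classes is not None else [str(i) for i in range(n_classes)]
    one_hot = np.eye(n_classes)[y]

    model = SoftmaxModel(np.zeros((n_classes, x.shape[1])), np.zeros(n_classes), class_names)
    m_w = np.zeros_like(model.weights)
    v_w = np.zeros_like(model.weights)
    m_b = np.zeros_like(model.bias)
    v_b = np.zeros_like(model.bias)

    rng = np.random.default_rng(cfg.seed)
    n = x.shape[0]
    t = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            gw, gb = _gradients(model, x[idx], one_hot[idx])
            t += 1
            m_w = cfg.beta1 * m_w + (1 - cfg.beta1) * gw
            v_w = cfg.beta2 * v_w + (1 - cfg.beta2) * gw**2
            m_b = cfg.beta1 * m_b + (1 - cfg.beta1) * gb
            v_b = cfg.beta2 * v_b + (1 - cfg.beta2) * gb**2
            if cfg.bias_correction:
                mw_h = m_w / (1 - cfg.beta1**t)
                vw_h = v_w / (1 - cfg.beta2**t)
                mb_h = m_b / (1 - cfg.beta1**t)
                vb_h = v_b / (1 - cfg.beta2**t)
            else:
                mw_h, vw_h, mb_h, vb_h = m_w, v_w, m_b, v_b
            model.weights -= cfg.learning_rate * mw_h / (np.sqrt(vw_h) + cfg.epsilon)
            model.bias -= cfg.learning_rate * mb_h / (np.sqrt(vb_h) + cfg.epsilon)
    return model


def evaluate(model: SoftmaxModel, features: np.ndarray, labels: np.ndarray) -> ConfusionMatrix:
    """Argmax predictions tallied into a confusion matrix.

    Ties break toward the lowest class index (np.argmax convention)."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.shape[0] == 0:
        raise ValueError("empty evaluation set")
    pred = np.argmax(_softmax(_logits(model, x)), axis=1)
    n = len(model.classes)
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (y, pred), 1)
    return ConfusionMatrix(classes=list(model.classes), counts=counts)


def images_to_features(frames: np.ndarray, size: int = 256) -> np.ndarray:
    """Flatten RGB frames to grayscale feature vectors.

    Luminance-weighted channel mean (Rec.601 weights), bilinear resize
    to ``size`` x ``size``, then row-major flattening — 65,536 features
    at the default size.
    """
    from skimage.transform import resize

    frames = np.asarray(frames, dtype=float)
    single = frames.ndim == 3
    frames = frames[None] if single else frames
    if frames.max() > 1.0:
        frames = frames / 255.0
    gray = frames @ np.array([0.299, 0.587, 0.114])
    out = np.stack(
        [resize(g, (size, size), order=1, anti_aliasing=False).ravel() for g in gray]
    )
    return out[0] if single else out
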