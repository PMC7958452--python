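"""Scalar losses returning (value, gradient-w.r.t.-input) pairs."""

from __future__ import annotations

import numpy as np

from .layers import DTYPE


def bce_with_logits(logits: np.ndarray, target: float | np.ndarray):
    """Mean binary cross-entropy on raw logits.

    Numerically stable form: ``max(z,0) - z*t + log(1+exp(-|z|))``.
    Gradient is ``(sigmoid(z) - t) / n``.
    """
    z = np.asarray(logits, dtype=np.float64).ravel()
    t = np.broadcast_to(np.asarray(target, dtype=np.float64), z.shape)
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    sig = 1.0 / (1.0 + np.exp(-z))
    grad = ((sig - t) / z.size).astype(DTYPE).reshape(np.shape(logits))
    return float(loss), grad


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of softmax over the last axis of (N, K) logits."""
    z = np.asarray(logits, dtype=np.float64)
    n = z.shape[0]
    zs = z - z.max(axis=1, keepdims=True)
    logp = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
    labels = np.asarray(labels, dtype=int)
    loss = -logp[np.arange(n), labels].mean()
    grad = np.exp(logp)
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


def l1_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error; subgradient sign(pred - target)/numel."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = (np.sign(diff) / diff.size).astype(DTYPE)
    return loss, grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=np.float64)
    zs = z - z.max(axis=-1, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=-1, keepdims=True)
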