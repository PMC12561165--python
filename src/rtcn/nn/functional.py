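"""Loss functions and numerically stable softmax utilities."""
from __future__ import annotations

import numpy as np


def softmax(logits, axis=-1):
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits, targets):
    """Mean cross-entropy over the batch.

    Returns ``(loss, grad_logits)`` where the gradient is (p - onehot)/N —
    ready to feed the model's backward pass.
    """
    n = logits.shape[0]
    p = softmax(logits)
    idx = (np.arange(n), np.asarray(targets, dtype=int))
    loss = float(-np.mean(np.log(np.clip(p[idx], 1e-12, None))))
    grad = p.copy()
    grad[idx] -= 1.0
    return loss, grad / n


def mse(pred, target):
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size
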