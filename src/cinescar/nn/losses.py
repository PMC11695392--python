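"""Binary cross-entropy on logits, numerically stable."""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Logistic function, clipped away from 0 and 1 so downstream
    probability contracts (and log-losses on outputs) stay well-defined."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    eps = np.finfo(float).eps
    return np.clip(out, eps, 1.0 - eps)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits.

    Uses the log-sum-exp form max(z,0) - z*y + log(1 + exp(-|z|)) so large
    logits never overflow.
    """
    z = np.asarray(logits, dtype=float).ravel()
    y = np.asarray(targets, dtype=float).ravel()
    if z.shape != y.shape:
        raise ValueError("logits and targets must have the same length")
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / z.size).reshape(np.asarray(logits).shape)
    return loss, grad
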