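"""Huber loss: quadratic near zero, linear in the tails.

For residual r = y - f(x) and threshold delta:

    L(r) = r^2 / 2                  for |r| <= delta
    L(r) = delta * |r| - delta^2/2  otherwise

The loss is continuous with continuous first derivative at |r| = delta, is
bounded above by the squared-error branch everywhere, and its gradient
saturates at delta for large residuals — which is what makes it robust to
the outliers that survive quality control.
"""

from __future__ import annotations

import numpy as np

__all__ = ["huber_loss", "huber_grad"]


def huber_loss(y: np.ndarray, fx: np.ndarray, delta: float = 1.0) -> float:
    """Mean Huber loss over all elements."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = np.asarray(y, dtype=float) - np.asarray(fx, dtype=float)
    a = np.abs(r)
    quad = 0.5 * r**2
    lin = delta * a - 0.5 * delta**2
    return float(np.mean(np.where(a <= delta, quad, lin)))


def huber_grad(y: np.ndarray, fx: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """Gradient of the mean Huber loss with respect to the prediction fx."""
    y = np.asarray(y, dtype=float)
    fx = np.asarray(fx, dtype=float)
    r = y - fx
    return -np.clip(r, -delta, delta) / r.size
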