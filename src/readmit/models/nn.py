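"""Minimal NumPy neural-net core: dense layers, Adam, softmax cross-entropy.

Sized for desk-scale CPU training of the two network models. Sparse
(CSR) inputs are supported in the first layer. Dropout is applied only
during training; inference is deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["Adam", "he_init", "softmax", "softmax_xent", "relu", "Dropout"]


def he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray):
    """Mean categorical cross-entropy and gradient w.r.t. logits.

    ``y`` holds integer class labels (0/1 for the two-unit output)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, g / n


class Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = float(rate)
        self.rng = rng
        self.mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self.mask = None
            return x
        self.mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self.mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self.mask is None else g * self.mask


class Adam:
    """Adam optimizer over a flat dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            self.params[k] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def matmul(X, W):
    """X @ W for dense or CSR X."""
    return X @ W if not sparse.issparse(X) else X.dot(W)
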