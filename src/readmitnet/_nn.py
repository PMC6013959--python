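"""Shared numerics for the hand-rolled networks: activations with
derivatives, inverted dropout, sigmoid cross-entropy, and classical
momentum SGD."""

from __future__ import annotations

import numpy as np


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _d_sigmoid(pre, val):
    return val * (1.0 - val)


def _d_tanh(pre, val):
    return 1.0 - val * val


def _d_softplus(pre, val):
    return sigmoid(pre)


def _softsign(x):
    return x / (1.0 + np.abs(x))


def _d_softsign(pre, val):
    return 1.0 / (1.0 + np.abs(pre)) ** 2


ACTIVATIONS = {
    "sigmoid": (sigmoid, _d_sigmoid),
    "tanh": (np.tanh, _d_tanh),
    "softplus": (lambda x: np.logaddexp(0.0, x), _d_softplus),
    "softsign": (_softsign, _d_softsign),
}


def get_activation(name: str):
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; "
                         f"choose from {sorted(ACTIVATIONS)}") from None


def dropout_mask(rng: np.random.Generator, shape, rate: float):
    """Inverted-dropout multiplier: zeros with probability ``rate``,
    1/(1-rate) otherwise, so inference needs no rescaling."""
    if rate <= 0.0:
        return None
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(float) / keep


def bce_loss(y_hat, y, eps: float = 1e-12):
    y_hat = np.clip(y_hat, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(y_hat) + (1.0 - y) * np.log(1.0 - y_hat)))


class MomentumSGD:
    """Classical momentum: v <- mu*v - lr*g; theta <- theta + v."""

    def __init__(self, learning_rate: float, momentum: float):
        self.lr = learning_rate
        self.mu = momentum
        self._v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        for key, g in grads.items():
            if g is None:
                continue
            v = self._v.get(key)
            if v is None:
                v = np.zeros_like(g)
            v = self.mu * v - self.lr * g
            self._v[key] = v
            params[key] += v


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]
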