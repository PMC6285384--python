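"""Minimal dense-network training engine (numpy).

Forward/backward passes for fully-connected layers with relu/tanh/linear
activations, softmax + categorical cross-entropy heads, and the two
stochastic optimizers the architectures in :mod:`cdrp.nets` train with
(RMSProp and Adadelta).  Weights are Glorot-uniform initialized from a
seeded generator, so training is bit-reproducible for a fixed seed under
single-threaded BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "RMSProp", "Adadelta", "softmax",
           "categorical_crossentropy", "glorot_uniform"]


def glorot_uniform(n_in: int, n_out: int, rng: np.random.Generator):
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def _relu(z):
    return np.maximum(z, 0.0)


def _relu_grad(z, a):
    return (z > 0.0).astype(z.dtype)


def _tanh_grad(z, a):
    return 1.0 - a * a


_ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "tanh": (np.tanh, _tanh_grad),
    "linear": (lambda z: z, lambda z, a: np.ones_like(z)),
}


class Dense:
    """Fully-connected layer ``a = act(x W + b)`` with cached backward."""

    def __init__(self, n_in: int, n_out: int, activation: str,
                 rng: np.random.Generator):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.n_in, self.n_out = n_in, n_out
        self.activation = activation
        self.W = glorot_uniform(n_in, n_out, rng)
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = self._z = self._a = None

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        z = x @ self.W + self.b
        fn, _ = _ACTIVATIONS[self.activation]
        a = fn(z)
        if store:
            self._x, self._z, self._a = x, z, a
        return a

    def backward(self, grad_a: np.ndarray) -> np.ndarray:
        _, gfn = _ACTIVATIONS[self.activation]
        dz = grad_a * gfn(self._z, self._a)
        self.gW += self._x.T @ dz
        self.gb += dz.sum(axis=0)
        return dz @ self.W.T

    def zero_grad(self):
        self.gW[:] = 0.0
        self.gb[:] = 0.0

    @property
    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def categorical_crossentropy(probs: np.ndarray, y_onehot: np.ndarray,
                             sample_weight=None) -> float:
    """Mean (optionally sample-weighted) cross-entropy over the batch."""
    eps = 1e-12
    per = -np.sum(y_onehot * np.log(probs + eps), axis=1)
    if sample_weight is not None:
        per = per * sample_weight
    return float(per.mean())


class RMSProp:
    """RMSProp with the conventional defaults (lr 1e-3, rho 0.9)."""

    def __init__(self, layers, lr: float = 1e-3, rho: float = 0.9,
                 eps: float = 1e-7):
        self.layers, self.lr, self.rho, self.eps = layers, lr, rho, eps
        self._acc = [[np.zeros_like(p) for p, _ in l.params] for l in layers]

    def step(self):
        for layer, accs in zip(self.layers, self._acc):
            for (p, g), acc in zip(layer.params, accs):
                acc *= self.rho
                acc += (1.0 - self.rho) * g * g
                p -= self.lr * g / (np.sqrt(acc) + self.eps)


class Adadelta:
    """Adadelta with learning-rate scale `lr` and no lr decay.

    `lr` plays the role of the global step-size multiplier η (default 1.0,
    the canonical parameter-free setting); the lr-decay constant is 0.
    """

    def __init__(self, layers, lr: float = 1.0, rho: float = 0.95,
                 eps: float = 1e-7):
        self.layers, self.lr, self.rho, self.eps = layers, lr, rho, eps
        self._acc_g = [[np.zeros_like(p) for p, _ in l.params] for l in layers]
        self._acc_d = [[np.zeros_like(p) for p, _ in l.params] for l in layers]

    def step(self):
        for layer, accg, accd in zip(self.layers, self._acc_g, self._acc_d):
            for (p, g), ag, ad in zip(layer.params, accg, accd):
                ag *= self.rho
                ag += (1.0 - self.rho) * g * g
                delta = -np.sqrt(ad + self.eps) / np.sqrt(ag + self.eps) * g
                ad *= self.rho
                ad += (1.0 - self.rho) * delta * delta
                p += self.lr * delta
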