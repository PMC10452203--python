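"""Minimal dense-network primitives: layers with explicit backward passes,
fan-in uniform initialisation, and an Adam optimiser.

Layers cache their forward activations and consume them in ``backward``; a
training step is forward -> loss gradient -> backward -> ``Adam.step``. All
math is float64 numpy, which keeps numerical gradient checks tight at the
problem sizes involved (hundreds of samples, <10^5 weights at test scale).
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)


def fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """U(-1/sqrt(fan_in), 1/sqrt(fan_in)) init for weights and biases."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


class Linear(Module):
    """y = x W + b on the last axis."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Parameter(fan_in_uniform(rng, (n_in, n_out), n_in))
        self.b = Parameter(fan_in_uniform(rng, (n_out,), n_in))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return g @ self.W.data.T


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._scale: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        if training and self.p > 0:
            if rng is None:
                raise ValueError("training-mode dropout needs an rng")
            mask = rng.random(x.shape) >= self.p
            self._scale = mask / (1.0 - self.p)
            return x * self._scale
        self._scale = 1.0
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._scale


class LayerNorm(Module):
    """Normalisation over the last axis with trainable gain and bias."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma.data * self._xhat + self.beta.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        axes = tuple(range(g.ndim - 1))
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gx = g * self.gamma.data
        mean_gx = gx.mean(axis=-1, keepdims=True)
        mean_gx_xhat = (gx * xhat).mean(axis=-1, keepdims=True)
        return inv * (gx - mean_gx - xhat * mean_gx_xhat)


def softmax_last(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(A: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Gradient through a row-wise softmax with output A."""
    return A * (g - (g * A).sum(axis=-1, keepdims=True))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    y = np.asarray(y, dtype=float)
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    grad = (sigmoid(logits) - y) / logits.shape[0]
    return loss, grad


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 8e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * p.grad
            v[...] = self.b2 * v + (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
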