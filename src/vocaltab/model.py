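"""The Vocal Tab Transformer: per-feature continuous embedding, a stack of
self-attention encoder blocks, and an MLP classification head.

Each of the n selected vocal features is embedded by its *own* two-layer relu
network (scalar -> d/2 -> d); there is no weight sharing across features and
no positional encoding — feature identity is carried entirely by the
per-feature embedders. The n x d embedding matrix is contextualised by L
post-norm transformer encoder blocks (multi-head self-attention across
features, then a position-wise feed-forward net expanding d by a factor rho),
flattened, and mapped by a two-layer head to a single sigmoid probability of
Parkinson's disease.

A plain MLP over the raw feature vector (used as the depth-robustness
baseline) lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported for convenience)
    Dropout,
    LayerNorm,
    Linear,
    Module,
    Parameter,
    ReLU,
    fan_in_uniform,
    sigmoid,
    softmax_backward,
    softmax_last,
)


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the Vocal Tab Transformer.

    Defaults are the headline configuration: 96 selected features embedded to
    d=64, six encoder blocks with a single attention head and feed-forward
    expansion rho=32 (hidden width rho*d = 2048), and a 2048-wide head over
    the flattened 96x64 representation.
    """

    n_features: int = 96
    embed_dim: int = 64
    n_encoders: int = 6
    n_heads: int = 1
    rho: int = 32
    head_hidden: int = 2048
    dropout_p: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_features, self.embed_dim, self.n_heads, self.rho, self.head_hidden) < 1:
            raise ValueError("all size fields must be positive")
        if self.n_encoders < 0:
            raise ValueError("n_encoders must be >= 0")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.embed_dim % 2:
            raise ValueError("embed_dim must be even (embedder hidden width d/2)")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")


def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention: row-softmax(Q K^T / sqrt(k)) @ V."""
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    k = Q.shape[-1]
    if k == 0:
        raise ValueError("key/query dimension must be positive")
    A = softmax_last(Q @ np.swapaxes(K, -1, -2) / np.sqrt(k))
    return A @ V


class PerFeatureEmbedder(Module):
    """n independent scalar->d/2->d relu embedders (one per vocal feature)."""

    def __init__(self, n: int, d: int, p: float, rng: np.random.Generator):
        h = d // 2
        self.n, self.d, self.h = n, d, h
        # FC1: scalar input, fan-in 1; FC2: fan-in d/2
        self.W1 = Parameter(fan_in_uniform(rng, (n, h), 1))
        self.b1 = Parameter(fan_in_uniform(rng, (n, h), 1))
        self.W2 = Parameter(fan_in_uniform(rng, (n, h, d), h))
        self.b2 = Parameter(fan_in_uniform(rng, (n, d), h))
        self.drop = Dropout(p)

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        # x: (b, n) -> (b, n, d)
        self._x = x
        z1 = x[:, :, None] * self.W1.data + self.b1.data
        self._m1 = z1 > 0
        a1 = np.where(self._m1, z1, 0.0)
        self._a1 = a1
        z2 = np.einsum("bnh,nhd->bnd", a1, self.W2.data) + self.b2.data
        self._m2 = z2 > 0
        a2 = np.where(self._m2, z2, 0.0)
        return self.drop.forward(a2, training, rng)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.drop.backward(g)
        g2 = np.where(self._m2, g, 0.0)
        self.W2.grad += np.einsum("bnh,bnd->nhd", self._a1, g2)
        self.b2.grad += g2.sum(axis=0)
        g1 = np.einsum("bnd,nhd->bnh", g2, self.W2.data)
        g1 = np.where(self._m1, g1, 0.0)
        self.W1.grad += (self._x[:, :, None] * g1).sum(axis=0)
        self.b1.grad += g1.sum(axis=0)
        return (g1 * self.W1.data).sum(axis=-1)


class MultiHeadSelfAttention(Module):
    """h-head self-attention across the n feature embeddings (k = v = d/h)."""

    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        self.d, self.heads = d, heads
        self.dh = d // heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, n, _ = x.shape
        return x.reshape(b, n, self.heads, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, n, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, n, h * dh)

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(self.dh)
        A = softmax_last(scores)
        ctx = A @ v
        self._q, self._k, self._v, self._A = q, k, v, A
        return self.wo.forward(self._merge(ctx))

    def backward(self, g: np.ndarray) -> np.ndarray:
        g_ctx = self._split(self.wo.backward(g))
        gA = g_ctx @ np.swapaxes(self._v, -1, -2)
        gv = np.swapaxes(self._A, -1, -2) @ g_ctx
        gs = softmax_backward(self._A, gA) / np.sqrt(self.dh)
        gq = gs @ self._k
        gk = np.swapaxes(gs, -1, -2) @ self._q
        gx = self.wq.backward(self._merge(gq))
        gx = gx + self.wk.backward(self._merge(gk))
        gx = gx + self.wv.backward(self._merge(gv))
        return gx


class EncoderBlock(Module):
    """Post-norm transformer encoder: MHSA and rho-expanded feed-forward,
    each wrapped in dropout + residual + layer normalisation."""

    def __init__(self, d: int, heads: int, rho: int, p: float, rng: np.random.Generator):
        self.mhsa = MultiHeadSelfAttention(d, heads, rng)
        self.drop1 = Dropout(p)
        self.ln1 = LayerNorm(d)
        self.ff1 = Linear(d, rho * d, rng)
        self.relu = ReLU()
        self.ff2 = Linear(rho * d, d, rng)
        self.drop2 = Dropout(p)
        self.ln2 = LayerNorm(d)

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        a = self.drop1.forward(self.mhsa.forward(x), training, rng)
        x1 = self.ln1.forward(x + a)
        f = self.ff2.forward(self.relu.forward(self.ff1.forward(x1)))
        f = self.drop2.forward(f, training, rng)
        return self.ln2.forward(x1 + f)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.ln2.backward(g)
        gf = self.drop2.backward(g)
        gf = self.ff1.backward(self.relu.backward(self.ff2.backward(gf)))
        g1 = self.ln1.backward(g + gf)
        ga = self.drop1.backward(g1)
        return g1 + self.mhsa.backward(ga)


class MLPHead(Module):
    """Flatten the n x d representation and project via one hidden relu layer
    to a single logit."""

    def __init__(self, n: int, d: int, hidden: int, p: float, rng: np.random.Generator):
        self.n, self.d = n, d
        self.fc1 = Linear(n * d, hidden, rng)
        self.relu = ReLU()
        self.drop = Dropout(p)
        self.fc2 = Linear(hidden, 1, rng)

    def forward(self, e: np.ndarray, training: bool, rng) -> np.ndarray:
        b = e.shape[0]
        self._shape = e.shape
        h = self.fc1.forward(e.reshape(b, self.n * self.d))
        h = self.drop.forward(self.relu.forward(h), training, rng)
        return self.fc2.forward(h)[:, 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        gh = self.fc2.backward(g[:, None])
        gh = self.relu.backward(self.drop.backward(gh))
        return self.fc1.backward(gh).reshape(self._shape)


class VocalTabTransformer(Module):
    """Embed -> L encoder blocks -> head; outputs P(PD) per sample."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.embedder = PerFeatureEmbedder(c.n_features, c.embed_dim, c.dropout_p, rng)
        self.blocks = [
            EncoderBlock(c.embed_dim, c.n_heads, c.rho, c.dropout_p, rng)
            for _ in range(c.n_encoders)
        ]
        self.head = MLPHead(c.n_features, c.embed_dim, c.head_hidden, c.dropout_p, rng)

    def forward_logits(self, X: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.n_features:
            raise ValueError(
                f"expected batch of width {self.config.n_features}, got {X.shape}"
            )
        e = self.embedder.forward(X, training, rng)
        for blk in self.blocks:
            e = blk.forward(e, training, rng)
        return self.head.forward(e, training, rng)

    def forward(self, X: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        return sigmoid(self.forward_logits(X, training, rng))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = self.head.backward(dlogits)
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        return self.embedder.backward(g)


def count_parameters(config: ModelConfig) -> int:
    """Closed-form trainable-parameter count of :class:`VocalTabTransformer`.

    embedders: n * [(d/2 + d/2) + (d/2*d + d)]
    encoders:  L * [4*(d^2 + d) + (d*rho*d + rho*d) + (rho*d*d + d) + 2*(2d)]
    head:      (n*d*H + H) + (H + 1)
    """
    n, d, L, rho, H = (
        config.n_features,
        config.embed_dim,
        config.n_encoders,
        config.rho,
        config.head_hidden,
    )
    h = d // 2
    embed = n * ((h + h) + (h * d + d))
    enc = L * (4 * (d * d + d) + (d * rho * d + rho * d) + (rho * d * d + d) + 2 * (2 * d))
    head = (n * d * H + H) + (H + 1)
    return embed + enc + head


@dataclass
class MLPConfig:
    """Baseline MLP: hidden relu+dropout stacks, then a single-logit layer.

    The default widths (2048/1280/1024) give ~5.5M trainable parameters on a
    753-feature input. For the depth experiment the hidden stack is a repeated
    fixed-width block.
    """

    n_features: int = 753
    hidden: tuple = (2048, 1280, 1024)
    dropout_p: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden:
            raise ValueError("at least one hidden layer required")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")

    @classmethod
    def stacked(cls, n_features: int, width: int, n_blocks: int, **kw) -> "MLPConfig":
        return cls(n_features=n_features, hidden=(width,) * n_blocks, **kw)


class MLPNet(Module):
    """Plain feed-forward classifier over the raw (selected) feature vector."""

    def __init__(self, config: MLPConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = [config.n_features, *config.hidden]
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.relus = [ReLU() for _ in config.hidden]
        self.drops = [Dropout(config.dropout_p) for _ in config.hidden]
        self.out = Linear(widths[-1], 1, rng)

    def forward_logits(self, X: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        if h.ndim != 2 or h.shape[1] != self.config.n_features:
            raise ValueError(f"expected batch of width {self.config.n_features}")
        for lin, relu, drop in zip(self.layers, self.relus, self.drops):
            h = drop.forward(relu.forward(lin.forward(h)), training, rng)
        return self.out.forward(h)[:, 0]

    def forward(self, X: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        return sigmoid(self.forward_logits(X, training, rng))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = self.out.backward(dlogits[:, None])
        for lin, relu, drop in zip(
            reversed(self.layers), reversed(self.relus), reversed(self.drops)
        ):
            g = lin.backward(relu.backward(drop.backward(g)))
        return g
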