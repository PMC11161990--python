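"""Neural-network building blocks on top of the autograd core.

Layers follow the standard Transformer recipe (pre-activation residual
blocks are not used; this mirrors the post-norm layout of the original
architecture).  All parameters are float64 and initialised from an explicit
``numpy.random.Generator``, so training is reproducible bit-for-bit given a
seed.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .autograd import Tensor, concat, embedding_lookup

__all__ = [
    "Module", "Linear", "Embedding", "LayerNorm", "MLP", "Conv1d",
    "MultiHeadAttention", "TransformerEncoderLayer", "TransformerDecoderLayer",
    "Adam", "cross_entropy",
]


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(arrays):
            raise ValueError("parameter count mismatch in checkpoint")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch in checkpoint")
            p.data = np.asarray(a, dtype=np.float64)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 he: bool = False):
        super().__init__()
        if he:  # variance-preserving under a following ReLU
            self.weight = Tensor(rng.normal(0.0, math.sqrt(2.0 / in_dim),
                                            size=(in_dim, out_dim)),
                                 requires_grad=True)
        else:
            scale = math.sqrt(1.0 / in_dim)
            self.weight = Tensor(
                rng.uniform(-scale, scale, size=(in_dim, out_dim)),
                requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(n_embeddings, dim)),
                             requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2.0).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gain + self.bias


class Dropout(Module):
    """Inverted dropout driven by the module-level rng (eval: identity)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class MLP(Module):
    """Stack of linear layers with ReLU between them (not after the last)."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        super().__init__()
        self.layers = [Linear(dims[i], dims[i + 1], rng, he=True)
                       for i in range(len(dims) - 1)]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class Conv1d(Module):
    """Same-padded 1D convolution over (B, L, C) activations."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        scale = math.sqrt(1.0 / (in_channels * kernel))
        self.weight = Tensor(
            rng.uniform(-scale, scale, size=(kernel, in_channels, out_channels)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        half = self.kernel // 2
        L = x.shape[1]
        padded = x.pad_axis1(half, half)
        out = None
        for k in range(self.kernel):
            term = padded[:, k:k + L] @ self.weight[k]
            out = term if out is None else out + term
        return out + self.bias


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    B, L, E = x.shape
    return x.reshape(B, L, n_heads, E // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    B, H, L, D = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, L, H * D)


class MultiHeadAttention(Module):
    """Scaled dot-product attention; supports self- and cross-attention.

    ``mask`` is an additive float array broadcastable to (B, H, Lq, Lk)
    with 0 for allowed and a large negative number for blocked positions.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("embedding dim must be divisible by head count")
        self.n_heads = n_heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor,
                 mask: np.ndarray | None = None) -> Tensor:
        q = _split_heads(self.q_proj(query), self.n_heads)
        k = _split_heads(self.k_proj(key), self.n_heads)
        v = _split_heads(self.v_proj(value), self.n_heads)
        scores = (q @ k.swap_last()) * (1.0 / math.sqrt(q.shape[-1]))
        if mask is not None:
            scores = scores + Tensor(mask)
        attn = scores.softmax(axis=-1)
        return self.out_proj(_merge_heads(attn @ v))


class TransformerEncoderLayer(Module):
    def __init__(self, dim: int, n_heads: int, ff_dim: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff = MLP([dim, ff_dim, dim], rng)
        self.norm2 = LayerNorm(dim)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x, x, x, mask)))
        return self.norm2(x + self.drop(self.ff(x)))


class TransformerDecoderLayer(Module):
    def __init__(self, dim: int, n_heads: int, ff_dim: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.self_attn = MultiHeadAttention(dim, n_heads, rng)
        self.cross_attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.norm3 = LayerNorm(dim)
        self.ff = MLP([dim, ff_dim, dim], rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, memory: Tensor,
                 self_mask: np.ndarray | None = None) -> Tensor:
        x = self.norm1(x + self.drop(self.self_attn(x, x, x, self_mask)))
        x = self.norm2(x + self.drop(self.cross_attn(x, memory, memory)))
        return self.norm3(x + self.drop(self.ff(x)))


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  ignore_id: int | None = None) -> tuple[Tensor, float]:
    """Mean token cross-entropy and argmax accuracy.

    ``logits``: (..., V); ``targets``: integer array matching the leading
    shape.  Positions equal to ``ignore_id`` contribute to neither.
    """
    targets = np.asarray(targets)
    log_probs = logits.log_softmax(axis=-1)
    picked = log_probs.gather_last(targets)
    if ignore_id is None:
        mask = np.ones(targets.shape)
    else:
        mask = (targets != ignore_id).astype(float)
    count = max(mask.sum(), 1.0)
    loss = -(picked * Tensor(mask)).sum() * (1.0 / count)
    predictions = logits.data.argmax(axis=-1)
    accuracy = float(((predictions == targets) * mask).sum() / count)
    return loss, accuracy


class Adam:
    """Adam with the usual bias correction (the assumed optimizer family)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
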