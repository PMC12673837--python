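"""Neural-network building blocks on top of :mod:`dtifuse.autodiff`.

Layers follow the usual Module convention: parameters are registered
attributes, ``parameters()`` walks the tree, and stochastic layers (dropout)
take an explicit ``rng`` — passing ``rng=None`` runs them deterministically.
That explicit handle is what makes Monte-Carlo uncertainty passes and
bit-reproducible training possible without global RNG state.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, concat, gather_rows, relu, softmax

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "MLP",
    "Dropout",
    "Embedding",
    "LayerNorm",
    "MultiheadSelfAttention",
    "TransformerLayer",
    "sinusoidal_positions",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def parameters(self) -> Iterator[Parameter]:
        seen = set()
        for v in self.__dict__.values():
            if isinstance(v, Parameter) and id(v) not in seen:
                seen.add(id(v))
                yield v
            elif isinstance(v, Module):
                yield from v.parameters()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Parameter):
                        yield item
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Parameter):
                        yield item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = list(self.parameters())
        if len(params) != len(arrays):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


class Linear(Module):
    """Affine map ``x W + b`` with Glorot-uniform init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        bound = math.sqrt(6.0 / (d_in + d_out))
        self.W = Parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Dropout(Module):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        if rng is None or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class MLP(Module):
    """Stack of Linear+ReLU layers; final layer linear, optional dropout."""

    def __init__(self, dims: list[int], rng: np.random.Generator, dropout: float = 0.0,
                 final_activation: bool = False):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.dropout = Dropout(dropout)
        self.final_activation = final_activation

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            last = i == len(self.layers) - 1
            if not last or self.final_activation:
                x = relu(x)
                x = self.dropout(x, rng)
        return x


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        self.table = Parameter(rng.normal(0.0, 0.02, size=(n_vocab, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids)
        flat = gather_rows(self.table, ids.reshape(-1))
        return flat.reshape(*ids.shape, self.table.shape[1])


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Parameter(np.ones(dim))
        self.b = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.g + self.b


def sinusoidal_positions(n_pos: int, dim: int) -> np.ndarray:
    """Fixed sine/cosine positional table (interleaved by frequency)."""
    pos = np.arange(n_pos)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table


_NEG_INF = -1e30


class MultiheadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        """x: (B, L, D); key_mask: (B, L) bool, True where attendable."""
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (B, L, D) -> (B, H, L, dh)
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        if key_mask is not None:
            bias = np.where(key_mask[:, None, None, :], 0.0, _NEG_INF)
            scores = scores + Tensor(bias)
        attn = softmax(scores, axis=-1)
        out = attn @ v  # (B, H, L, dh)
        out = out.transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.wo(out)


class TransformerLayer(Module):
    """Post-norm transformer encoder block (attention + position-wise FFN)."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 d_ff: int | None = None, dropout: float = 0.0):
        d_ff = d_ff or 2 * d_model
        self.attn = MultiheadSelfAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.ln2 = LayerNorm(d_model)
        self.dropout = Dropout(dropout)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None,
                 rng: np.random.Generator | None = None) -> Tensor:
        x = self.ln1(x + self.dropout(self.attn(x, key_mask), rng))
        x = self.ln2(x + self.dropout(self.ff2(relu(self.ff1(x))), rng))
        return x


class Adam(Module):
    """Adam with optional L2 regularization added to the gradient.

    ``exclude_l2`` lists parameters whose L2 term is handled elsewhere
    (the task–modality relevance matrix carries its own explicit penalty,
    so it is excluded here to avoid double regularization).
    """

    def __init__(self, params: list[Parameter], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, exclude_l2: list[Parameter] | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._excluded = {id(p) for p in (exclude_l2 or [])}
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and id(p) not in self._excluded:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
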