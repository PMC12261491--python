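"""Neural-network layers, losses and the Adam optimizer on top of the autodiff engine."""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "MLP",
    "Embedding",
    "LayerNorm",
    "Dropout",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "TransformerEncoder",
    "Adam",
    "mse_loss",
    "bce_with_logits_loss",
]


class Module:
    """Base class: anything with learnable parameters, discoverable recursively."""

    training: bool = True

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

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.set_training(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(mode)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length does not match parameter count")
        for p, s in zip(params, state):
            p.data = s.copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / in_dim)  # He init, ReLU-friendly
        self.weight = Tensor(rng.normal(0.0, scale, size=(in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Dense stack with ReLU between layers; no activation after the last."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        if len(dims) < 2:
            raise ValueError("MLP needs at least an input and an output dimension")
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(n_tokens, dim)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight.take_rows(np.asarray(ids, dtype=np.int64))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centred * inv * self.gain + self.shift


class Dropout(Module):
    """Inverted dropout; identity when p == 0 or in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over (batch, seq, d_model) inputs.

    `pad_mask` marks padding positions (True = ignore); masked keys receive a
    large negative score before the softmax.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q_proj = Linear(d_model, d_model, rng)
        self.k_proj = Linear(d_model, d_model, rng)
        self.v_proj = Linear(d_model, d_model, rng)
        self.out_proj = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        b, L, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(b, L, h, dh).transpose((0, 2, 1, 3))  # (b, h, L, dh)

        q = split_heads(self.q_proj(x))
        k = split_heads(self.k_proj(x))
        v = split_heads(self.v_proj(x))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / math.sqrt(dh))  # (b, h, L, L)
        if pad_mask is not None:
            bias = np.where(pad_mask[:, None, None, :], -1e9, 0.0)
            scores = scores + Tensor(bias)
        attn = scores.softmax(axis=-1)
        out = attn @ v  # (b, h, L, dh)
        out = out.transpose((0, 2, 1, 3)).reshape(b, L, d)
        return self.out_proj(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: attention + residual, then feed-forward + residual."""

    def __init__(self, d_model: int, n_heads: int, ff_dim: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        self.attention = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ff_dim, rng)
        self.ff2 = Linear(ff_dim, d_model, rng)
        self.norm2 = LayerNorm(d_model)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        x = self.norm1(x + self.drop(self.attention(x, pad_mask)))
        x = self.norm2(x + self.drop(self.ff2(self.ff1(x).relu())))
        return x


class TransformerEncoder(Module):
    """Token + learned positional embeddings, a stack of encoder layers, and
    mean pooling over non-pad positions."""

    def __init__(
        self,
        vocab_size: int,
        d_model: int,
        n_layers: int,
        n_heads: int,
        ff_dim: int,
        max_len: int,
        rng: np.random.Generator,
        pad_id: int = 0,
        dropout: float = 0.0,
    ):
        self.token_embed = Embedding(vocab_size, d_model, rng)
        self.pos_embed = Embedding(max_len, d_model, rng)
        self.blocks = [
            TransformerEncoderLayer(d_model, n_heads, ff_dim, rng, dropout=dropout)
            for _ in range(n_layers)
        ]
        self.pad_id = pad_id
        self.max_len = max_len

    def __call__(self, token_ids: np.ndarray) -> Tensor:
        token_ids = np.asarray(token_ids, dtype=np.int64)
        b, L = token_ids.shape
        if L > self.max_len:
            raise ValueError(f"sequence length {L} exceeds max_len {self.max_len}")
        pad_mask = token_ids == self.pad_id
        x = self.token_embed(token_ids) + self.pos_embed(np.arange(L))
        for block in self.blocks:
            x = block(x, pad_mask)
        keep = (~pad_mask).astype(float)  # (b, L)
        counts = np.maximum(keep.sum(axis=1, keepdims=True), 1.0)
        pooled = (x * Tensor(keep[:, :, None])).sum(axis=1) * Tensor(1.0 / counts)
        return pooled  # (b, d_model)


class Adam:
    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean()


def bce_with_logits_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy on logits:
    max(x, 0) - x*z + log(1 + exp(-|x|))."""
    z = Tensor(np.asarray(target, dtype=float))
    per = logits.relu() - logits * z + (1.0 + (-logits.abs()).exp()).log()
    return per.mean()
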