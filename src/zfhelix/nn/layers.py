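"""Neural-network layers and the Adam optimizer.

Layers follow the original Transformer wiring: multi-head scaled dot-product
attention, position-wise feedforward blocks with ReLU, residual connections
with post-layer normalization, and dropout after every attention and
feedforward layer.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from zfhelix.nn.autograd import Tensor


class Module:
    """Base class with recursive parameter discovery and train/eval modes."""

    def __init__(self) -> None:
        self._training = True

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        """All parameter tensors, frozen ones included."""
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m._training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m._training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)[:5]} ...")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}"
                )
            p.data = state[name].copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_vocab: int, d_model: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            rng.standard_normal((n_vocab, d_model)) * 0.02, requires_grad=True
        )

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.weight.take_rows(indices)


class LayerNorm(Module):
    def __init__(self, d_model: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Tensor(np.ones(d_model), requires_grad=True)
        self.bias = Tensor(np.zeros(d_model), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps).pow(-0.5)
        return centered * inv * self.gain + self.bias


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self._training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.binomial(1, keep, size=x.shape) / keep
        return x * Tensor(mask)


class FeedForward(Module):
    """Position-wise feedforward: Linear -> ReLU -> Linear."""

    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        super().__init__()
        self.lin1 = Linear(d_model, d_ff, rng)
        self.lin2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``n_heads`` heads.

    Queries come from ``x_q`` and keys/values from ``x_kv`` (self-attention
    when they coincide).  Attention is full (bidirectional): masked residue
    prediction conditions on all positions, so no causal mask is used.
    """

    def __init__(self, d_model: int, n_heads: int, d_k: int, d_v: int, rng):
        super().__init__()
        self.n_heads = n_heads
        self.d_k = d_k
        self.d_v = d_v
        self.wq = Linear(d_model, n_heads * d_k, rng)
        self.wk = Linear(d_model, n_heads * d_k, rng)
        self.wv = Linear(d_model, n_heads * d_v, rng)
        self.wo = Linear(n_heads * d_v, d_model, rng)

    def _split(self, x: Tensor, d_head: int) -> Tensor:
        b, length = x.shape[0], x.shape[1]
        return x.reshape(b, length, self.n_heads, d_head).transpose(0, 2, 1, 3)

    def __call__(self, x_q: Tensor, x_kv: Tensor) -> Tensor:
        b, lq = x_q.shape[0], x_q.shape[1]
        q = self._split(self.wq(x_q), self.d_k)  # (B, H, Lq, dk)
        k = self._split(self.wk(x_kv), self.d_k)
        v = self._split(self.wv(x_kv), self.d_v)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_k))
        attn = scores.softmax()
        ctx = attn @ v  # (B, H, Lq, dv)
        merged = ctx.transpose(0, 2, 1, 3).reshape(b, lq, self.n_heads * self.d_v)
        return self.wo(merged)


class TransformerBlock(Module):
    """Residual attention block with post-layer-norm.

    With ``cross=True`` the block also attends to a memory sequence between
    the self-attention and feedforward sublayers (decoder wiring).
    """

    def __init__(
        self,
        d_model: int,
        n_heads: int,
        d_k: int,
        d_v: int,
        d_ff: int,
        dropout: float,
        rng: np.random.Generator,
        cross: bool = False,
    ):
        super().__init__()
        self.self_attn = MultiHeadAttention(d_model, n_heads, d_k, d_v, rng)
        self.norm1 = LayerNorm(d_model)
        self.cross_attn = (
            MultiHeadAttention(d_model, n_heads, d_k, d_v, rng) if cross else None
        )
        self.norm_cross = LayerNorm(d_model) if cross else None
        self.ff = FeedForward(d_model, d_ff, rng)
        self.norm2 = LayerNorm(d_model)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, memory: Tensor | None = None) -> Tensor:
        x = self.norm1(x + self.drop(self.self_attn(x, x)))
        if self.cross_attn is not None:
            if memory is None:
                raise ValueError("decoder block needs a memory sequence")
            x = self.norm_cross(x + self.drop(self.cross_attn(x, memory)))
        x = self.norm2(x + self.drop(self.ff(x)))
        return x


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
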