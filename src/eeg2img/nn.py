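"""Neural-network layers and an AdamW optimizer over the autodiff core.

The layer zoo is deliberately small: linear maps, layer normalization,
multi-head (self/cross) attention, dropout and GELU cover everything the
EEG encoder and the diffusion prior are assembled from.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._tensor import Tensor, concat, gelu, no_grad, softmax


class Module:
    """Base class with parameter discovery, train/eval mode and state dicts."""

    def __init__(self) -> None:
        self.training = True

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _set_mode(self, training: bool) -> None:
        self.training = training
        for value in vars(self).values():
            if isinstance(value, Module):
                value._set_mode(training)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._set_mode(training)

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = 1.0 / np.sqrt(d_in)
        self.weight = Tensor(rng.uniform(-scale, scale, size=(d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; draws masks from its own seeded generator."""

    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1): {p}")
        self.p = p
        self.rng = np.random.default_rng(seed)

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiheadAttention(Module):
    """Scaled dot-product attention; ``query is key`` gives self-attention."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"attention width {dim} not divisible by "
                             f"{n_heads} heads")
        self.dim, self.n_heads, self.d_head = dim, n_heads, dim // n_heads
        self.w_q = Linear(dim, dim, rng)
        self.w_k = Linear(dim, dim, rng)
        self.w_v = Linear(dim, dim, rng)
        self.w_o = Linear(dim, dim, rng)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        # (B, L, dim) -> (B, heads, L, d_head)
        return x.reshape(B, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor) -> Tensor:
        B, Lq, _ = query.shape
        Lk = key.shape[1]
        q = self._split(self.w_q(query), B, Lq)
        k = self._split(self.w_k(key), B, Lk)
        v = self._split(self.w_v(value), B, Lk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, Lq, self.dim)
        return self.w_o(out)


class TransformerBlock(Module):
    """Pre-norm self-attention + feed-forward block."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 ff_mult: int = 2):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_mult * dim, rng)
        self.ff2 = Linear(ff_mult * dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm1(x)
        x = x + self.attn(h, h, h)
        return x + self.ff2(gelu(self.ff1(self.norm2(x))))


class AdamW(Module):
    """AdamW with decoupled weight decay.

    Defaults follow the contrastive-training recipe used throughout the
    package: lr 2e-4, betas (0.5, 0.999).
    """

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        super().__init__()
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


__all__ = ["Module", "Linear", "LayerNorm", "Dropout", "MultiheadAttention",
           "TransformerBlock", "AdamW", "Tensor", "concat", "gelu", "no_grad",
           "softmax"]
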