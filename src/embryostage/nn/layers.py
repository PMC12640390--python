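"""Neural-network building blocks on top of the autograd core."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "ReLU",
    "Sequential",
    "GlobalAvgPool",
    "LayerNorm",
    "MultiheadSelfAttention",
    "TransformerEncoderLayer",
]


class Module:
    """Base class: recursive parameter discovery over attributes and lists."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_dim)
        self.weight = Tensor(rng.normal(0, scale, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.weight), self.bias)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
    ):
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0, scale, (out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


class GlobalAvgPool(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.mean(x, axis=(2, 3))


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gamma, self.beta)


class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads = dim, heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        bsz, tokens, dim = x.shape
        dh = dim // self.heads

        def split(t: Tensor) -> Tensor:
            t = ag.reshape(t, (bsz, tokens, self.heads, dh))
            return ag.transpose(t, (0, 2, 1, 3))  # (B, H, T, dh)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = ag.mul(ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
        attn = ag.softmax(scores, axis=-1)
        ctx = ag.matmul(attn, v)  # (B, H, T, dh)
        ctx = ag.transpose(ctx, (0, 2, 1, 3))
        ctx = ag.reshape(ctx, (bsz, tokens, dim))
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: self-attention and a 2x-width feed-forward."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.attn = MultiheadSelfAttention(dim, heads, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Linear(dim, 2 * dim, rng)
        self.ff2 = Linear(2 * dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = ag.add(x, self.attn(self.norm1(x)))
        return ag.add(x, self.ff2(ag.relu(self.ff1(self.norm2(x)))))
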