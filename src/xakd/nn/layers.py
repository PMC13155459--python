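"""Minimal layer library: Linear, LayerNorm, Conv2d, multi-head self-attention."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor, concat

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Conv2d",
    "MultiHeadSelfAttention",
    "TransformerBlock",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters are trainable even under no_grad


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter):
                        out.append(item)
                    elif isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict size mismatch")
        for i, p in enumerate(params):
            p.data[...] = state[str(i)]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class ChannelNorm(Module):
    """Group-norm with a single group: normalize each sample over (C,H,W),
    then apply a per-channel affine. Batch-size independent, so train and
    eval behave identically."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=(1, 2, 3), keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int, rng):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Parameter(rng.normal(0.0, scale, size=(c_out, c_in, k, k)))
        self.bias = Parameter(np.zeros(c_out))
        self.stride, self.pad = stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class MultiHeadSelfAttention(Module):
    """Standard full self-attention; optionally records the attention tensor."""

    def __init__(self, dim: int, n_heads: int, rng):
        if dim % n_heads:
            raise ValueError("embed dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.last_attention: np.ndarray | None = None  # (N, H, T, T) when captured

    def forward(self, x: Tensor, capture_attention: bool = False) -> Tensor:
        n, t, d = x.shape
        qkv = self.qkv(x).reshape(n, t, 3, self.n_heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, N, H, T, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        attn = F.softmax(scores, axis=-1)
        if capture_attention:
            self.last_attention = attn.data.copy()
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm encoder block: LN -> MHSA -> +, LN -> MLP -> +."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: int, rng):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, dim * mlp_ratio, rng)
        self.fc2 = Linear(dim * mlp_ratio, dim, rng)

    def forward(self, x: Tensor, capture_attention: bool = False) -> Tensor:
        x = x + self.attn(self.norm1(x), capture_attention=capture_attention)
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())
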