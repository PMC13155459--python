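"""Composite neural-net operations built on the autodiff Tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "softmax",
    "log_softmax",
    "cross_entropy",
    "conv2d",
    "avg_pool2d",
    "global_avg_pool",
]


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor._wrap(x)
    shifted = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift, no grad
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor._wrap(x)
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer `labels` under `logits`."""
    labels = np.asarray(labels)
    logp = log_softmax(logits, axis=-1)
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
    )
    return np.ascontiguousarray(cols).reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    out = np.zeros((n, c, hp, wp))
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[
                :, :, i, j
            ]
    return out[:, :, pad : pad + h, pad : pad + w] if pad else out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution. x: (N,C,H,W), weight: (O,C,kh,kw), bias: (O,)."""
    x = Tensor._wrap(x)
    o, c, kh, kw = weight.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)  # (N, C*kh*kw, oh*ow)
    wmat = weight.data.reshape(o, -1)
    out_data = np.einsum("ok,nkp->nop", wmat, cols, optimize=True).reshape(
        x.shape[0], o, oh, ow
    )
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gm = g.reshape(g.shape[0], o, oh * ow)
        gw = np.einsum("nop,nkp->ok", gm, cols, optimize=True).reshape(weight.shape)
        gcols = np.einsum("ok,nop->nkp", wmat, gm, optimize=True)
        gx = _col2im(gcols, x.shape, kh, kw, stride, pad)
        if bias is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return Tensor._from_op(out_data, parents, backward)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling; spatial dims must divide k."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
    return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    return x.mean(axis=(2, 3))
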