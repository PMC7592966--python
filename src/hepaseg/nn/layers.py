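"""Functional conv-net primitives with explicit forward/backward passes.

All tensors are NHWC float32 (channels last — the layout that keeps the
channel axis contiguous for BLAS).  3x3 convolutions are 'same' and are
computed as nine shifted matmuls, which avoids materialising an im2col
buffer; the transposed convolution is the 2x2 stride-2 upsampling used
by the U-Net expanding path.  Each forward returns ``(out, cache)`` and
the matching backward consumes ``cache``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d_forward",
    "conv2d_backward",
    "convt2_forward",
    "convt2_backward",
    "maxpool2_forward",
    "maxpool2_backward",
    "relu_forward",
    "relu_backward",
    "sigmoid",
    "dropout_forward",
    "dropout_backward",
    "Adam",
]


def conv2d_forward(x, w, b):
    """'same' 2D convolution; x (N,H,W,C), w (k,k,C,F) with odd k."""
    n, h, wd, c = x.shape
    k = w.shape[0]
    f = w.shape[3]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x
    acc = np.zeros((n * h * wd, f), dtype=np.result_type(x, w))
    for i in range(k):
        for j in range(k):
            sl = np.ascontiguousarray(xp[:, i : i + h, j : j + wd, :])
            acc += sl.reshape(-1, c) @ w[i, j]
    out = (acc + b).reshape(n, h, wd, f)
    return out, (xp, x.shape, w.shape)


def conv2d_backward(dout, cache, w):
    xp, xshape, wshape = cache
    n, h, wd, c = xshape
    k = wshape[0]
    f = wshape[3]
    pad = k // 2
    dout2 = dout.reshape(-1, f)
    dw = np.empty(wshape, dtype=np.result_type(dout, w))
    dxp = np.zeros(xp.shape, dtype=np.result_type(dout, w))
    for i in range(k):
        for j in range(k):
            sl = np.ascontiguousarray(xp[:, i : i + h, j : j + wd, :])
            dw[i, j] = sl.reshape(-1, c).T @ dout2
            dxp[:, i : i + h, j : j + wd, :] += (dout2 @ w[i, j].T).reshape(
                n, h, wd, c
            )
    db = dout2.sum(axis=0)
    dx = dxp[:, pad : pad + h, pad : pad + wd, :] if pad else dxp
    return dx, dw, db


def convt2_forward(x, w, b):
    """2x2 stride-2 transposed convolution; x (N,H,W,C), w (2,2,C,F)."""
    n, h, wd, c = x.shape
    f = w.shape[3]
    x2 = x.reshape(-1, c)
    y = np.empty((n, h, 2, wd, 2, f), dtype=np.result_type(x, w))
    for i in range(2):
        for j in range(2):
            y[:, :, i, :, j, :] = (x2 @ w[i, j]).reshape(n, h, wd, f)
    out = y.reshape(n, 2 * h, 2 * wd, f) + b
    return out, (x, w.shape)


def convt2_backward(dout, cache, w):
    x, wshape = cache
    n, h, wd, c = x.shape
    f = wshape[3]
    dy = dout.reshape(n, h, 2, wd, 2, f)
    x2 = x.reshape(-1, c)
    dx = np.zeros((n * h * wd, c), dtype=np.result_type(dout, w))
    dw = np.empty(wshape, dtype=np.result_type(dout, w))
    for i in range(2):
        for j in range(2):
            dij = np.ascontiguousarray(dy[:, :, i, :, j, :]).reshape(-1, f)
            dx += dij @ w[i, j].T
            dw[i, j] = x2.T @ dij
    db = dout.sum(axis=(0, 1, 2))
    return dx.reshape(x.shape), dw, db


def maxpool2_forward(x):
    n, h, wd, c = x.shape
    xr = (
        x.reshape(n, h // 2, 2, wd // 2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h // 2, wd // 2, c, 4)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2_backward(dout, cache):
    idx, xshape = cache
    n, h, wd, c = xshape
    dxr = np.zeros((n, h // 2, wd // 2, c, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return (
        dxr.reshape(n, h // 2, wd // 2, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, h, wd, c)
    )


def relu_forward(x):
    return np.maximum(x, 0.0), (x > 0)


def relu_backward(dout, cache):
    return dout * cache


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def dropout_forward(x, rate, rng, train):
    if not train or rate <= 0:
        return x, None
    keep = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return x * keep, keep


def dropout_backward(dout, cache):
    return dout if cache is None else dout * cache


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
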