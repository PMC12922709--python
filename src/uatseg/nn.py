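"""Minimal numpy neural-network kernels: convolution, pooling, Adam.

A deliberately small, dependency-free forward/backward engine sufficient for
the desk-scale U-Net fixture. Convolutions use an im2col formulation (9
strided slices + one matmul for a 3x3 kernel); pooling is 2x2 average,
upsampling is nearest-neighbour. All arrays are float64 NCHW.

Gradients are exact analytic derivatives, verified against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv_forward",
    "conv_backward",
    "avgpool2_forward",
    "avgpool2_backward",
    "upsample2_forward",
    "upsample2_backward",
    "relu_forward",
    "relu_backward",
    "sigmoid",
    "Adam",
]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patches for 'same' convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
    return cols.reshape(n, c * k * k, h * w)


def conv_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """Same-padding 2D convolution.

    x: (N, C, H, W); weight: (K, C, k, k) with k odd; bias: (K,).
    Returns (y, cache) with y of shape (N, K, H, W).
    """
    n, c, h, w = x.shape
    kk, cc, k, _ = weight.shape
    cols = _im2col(x, k, k // 2)
    wmat = weight.reshape(kk, cc * k * k)
    y = np.matmul(wmat, cols) + bias[:, None]
    return y.reshape(n, kk, h, w), (x.shape, cols, weight)


def conv_backward(dy: np.ndarray, cache):
    x_shape, cols, weight = cache
    n, c, h, w = x_shape
    kk = weight.shape[0]
    k = weight.shape[2]
    pad = k // 2
    dyf = dy.reshape(n, kk, h * w)
    dw = np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0).reshape(weight.shape)
    db = dyf.sum(axis=(0, 2))
    wmat = weight.reshape(kk, c * k * k)
    dcols = np.matmul(wmat.T, dyf).reshape(n, c, k, k, h, w)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dy.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
    dx = dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp
    return dx, dw, db


def avgpool2_forward(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def avgpool2_backward(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dy * mask


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to the
    gradient (the convention of the reference deep-learning optimisers)."""

    def __init__(self, params: dict, lr: float = 1e-3, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p in self.params.items():
            g = grads[key]
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
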