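"""Minimal NumPy convolutional-network primitives with backpropagation.

Only what the models here need: strided 2-D convolution (im2col), ReLU,
max pooling with ceil-mode boundary clipping, a fully connected layer,
softmax cross-entropy, and Adam.  All computation is float32 and fully
deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "Linear",
    "Adam",
    "softmax_cross_entropy",
    "conv_out_size",
    "pool_out_size",
]


def conv_out_size(n: int, kernel: int, stride: int, pad: int) -> int:
    out = (n + 2 * pad - kernel) // stride + 1
    if out < 1:
        raise ValueError(
            f"conv collapses a {n}-px map (kernel {kernel}, stride {stride}, pad {pad})"
        )
    return out


def pool_out_size(n: int, kernel: int, stride: int) -> int:
    # ceil mode with windows clipped at the border; never below 1x1
    return max(1, int(np.ceil((n - kernel) / stride)) + 1)


class Conv2d:
    """2-D convolution via im2col.  Input/output layout: (B, C, H, W).

    Bias-free by default so that zero (background) input yields exactly zero
    output through the whole rectified stack; a stimulus then contributes
    nothing to any scale channel that does not see it.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, pad: int,
                 rng: np.random.Generator, bias: bool = False):
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.has_bias = bias
        fan_in = c_in * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        pairs = [(self.W, self.dW)]
        if self.has_bias:
            pairs.append((self.b, self.db))
        return pairs

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, Wd = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        k, s, p = self.kernel, self.stride, self.pad
        ho = conv_out_size(H, k, s, p)
        wo = conv_out_size(Wd, k, s, p)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (B, C, ho, wo, k, k) -> (B*ho*wo, C*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * ho * wo, C * k * k
        )
        out = cols @ self.W.T + self.b
        if train:
            self._cache = (cols, x.shape, (ho, wo))
        return out.reshape(B, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, (ho, wo) = self._cache
        B, C, H, Wd = xshape
        k, s, p = self.kernel, self.stride, self.pad
        d2 = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.dW += d2.T @ cols
        self.db += d2.sum(axis=0)
        dcols = (d2 @ self.W).reshape(B, ho, wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, C, H + 2 * p, Wd + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[..., ki, kj]
        return dxp[:, :, p : p + H, p : p + Wd] if p else dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d:
    """Max pooling, ceil mode: border windows are clipped rather than dropped."""

    def __init__(self, kernel: int, stride: int):
        self.kernel, self.stride = kernel, stride
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, Wd = x.shape
        k, s = self.kernel, self.stride
        ho, wo = pool_out_size(H, k, s), pool_out_size(Wd, k, s)
        ph, pw = (ho - 1) * s + k - H, (wo - 1) * s + k - Wd
        xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(B, C, ho, wo, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, x.shape, (ho, wo), (H + ph, Wd + pw))
        return np.ascontiguousarray(out.astype(np.float32))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, (B, C, H, Wd), (ho, wo), (Hp, Wp) = self._cache
        k, s = self.kernel, self.stride
        rows = arg // k + np.arange(ho)[None, None, :, None] * s
        cols = arg % k + np.arange(wo)[None, None, None, :] * s
        dxp = np.zeros((B, C, Hp, Wp), dtype=np.float32)
        b_idx = np.arange(B)[:, None, None, None]
        c_idx = np.arange(C)[None, :, None, None]
        np.add.at(dxp, (b_idx, c_idx, rows, cols), dout)
        return dxp[:, :, :H, :Wd]


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in),
                            size=(d_out, d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW += dout.T @ self._x
        self.db += dout.sum(axis=0)
        return dout @ self.W


def softmax_cross_entropy(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. scores."""
    z = scores - scores.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = scores.shape[0]
    loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
    dscores = probs.copy()
    dscores[np.arange(n), y] -= 1.0
    return loss, (dscores / n).astype(np.float32)


class Adam:
    def __init__(self, param_grad_pairs, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = list(param_grad_pairs)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def zero_grad(self) -> None:
        for _, g in self.pairs:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
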