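"""Minimal CNN layer zoo with explicit backpropagation.

Each layer owns ``params`` and matching ``grads`` dicts and implements
``forward(x, train)`` / ``backward(dout)``.  Convolutions use im2col +
BLAS matmul; col2im accumulates over the k*k kernel taps with strided
slice additions, so there are no per-pixel Python loops anywhere.
Arrays are NCHW float32 by default (float64 is supported for gradient
checking).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    b, c, ho, wo, _, _ = win.shape
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(b, c * k * k, ho * wo)
    return cols, ho, wo


def _col2im(dcols, xshape, k, stride, pad, ho, wo):
    b, c, h, w = xshape
    dc = dcols.reshape(b, c, k, k, ho, wo)
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += dc[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp


class Layer:
    """Base: parameterless layers inherit empty params/grads."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    """k x k convolution, 'same' padding, He-normal init."""

    def __init__(self, cin, cout, k=3, stride=1, bias=True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2
        std = np.sqrt(2.0 / (cin * k * k))
        self.params["w"] = rng.normal(0, std, (cout, cin, k, k)).astype(dtype)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.bias = bias
        if bias:
            self.params["b"] = np.zeros(cout, dtype=dtype)
            self.grads["b"] = np.zeros_like(self.params["b"])

    def forward(self, x, train=True):
        self._xshape = x.shape
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._howo = cols, (ho, wo)
        w = self.params["w"].reshape(self.cout, -1)
        y = np.matmul(w, cols)
        if self.bias:
            y += self.params["b"][None, :, None]
        return y.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, dout):
        b = dout.shape[0]
        ho, wo = self._howo
        dflat = dout.reshape(b, self.cout, ho * wo)
        dw = np.matmul(dflat, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["w"] += dw.reshape(self.params["w"].shape)
        if self.bias:
            self.grads["b"] += dflat.sum(axis=(0, 2))
        w = self.params["w"].reshape(self.cout, -1)
        dcols = np.matmul(w.T, dflat)
        return _col2im(dcols, self._xshape, self.k, self.stride, self.pad, ho, wo)


class DepthwiseConv2d(Layer):
    """Per-channel k x k convolution (the spatial tap of an MBConv block)."""

    def __init__(self, c, k=3, stride=1, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c, self.k, self.stride = c, k, stride
        self.pad = k // 2
        std = np.sqrt(2.0 / (k * k))
        self.params["w"] = rng.normal(0, std, (c, k, k)).astype(dtype)
        self.grads["w"] = np.zeros_like(self.params["w"])

    def forward(self, x, train=True):
        self._xshape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))[:, :, ::self.stride, ::self.stride]
        self._win = win
        return np.einsum("bchwij,cij->bchw", win, self.params["w"], optimize=True)

    def backward(self, dout):
        self.grads["w"] += np.einsum("bchw,bchwij->cij", dout, self._win, optimize=True)
        b, c, h, w = self._xshape
        ho, wo = dout.shape[2:]
        dxp = np.zeros((b, c, h + 2 * self.pad, w + 2 * self.pad), dtype=dout.dtype)
        wgt = self.params["w"]
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + self.stride * ho:self.stride,
                    j:j + self.stride * wo:self.stride] += dout * wgt[None, :, i, j, None, None]
        return dxp[:, :, self.pad:self.pad + h, self.pad:self.pad + w] if self.pad else dxp


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.99, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.grads["gamma"] = np.zeros_like(self.params["gamma"])
        self.grads["beta"] = np.zeros_like(self.params["beta"])
        self.buffers["running_mean"] = np.zeros(c, dtype=dtype)
        self.buffers["running_var"] = np.ones(c, dtype=dtype)

    def forward(self, x, train=True):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["running_mean"] = (m * self.buffers["running_mean"]
                                            + (1 - m) * mu).astype(x.dtype)
            self.buffers["running_var"] = (m * self.buffers["running_var"]
                                           + (1 - m) * var).astype(x.dtype)
        else:
            mu = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar) if train else None
        return self.params["gamma"][None, :, None, None] * xhat \
            + self.params["beta"][None, :, None, None]

    def backward(self, dout):
        xhat, ivar = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.params["gamma"][None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (ivar[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class ReLU6(Layer):
    def forward(self, x, train=True):
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0, 6)

    def backward(self, dout):
        return dout * self._mask


class Upsample2x(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        b, c, h, w = dout.shape
        return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam with the training schedule's constants (eps defaults to 1e-7)."""

    def __init__(self, items, lr=5e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.items = list(items)  # (layer, param key)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(l.params[k]) for l, k in self.items]
        self.v = [np.zeros_like(l.params[k]) for l, k in self.items]
        self.t = 0

    def zero_grad(self):
        for layer, _ in self.items:
            layer.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, (layer, key) in enumerate(self.items):
            g = layer.grads[key]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            layer.params[key] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                layer.params[key].dtype)
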