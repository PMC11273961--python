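"""Layers with explicit forward/backward passes.

Convolutions use im2col + GEMM; the col2im scatter in the backward pass is a
short python loop over the kernel taps, which vectorises well for 3x3/4x4
kernels. Weight init is He-normal from a caller-supplied generator so that a
fixed seed reproduces parameters bit for bit.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base class: parameter/grad/buffer dictionaries keyed by short names."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, OH*OW, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - k) // stride + 1
    ow = (x.shape[3] - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N,C,OH,OW,k,k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int,
            oh: int, ow: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + stride * oh:stride, kj:kj + stride * ow:stride] += d[..., ki, kj]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = k // 2 if pad is None else pad
        fan_in = in_ch * k * k
        self.W = (rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._cache = None

    def params(self):
        p = {"W": self.W}
        if self.b is not None:
            p["b"] = self.b
        return p

    def grads(self):
        g = {"W": self.dW}
        if self.b is not None:
            g["b"] = self.db
        return g

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=F32)
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        out = cols @ self.W.T  # (N, OH*OW, out_ch)
        if self.b is not None:
            out += self.b
        self._cache = (x.shape, cols, oh, ow)
        n = x.shape[0]
        return out.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        x_shape, cols, oh, ow = self._cache
        n = x_shape[0]
        d = np.ascontiguousarray(dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_ch),
                                 dtype=F32)
        flat_cols = cols.reshape(n * oh * ow, -1)
        self.dW += d.T @ flat_cols
        if self.b is not None:
            self.db += d.sum(axis=0)
        dcols = (d @ self.W).reshape(n, oh * ow, -1)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, oh, ow)


class ConvTranspose2d(Layer):
    """Stride-2 learnable upsampling (kernel 4, pad 1 doubles spatial size)."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride, self.pad = in_ch, out_ch, k, stride, pad
        fan_in = in_ch * k * k / (stride * stride)
        self.W = (rng.standard_normal((in_ch, out_ch, k, k)) * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def out_size(self, h: int) -> int:
        return (h - 1) * self.stride - 2 * self.pad + self.k

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=F32)
        n, c, h, w = x.shape
        oh, ow = self.out_size(h), self.out_size(w)
        p = self.pad
        ypad = np.zeros((n, self.out_ch, oh + 2 * p, ow + 2 * p), dtype=F32)
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                tap = np.tensordot(x, self.W[:, :, ki, kj], axes=([1], [0]))  # (N,H,W,out)
                ypad[:, :, ki:ki + s * h:s, kj:kj + s * w:s] += tap.transpose(0, 3, 1, 2)
        y = ypad[:, :, p:p + oh, p:p + ow] if p else ypad
        y += self.b[None, :, None, None]
        self._cache = (x, oh, ow)
        return y

    def backward(self, dout):
        x, oh, ow = self._cache
        n, c, h, w = x.shape
        p, s = self.pad, self.stride
        dpad = np.zeros((n, self.out_ch, oh + 2 * p, ow + 2 * p), dtype=F32)
        dpad[:, :, p:p + oh, p:p + ow] = dout
        self.db += dout.sum(axis=(0, 2, 3))
        dx = np.zeros_like(x)
        for ki in range(self.k):
            for kj in range(self.k):
                dtap = dpad[:, :, ki:ki + s * h:s, kj:kj + s * w:s]  # (N,out,H,W)
                self.dW[:, :, ki, kj] += np.einsum("nihw,nohw->io", x, dtap, optimize=True)
                dx += np.tensordot(dtap, self.W[:, :, ki, kj], axes=([1], [1])
                                   ).transpose(0, 3, 1, 2)
        return dx


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=F32)
        self.beta = np.zeros(ch, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=F32)
        self.running_var = np.ones(ch, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return (self.gamma[None, :, None, None] * xhat
                + self.beta[None, :, None, None])

    def backward(self, dout):
        xhat, inv, training, shape = self._cache
        self.dgamma += (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        if not training:
            return dout * g
        dxhat = dout * self.gamma[None, :, None, None]
        term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return term * inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((out_f, in_f)) * np.sqrt(2.0 / in_f)).astype(F32)
        self.b = np.zeros(out_f, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False):
        self._x = np.ascontiguousarray(x, dtype=F32)
        return self._x @ self.W.T + self.b

    def backward(self, dout):
        dout = np.ascontiguousarray(dout, dtype=F32)
        self.dW += dout.T @ self._x
        self.db += dout.sum(axis=0)
        return dout @ self.W


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return {f"{i}.{k}": v for i, l in enumerate(self.layers)
                for k, v in l.params().items()}

    def grads(self):
        return {f"{i}.{k}": v for i, l in enumerate(self.layers)
                for k, v in l.grads().items()}

    def buffers(self):
        return {f"{i}.{k}": v for i, l in enumerate(self.layers)
                for k, v in l.buffers().items()}

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


def upsample2x_nearest(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2x_nearest_backward(dout: np.ndarray) -> np.ndarray:
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
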