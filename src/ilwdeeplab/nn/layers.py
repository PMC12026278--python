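"""Primitive layers: convolutions, batch norm, activations, pooling, resizing.

Convolutions dispatch on structure: pointwise (1x1) runs as a tensordot,
depthwise as a shift-and-accumulate over kernel taps (cheap for the 3x3/5x5
kernels used here), and the general dense case through im2col. This covers the
three convolution shapes the architecture uses (stem, depthwise, pointwise)
plus the small dense gates of the attention blocks.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Parameter


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 dilation: int = 1, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if cin % groups or cout % groups:
            raise ValueError("channels must divide groups")
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.dilation, self.groups = stride, dilation, groups
        # 'same'-style symmetric padding: output spatial = ceil(in/stride)
        self.pad = dilation * (k - 1) // 2
        rng = rng or np.random.default_rng(0)
        fan_in = (cin // groups) * k * k
        self.weight = Parameter(
            he_normal(rng, (cout, cin // groups, k, k), fan_in))
        self.bias = Parameter(np.zeros(cout, np.float32)) if bias else None
        self._cache = None

    # -- helpers -------------------------------------------------------------
    def _dw_slices(self, i: int, j: int, ho: int, wo: int):
        d, s = self.dilation, self.stride
        return (slice(i * d, i * d + s * (ho - 1) + 1, s),
                slice(j * d, j * d + s * (wo - 1) + 1, s))

    def forward(self, x, training: bool = False):
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        s, k, p = self.stride, self.k, self.pad
        ho = (h + 2 * p - self.dilation * (k - 1) - 1) // s + 1
        wo = (w + 2 * p - self.dilation * (k - 1) - 1) // s + 1
        W = self.weight.data
        if k == 1 and self.groups == 1:
            xs = x[:, :, ::s, ::s] if s > 1 else x
            out = np.tensordot(xs, W[:, :, 0, 0], axes=([1], [1]))
            out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
            mode = ("pw", xs if training else None)
        elif self.groups == self.cin and self.cin == self.cout:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
            out = np.zeros((n, c, ho, wo), np.float32)
            for i in range(k):
                for j in range(k):
                    hs, ws = self._dw_slices(i, j, ho, wo)
                    out += W[:, 0, i, j][None, :, None, None] * xp[:, :, hs, ws]
            mode = ("dw", xp if training else None)
        elif self.groups == 1:
            if self.dilation != 1:
                raise NotImplementedError("dense dilated conv not needed here")
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
            win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
            cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
            out = cols @ W.reshape(self.cout, -1).T
            out = np.ascontiguousarray(
                out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2))
            mode = ("im2col", (cols, xp.shape) if training else None)
        else:
            raise NotImplementedError("grouped (non-depthwise) conv unused")
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        if training:
            self._cache = (mode, x.shape, (ho, wo))
        return out

    def backward(self, grad):
        (kind, saved), xshape, (ho, wo) = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        W = self.weight.data
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        if kind == "pw":
            xs = saved
            self.weight.grad[:, :, 0, 0] += np.tensordot(
                grad, xs, axes=([0, 2, 3], [0, 2, 3]))
            gx = np.tensordot(grad, W[:, :, 0, 0], axes=([1], [0]))
            gx = np.ascontiguousarray(gx.transpose(0, 3, 1, 2))
            if s > 1:
                full = np.zeros(xshape, np.float32)
                full[:, :, ::s, ::s] = gx
                gx = full
            return gx
        if kind == "dw":
            xp = saved
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    hs, ws = self._dw_slices(i, j, ho, wo)
                    patch = xp[:, :, hs, ws]
                    self.weight.grad[:, 0, i, j] += (grad * patch).sum(
                        axis=(0, 2, 3))
                    gxp[:, :, hs, ws] += W[:, 0, i, j][None, :, None, None] * grad
            return gxp[:, :, p:p + h, p:p + w] if p else gxp
        # im2col
        cols, xpshape = saved
        gmat = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.weight.grad += (gmat.T @ cols).reshape(W.shape)
        gcols = (gmat @ W.reshape(self.cout, -1)).reshape(n, ho, wo, c, k, k)
        gxp = np.zeros(xpshape, np.float32)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + s * (ho - 1) + 1:s, j:j + s * (wo - 1) + 1:s] += \
                    gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return gxp[:, :, p:p + h, p:p + w] if p else gxp


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Parameter(np.ones(c, np.float32))
        self.beta = Parameter(np.zeros(c, np.float32))
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self._cache = None

    def forward(self, x, training: bool = False):
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + \
            self.beta.data[None, :, None, None]

    def backward(self, grad):
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        gsum = grad.sum(axis=(0, 2, 3))
        gxhat_sum = (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gsum
        self.gamma.grad += gxhat_sum
        coef = (self.gamma.data * inv / m)[None, :, None, None]
        return coef * (m * grad - gsum[None, :, None, None]
                       - xhat * gxhat_sum[None, :, None, None])


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x, training: bool = False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class SiLU(Module):
    """x * sigmoid(x) — the EfficientNet activation."""

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x, training: bool = False):
        sig = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._cache = (x, sig)
        return x * sig

    def backward(self, grad):
        x, sig = self._cache
        return grad * (sig * (1.0 + x * (1.0 - sig)))


class Sigmoid(Module):
    def __init__(self):
        super().__init__()
        self._out = None

    def forward(self, x, training: bool = False):
        out = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class GlobalAvgPool(Module):
    """N,C,H,W -> N,C,1,1."""

    def __init__(self):
        super().__init__()
        self._hw = None

    def forward(self, x, training: bool = False):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3), keepdims=True)

    def backward(self, grad):
        h, w = self._hw
        return np.broadcast_to(grad / (h * w), grad.shape[:2] + (h, w)).copy()


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel centres)."""
    A = np.zeros((n_out, n_in), np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        t = src - i0
        A[i, i0] += 1.0 - t
        A[i, i1] += t
    return A


class BilinearResize(Module):
    """Bilinear up/down-sampling by an integer scale factor (corner-aligned off)."""

    def __init__(self, scale: int):
        super().__init__()
        self.scale = scale
        self._mats: dict[tuple[int, int], np.ndarray] = {}
        self._shape = None

    def _mat(self, n_in: int) -> np.ndarray:
        key = (n_in, n_in * self.scale)
        if key not in self._mats:
            self._mats[key] = _resize_matrix(n_in, n_in * self.scale)
        return self._mats[key]

    def forward(self, x, training: bool = False):
        n, c, h, w = x.shape
        A, B = self._mat(h), self._mat(w)
        out = np.einsum("oh,nchw,pw->ncop", A, x, B, optimize=True)
        if training:
            self._shape = x.shape
        return np.ascontiguousarray(out)

    def backward(self, grad):
        n, c, h, w = self._shape
        A, B = self._mat(h), self._mat(w)
        gx = np.einsum("oh,ncop,pw->nchw", A, grad, B, optimize=True)
        return np.ascontiguousarray(gx)


class Identity(Module):
    def forward(self, x, training: bool = False):
        return x

    def backward(self, grad):
        return grad
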