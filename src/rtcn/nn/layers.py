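"""Dense, convolutional, normalization and pooling layers with hand-derived
backward passes.  2-D convolutions use im2col/col2im so the heavy lifting is a
single matrix multiply per layer."""
from __future__ import annotations

import numpy as np

from .core import Module, Parameter


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _out_size(n, k, stride, pad):
    return (n + 2 * pad - k) // stride + 1


def im2col(x, kh, kw, stride, pad, pad_value=0.0):
    """(N, C, H, W) -> (N, C*kh*kw, OH*OW) patch matrix."""
    n, c, h, w = x.shape
    oh, ow = _out_size(h, kh, stride, pad), _out_size(w, kw, stride, pad)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                   constant_values=pad_value)
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride,
                                 j : j + stride * ow : stride]
    return cols.reshape(n, c * kh * kw, oh * ow), (oh, ow)


def col2im(cols, x_shape, kh, kw, stride, pad):
    """Adjoint of :func:`im2col`: scatter-add patches back to (N, C, H, W)."""
    n, c, h, w = x_shape
    oh, ow = _out_size(h, kh, stride, pad), _out_size(w, kw, stride, pad)
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * oh : stride,
               j : j + stride * ow : stride] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Linear(Module):
    def __init__(self, d_in, d_out, rng, bias=True, init_std=None):
        super().__init__()
        std = init_std if init_std is not None else np.sqrt(1.0 / d_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x):
        self._x = x
        y = x @ self.weight.value
        if self.bias is not None:
            y = y + self.bias.value
        return y

    def backward(self, g):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.weight.grad += x2.T @ g2
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=0)
        return g @ self.weight.value.T


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p, rng):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x):
        if not self.training or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, rng, stride=1, pad=0, bias=False):
        super().__init__()
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_out = c_out * kernel * kernel
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_out), size=(c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x):
        self._x_shape = x.shape
        cols, (oh, ow) = im2col(x, self.k, self.k, self.stride, self.pad)
        self._cols = cols
        w2 = self.weight.value.reshape(self.weight.shape[0], -1)
        y = np.einsum("of,nfl->nol", w2, cols, optimize=True)
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        return y.reshape(x.shape[0], -1, oh, ow)

    def backward(self, g):
        n, co, oh, ow = g.shape
        g2 = g.reshape(n, co, oh * ow)
        self.weight.grad += np.einsum("nol,nfl->of", g2, self._cols,
                                      optimize=True).reshape(self.weight.shape)
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=(0, 2))
        w2 = self.weight.value.reshape(co, -1)
        dcols = np.einsum("of,nol->nfl", w2, g2, optimize=True)
        return col2im(dcols, self._x_shape, self.k, self.k, self.stride, self.pad)


class Conv1d(Module):
    """1-D convolution (same padding optional) for the diffusion denoiser."""

    def __init__(self, c_in, c_out, kernel, rng, pad=None, bias=True):
        super().__init__()
        self.k = kernel
        self.pad = (kernel // 2) if pad is None else pad
        fan_out = c_out * kernel
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_out), size=(c_out, c_in, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x):  # x: (N, C, L)
        x4 = x[:, :, None, :]
        self._x_shape = x4.shape
        cols, (_, ol) = im2col(x4, 1, self.k, 1, 0) if self.pad == 0 else \
            im2col(np.pad(x4, ((0, 0), (0, 0), (0, 0), (self.pad, self.pad))),
                   1, self.k, 1, 0)
        self._cols = cols
        w2 = self.weight.value.reshape(self.weight.shape[0], -1)
        y = np.einsum("of,nfl->nol", w2, cols, optimize=True)
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        return y

    def backward(self, g):  # g: (N, C_out, L_out)
        n, co, ol = g.shape
        self.weight.grad += np.einsum("nol,nfl->of", g, self._cols,
                                      optimize=True).reshape(self.weight.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2))
        w2 = self.weight.value.reshape(co, -1)
        dcols = np.einsum("of,nol->nfl", w2, g, optimize=True)
        padded_shape = (self._x_shape[0], self._x_shape[1], 1,
                        self._x_shape[3] + 2 * self.pad)
        dxp = col2im(dcols, padded_shape, 1, self.k, 1, 0)
        dx = dxp[:, :, 0, :]
        if self.pad:
            dx = dx[:, :, self.pad : -self.pad]
        return dx


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x):
        axes = (0, 2, 3)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._train_stats = True
        else:
            mean, var = self.running_mean, self.running_var
            self._train_stats = False
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return self.gamma.value[None, :, None, None] * self._xhat + \
            self.beta.value[None, :, None, None]

    def backward(self, g):
        axes = (0, 2, 3)
        self.gamma.grad += (g * self._xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gs = self.gamma.value[None, :, None, None] / self._std[None, :, None, None]
        if not self._train_stats:
            return g * gs
        m = g.shape[0] * g.shape[2] * g.shape[3]
        dmean = g.mean(axis=axes)[None, :, None, None]
        dproj = (g * self._xhat).mean(axis=axes)[None, :, None, None]
        return gs * (g - dmean - self._xhat * dproj)


class LayerNorm(Module):
    """Normalization over the last axis with affine parameters."""

    def __init__(self, d, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def forward(self, x):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, g):
        red = tuple(range(g.ndim - 1))
        self.gamma.grad += (g * self._xhat).sum(axis=red)
        self.beta.grad += g.sum(axis=red)
        gh = g * self.gamma.value
        dmean = gh.mean(axis=-1, keepdims=True)
        dproj = (gh * self._xhat).mean(axis=-1, keepdims=True)
        return (gh - dmean - self._xhat * dproj) / self._std


class MaxPool2d(Module):
    def __init__(self, kernel=3, stride=2, pad=1):
        super().__init__()
        self.k, self.stride, self.pad = kernel, stride, pad

    def forward(self, x):
        n, c, h, w = x.shape
        self._x_shape = x.shape
        folded = x.reshape(n * c, 1, h, w)
        cols, (oh, ow) = im2col(folded, self.k, self.k, self.stride, self.pad,
                                pad_value=-np.inf)
        self._argmax = np.argmax(cols, axis=1)
        self._cols_shape = cols.shape
        y = np.take_along_axis(cols, self._argmax[:, None, :], axis=1)[:, 0, :]
        self._oh, self._ow = oh, ow
        return y.reshape(n, c, oh, ow)

    def backward(self, g):
        n, c, oh, ow = g.shape
        dcols = np.zeros(self._cols_shape)
        g2 = g.reshape(n * c, oh * ow)
        np.put_along_axis(dcols, self._argmax[:, None, :], g2[:, None, :], axis=1)
        dx = col2im(dcols, (n * c, 1, self._x_shape[2], self._x_shape[3]),
                    self.k, self.k, self.stride, self.pad)
        return dx.reshape(self._x_shape)


class GlobalAvgPool2d(Module):
    def forward(self, x):
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        return np.broadcast_to(g[:, :, None, None] / self._hw, self._shape).copy()
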