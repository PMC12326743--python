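"""Minimal 3-D convolutional network framework on numpy.

Implements exactly the pieces the episodic trainer needs: 3-D convolution,
batch normalization, ReLU, 2x2x2 max pooling, global average pooling, a
linear head, residual blocks, and SGD with momentum and L2 weight decay.
Every layer provides an analytic backward pass; correctness is verified by
numerical gradient checks in the test suite.

All tensors are float32 with layout (N, C, D, H, W).
"""

from __future__ import annotations

from collections import OrderedDict
from itertools import product
from typing import Dict, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32

# Ordered parameter-name -> array mapping; the unit of federated exchange.
ModelWeights = Dict[str, np.ndarray]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base class: children discovered by attribute scan, torch-style naming."""

    def parameters(self) -> "OrderedDict[str, Param]":
        out: "OrderedDict[str, Param]" = OrderedDict()
        for name, attr in vars(self).items():
            if isinstance(attr, Param):
                out[name] = attr
            elif isinstance(attr, Layer):
                for sub, p in attr.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(attr, list) and attr and isinstance(attr[0], Layer):
                for i, child in enumerate(attr):
                    for sub, p in child.parameters().items():
                        out[f"{name}.{i}.{sub}"] = p
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad[...] = 0.0

    def state_dict(self) -> ModelWeights:
        out: ModelWeights = OrderedDict()
        for name, p in self.parameters().items():
            out[name] = p.value.copy()
        for name, buf in self._buffers().items():
            out[name] = buf.copy()
        return out

    def load_state_dict(self, weights: ModelWeights) -> None:
        params = self.parameters()
        buffers = self._buffers(_refs=True)
        for name, arr in weights.items():
            if name in params:
                target = params[name].value
            elif name in buffers:
                target = buffers[name]
            else:
                raise KeyError(f"unknown parameter {name!r}")
            if target.shape != np.asarray(arr).shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: "
                    f"{target.shape} vs {np.asarray(arr).shape}"
                )
            target[...] = arr

    def _buffers(self, _refs: bool = False) -> "OrderedDict[str, np.ndarray]":
        """Non-trainable state (batch-norm running statistics)."""
        out: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for name, attr in vars(self).items():
            if isinstance(attr, Layer):
                for sub, b in attr._buffers(_refs).items():
                    out[f"{name}.{sub}"] = b
            elif isinstance(attr, list) and attr and isinstance(attr[0], Layer):
                for i, child in enumerate(attr):
                    for sub, b in child._buffers(_refs).items():
                        out[f"{name}.{i}.{sub}"] = b
        own = getattr(self, "_buffer_names", ())
        for name in own:
            out[name] = getattr(self, name)
        return out


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv3d(Layer):
    """Cubic-kernel 3-D convolution via im2col + GEMM."""

    def __init__(self, c_in, c_out, k, stride=1, pad=0, bias=True, *, rng):
        if isinstance(stride, int):
            stride = (stride, stride, stride)
        self.k, self.stride, self.pad = k, tuple(stride), pad
        self.c_in, self.c_out = c_in, c_out
        self.weight = Param(_he_init(rng, (c_out, c_in, k, k, k), c_in * k**3))
        self.bias = Param(np.zeros(c_out)) if bias else None
        self._cols = None
        self._xshape = None

    def _out_dims(self, d, h, w):
        k, p = self.k, self.pad
        sd, sh, sw = self.stride
        f = lambda n, s: (n + 2 * p - k) // s + 1
        return f(d, sd), f(h, sh), f(w, sw)

    def forward(self, x, train):
        n, c, d, h, w = x.shape
        k, p = self.k, self.pad
        sd, sh, sw = self.stride
        do, ho, wo = self._out_dims(d, h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        win = win[:, :, ::sd, ::sh, ::sw][:, :, :do, :ho, :wo]
        # (N, C, Do, Ho, Wo, k, k, k) -> (N*P, C*k^3)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        cols = cols.reshape(n * do * ho * wo, c * k**3)
        wmat = self.weight.value.reshape(self.c_out, -1)
        y = cols @ wmat.T
        if self.bias is not None:
            y += self.bias.value
        self._cols, self._xshape = cols, x.shape
        y = y.reshape(n, do, ho, wo, self.c_out).transpose(0, 4, 1, 2, 3)
        return np.ascontiguousarray(y)

    def backward(self, dy):
        n, c, d, h, w = self._xshape
        k, p = self.k, self.pad
        sd, sh, sw = self.stride
        do, ho, wo = self._out_dims(d, h, w)
        dyc = dy.transpose(0, 2, 3, 4, 1).reshape(n * do * ho * wo, self.c_out)
        self.weight.grad += (dyc.T @ self._cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dyc.sum(axis=0)
        dcols = dyc @ self.weight.value.reshape(self.c_out, -1)
        dcols = dcols.reshape(n, do, ho, wo, c, k, k, k)
        dxp = np.zeros((n, c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for a, b, g in product(range(k), range(k), range(k)):
            dxp[:, :, a : a + do * sd : sd, b : b + ho * sh : sh, g : g + wo * sw : sw] += (
                dcols[:, :, :, :, :, a, b, g].transpose(0, 4, 1, 2, 3)
            )
        self._cols = None
        return dxp[:, :, p : p + d, p : p + h, p : p + w] if p else dxp


class BatchNorm3d(Layer):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.eps, self.momentum = eps, momentum
        self.weight = Param(np.ones(c))
        self.bias = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._buffer_names = ("running_mean", "running_var")
        self._cache = None

    def forward(self, x, train):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, x.shape) if train else None
        return (self.weight.value.reshape(shape) * xhat + self.bias.value.reshape(shape)).astype(DTYPE)

    def backward(self, dy):
        xhat, inv, xshape = self._cache
        axes = (0, 2, 3, 4)
        m = xshape[0] * xshape[2] * xshape[3] * xshape[4]
        shape = (1, -1, 1, 1, 1)
        self.weight.grad += (dy * xhat).sum(axis=axes)
        self.bias.grad += dy.sum(axis=axes)
        dxhat = dy * self.weight.value.reshape(shape)
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape)
        ) * inv.reshape(shape)
        self._cache = None
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(DTYPE)


class MaxPool3d(Layer):
    """2x2x2 max pool, stride 2; trailing odd slices are dropped and
    singleton dimensions are left unpooled (so tiny inputs never vanish)."""

    def _factors(self, d, h, w):
        return tuple(2 if v >= 2 else 1 for v in (d, h, w))

    def forward(self, x, train):
        n, c, d, h, w = x.shape
        kd, kh, kw = self._factors(d, h, w)
        do, ho, wo = d // kd, h // kh, w // kw
        xc = x[:, :, : do * kd, : ho * kh, : wo * kw]
        win = xc.reshape(n, c, do, kd, ho, kh, wo, kw).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        win = win.reshape(n, c, do, ho, wo, kd * kh * kw)
        self._arg = win.argmax(axis=-1)
        self._xshape = x.shape
        return win.max(axis=-1)

    def backward(self, dy):
        n, c, d, h, w = self._xshape
        kd, kh, kw = self._factors(d, h, w)
        do, ho, wo = d // kd, h // kh, w // kw
        dwin = np.zeros((n, c, do, ho, wo, kd * kh * kw), dtype=DTYPE)
        np.put_along_axis(dwin, self._arg[..., None], dy[..., None], axis=-1)
        dwin = dwin.reshape(n, c, do, ho, wo, kd, kh, kw).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dx = np.zeros((n, c, d, h, w), dtype=DTYPE)
        dx[:, :, : do * kd, : ho * kh, : wo * kw] = dwin.reshape(
            n, c, do * kd, ho * kh, wo * kw
        )
        return dx


class GlobalAvgPool3d(Layer):
    def forward(self, x, train):
        self._xshape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        n, c, d, h, w = self._xshape
        return np.broadcast_to(
            dy[:, :, None, None, None] / (d * h * w), self._xshape
        ).astype(DTYPE)


class Linear(Layer):
    def __init__(self, f_in, f_out, *, rng):
        self.weight = Param(_he_init(rng, (f_out, f_in), f_in))
        self.bias = Param(np.zeros(f_out))

    def forward(self, x, train):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return (dy @ self.weight.value).astype(DTYPE)


class Sequential(Layer):
    def __init__(self, **layers: Layer):
        for name, layer in layers.items():
            setattr(self, name, layer)
        self._order = list(layers)

    def forward(self, x, train):
        for name in self._order:
            x = getattr(self, name).forward(x, train)
        return x

    def backward(self, dy):
        for name in reversed(self._order):
            dy = getattr(self, name).backward(dy)
        return dy


class ResidualBlock(Layer):
    """Pre-built main branch plus optional projection shortcut, ReLU on the sum."""

    def __init__(self, branch: Sequential, shortcut: Optional[Sequential] = None):
        self.branch = branch
        self.shortcut = shortcut

    def forward(self, x, train):
        y = self.branch.forward(x, train)
        s = self.shortcut.forward(x, train) if self.shortcut is not None else x
        self._mask = (y + s) > 0
        return np.where(self._mask, y + s, 0.0).astype(DTYPE)

    def backward(self, dy):
        dsum = np.where(self._mask, dy, 0.0).astype(DTYPE)
        dx = self.branch.backward(dsum)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(dsum)
        else:
            dx = dx + dsum
        return dx


class SGD:
    """SGD with momentum; weight decay folded into the gradient, so lr=0
    leaves weights untouched."""

    def __init__(self, net: Layer, momentum: float = 0.9, weight_decay: float = 0.0):
        self.net = net
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._buf = {name: np.zeros_like(p.value) for name, p in net.parameters().items()}

    def step(self, lr: float) -> None:
        for name, p in self.net.parameters().items():
            g = p.grad + self.weight_decay * p.value
            buf = self._buf[name]
            buf *= self.momentum
            buf += g
            p.value -= lr * buf


def save_weights(weights: ModelWeights, path) -> None:
    np.savez(path, **weights)


def load_weights(path) -> ModelWeights:
    with np.load(path) as data:
        return OrderedDict((k, data[k].copy()) for k in data.files)
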