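"""Minimal neural-network engine for small spectral-spatial CNNs.

Implements exactly the layer vocabulary the classifier topology needs —
N-dimensional "same"-padded convolution, "same"-padded strided max-pooling,
batch normalization, global average pooling, dense layers, dropout and a
sigmoid head — together with the Adam optimizer.  Everything runs on CPU and
is fully deterministic given a seeded ``numpy.random.Generator``.

Activations are channels-first: ``(N, C, H, W, B)`` in the 3D variant and
``(N, C, H, W)`` in 2D, which keeps the innermost (spectral) axis unit-stride
for the compiled kernels in :mod:`hsipatho.nn_kernels`.  A pure-numpy
shift-and-matmul fallback computes identical results when numba is absent.

Convolution follows the TensorFlow "same" convention: stride-1 convolution
preserves each extent, stride-``s`` pooling maps an extent ``d`` to
``ceil(d / s)`` with the shortfall padded (more at the trailing edge).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from . import nn_kernels as K
from .errors import ShapeError

__all__ = [
    "ConvND",
    "MaxPoolND",
    "BatchNorm",
    "GlobalAveragePool",
    "Dense",
    "Dropout",
    "Sigmoid",
    "Network",
    "Adam",
    "same_pool_output",
]


def same_pool_output(extent: int, stride: int) -> int:
    """Output extent of 'same'-padded pooling: ``ceil(extent / stride)``."""
    return -(-extent // stride)


def _conv_pads(kernel: Sequence[int], transposed: bool = False) -> list[tuple[int, int]]:
    if transposed:
        return [(k // 2, (k - 1) // 2) for k in kernel]
    return [((k - 1) // 2, k // 2) for k in kernel]


def _offsets(kernel: Sequence[int]):
    """All kernel offsets in C order (matches first-occurrence tie-breaks)."""
    return list(np.ndindex(*kernel))


def _shift_slice(offset: Sequence[int], dims: Sequence[int], stride: Sequence[int] | None = None):
    """Slices picking, for one kernel offset, the padded-input window origins."""
    stride = stride or (1,) * len(offset)
    return (slice(None),) + tuple(
        slice(o, o + s * d, s) for o, d, s in zip(offset, dims, stride)
    )


class Layer:
    """Base layer: ``params``/``grads`` are dicts of same-keyed arrays."""

    needs_input_grad = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ConvND(Layer):
    """'Same'-padded stride-1 convolution over 2 or 3 axes with optional ReLU.

    Weights are ``(C_in, *kernel, F)``, He-initialized.  Input/output are
    channels-first.
    """

    def __init__(
        self,
        kernel: Sequence[int],
        in_channels: int,
        filters: int,
        rng: np.random.Generator,
        activation: str = "relu",
    ) -> None:
        super().__init__()
        self.kernel = tuple(int(k) for k in kernel)
        self.nd = len(self.kernel)
        self.in_channels = in_channels
        self.filters = filters
        self.activation = activation
        fan_in = in_channels * math.prod(self.kernel)
        scale = math.sqrt(2.0 / fan_in)
        self.params["W"] = rng.normal(0.0, scale, (in_channels, *self.kernel, filters)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(filters, dtype=np.float32)

    def forward(self, x, train, rng):
        if x.shape[1] != self.in_channels:
            raise ShapeError(
                f"conv expects {self.in_channels} input channels, got {x.shape[1]}"
            )
        dims = x.shape[2:]
        pad_width = [(0, 0), (0, 0)] + _conv_pads(self.kernel)
        self._xp = np.pad(x, pad_width)
        self._dims = dims
        w = self.params["W"]
        if K.HAVE_NUMBA:
            kernel = K.conv3d_forward if self.nd == 3 else K.conv2d_forward
            out = kernel(self._xp, w.astype(x.dtype, copy=False), self.params["b"].astype(x.dtype))
        else:
            # channels-last shift-and-matmul fallback
            xl = np.moveaxis(self._xp, 1, -1)
            out_l = np.zeros((x.shape[0], *dims, self.filters), dtype=x.dtype)
            for off in _offsets(self.kernel):
                out_l += xl[_shift_slice(off, dims)] @ w[(slice(None), *off)]
            out_l += self.params["b"]
            out = np.moveaxis(out_l, -1, 1)
        if self.activation == "relu":
            self._mask = out > 0
            out = np.where(self._mask, out, 0.0)
        return out

    def backward(self, dy):
        if self.activation == "relu":
            dy = np.where(self._mask, dy, 0.0)
        w = self.params["W"]
        dims = self._dims
        crop = tuple(slice(p[0], p[0] + d) for p, d in zip(_conv_pads(self.kernel), dims))
        self.grads["b"] = dy.sum(axis=(0, *range(2, dy.ndim)))
        if K.HAVE_NUMBA:
            kernel = K.conv3d_backward if self.nd == 3 else K.conv2d_backward
            dw, dxp = kernel(
                self._xp.astype(dy.dtype, copy=False),
                w.astype(dy.dtype, copy=False),
                np.ascontiguousarray(dy),
                self.needs_input_grad,
            )
            self.grads["W"] = dw
            if not self.needs_input_grad:
                return None
            return dxp[(slice(None), slice(None), *crop)]
        xl = np.moveaxis(self._xp, 1, -1)
        dyl = np.moveaxis(dy, 1, -1)
        dy_flat = np.ascontiguousarray(dyl).reshape(-1, self.filters)
        dw = np.zeros_like(w, dtype=dy.dtype)
        for off in _offsets(self.kernel):
            xs = xl[_shift_slice(off, dims)].reshape(-1, self.in_channels)
            dw[(slice(None), *off)] = xs.T @ dy_flat
        self.grads["W"] = dw
        if not self.needs_input_grad:
            return None
        dxl = np.zeros_like(xl, dtype=dy.dtype)
        for off in _offsets(self.kernel):
            dxl[_shift_slice(off, dims)] += dyl @ w[(slice(None), *off)].T
        dx_full = np.moveaxis(dxl, -1, 1)
        return dx_full[(slice(None), slice(None), *crop)]


class MaxPoolND(Layer):
    """'Same'-padded max-pooling with independent pool size/stride per axis."""

    def __init__(self, pool: Sequence[int], stride: Sequence[int]) -> None:
        super().__init__()
        self.pool = tuple(int(p) for p in pool)
        self.stride = tuple(int(s) for s in stride)
        self.nd = len(self.pool)

    def forward(self, x, train, rng):
        dims = tuple(int(d) for d in x.shape[2:])
        outs = tuple(same_pool_output(d, s) for d, s in zip(dims, self.stride))
        pads = []
        for d, o, p, s in zip(dims, outs, self.pool, self.stride):
            total = max((o - 1) * s + p - d, 0)
            pads.append((total // 2, total - total // 2))
        self._pads = pads
        self._dims = dims
        self._outs = outs
        pad_before = tuple(p[0] for p in pads)
        if K.HAVE_NUMBA:
            kernel = K.maxpool3d_forward if self.nd == 3 else K.maxpool2d_forward
            best, self._arg = kernel(
                np.ascontiguousarray(x), self.pool, self.stride, pad_before, outs
            )
            return best
        xl = np.moveaxis(np.pad(x, [(0, 0), (0, 0)] + pads, constant_values=-np.inf), 1, -1)
        n, c = x.shape[0], x.shape[1]
        best = np.full((n, *outs, c), -np.inf, dtype=x.dtype)
        arg = np.zeros(best.shape, dtype=np.int16)
        # running max over kernel offsets; strict '>' keeps the first occurrence
        for flat_off, off in enumerate(_offsets(self.pool)):
            candidate = xl[_shift_slice(off, outs, self.stride)]
            better = candidate > best
            np.copyto(best, candidate, where=better)
            np.copyto(arg, flat_off, where=better)
        self._arg = arg
        return np.ascontiguousarray(np.moveaxis(best, -1, 1))

    def backward(self, dy):
        pad_before = tuple(p[0] for p in self._pads)
        if K.HAVE_NUMBA:
            kernel = K.maxpool3d_backward if self.nd == 3 else K.maxpool2d_backward
            return kernel(
                np.ascontiguousarray(dy), self._arg, self._dims, self.pool, self.stride, pad_before
            )
        dyl = np.moveaxis(dy, 1, -1)
        n, c = dy.shape[0], dy.shape[1]
        padded_dims = [d + p[0] + p[1] for d, p in zip(self._dims, self._pads)]
        dxl = np.zeros((n, *padded_dims, c), dtype=dy.dtype)
        # per offset the strided window origins are disjoint, so plain += works
        for flat_off, off in enumerate(_offsets(self.pool)):
            view = dxl[_shift_slice(off, self._outs, self.stride)]
            view += np.where(self._arg == flat_off, dyl, 0.0)
        crop = tuple(slice(p[0], p[0] + d) for p, d in zip(self._pads, self._dims))
        return np.moveaxis(dxl[(slice(None), *crop)], -1, 1)


class BatchNorm(Layer):
    """Per-channel batch normalization over batch + spatial/spectral axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    @staticmethod
    def _bshape(ndim: int):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, train, rng):
        axes = (0, *range(2, x.ndim))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        shape = self._bshape(x.ndim)
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).reshape(shape)
        self._xhat = (x - mu.reshape(shape)) * self._inv_std
        self._axes = axes
        self._m = x.size // x.shape[1]
        return self.params["gamma"].reshape(shape) * self._xhat + self.params["beta"].reshape(shape)

    def backward(self, dy):
        axes = self._axes
        shape = self._bshape(dy.ndim)
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"].reshape(shape)
        m = self._m
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - self._xhat * ((dxhat * self._xhat).sum(axis=axes) / m).reshape(shape)
        ) * self._inv_std
        return dx


class GlobalAveragePool(Layer):
    """Mean over all spatial/spectral axes, leaving ``(N, C)`` features."""

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dy):
        shape = self._shape
        m = int(np.prod(shape[2:]))
        expanded = dy.reshape(shape[0], shape[1], *(1,) * (len(shape) - 2))
        return np.broadcast_to(expanded / m, shape).astype(dy.dtype)


class Dense(Layer):
    """Fully connected layer with optional ReLU; He initialization."""

    def __init__(
        self, in_features: int, units: int, rng: np.random.Generator, activation: str | None = None
    ) -> None:
        super().__init__()
        self.activation = activation
        scale = math.sqrt(2.0 / in_features)
        self.params["W"] = rng.normal(0.0, scale, (in_features, units)).astype(np.float32)
        self.params["b"] = np.zeros(units, dtype=np.float32)

    def forward(self, x, train, rng):
        self._x = x
        out = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = out > 0
            out = np.where(self._mask, out, 0.0)
        return out

    def backward(self, dy):
        if self.activation == "relu":
            dy = np.where(self._mask, dy, 0.0)
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Sigmoid(Layer):
    """Elementwise logistic activation."""

    def forward(self, x, train, rng):
        self._p = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._p

    def backward(self, dy):
        return dy * self._p * (1.0 - self._p)


class Network:
    """An ordered layer stack with plain forward/backward passes."""

    def __init__(self, layers: list[Layer], variant: str = "3d", input_dims=None) -> None:
        self.layers = layers
        self.variant = variant
        self.input_dims = tuple(input_dims) if input_dims is not None else None
        # the first parametric conv never needs an input gradient
        for layer in layers:
            if isinstance(layer, ConvND):
                layer.needs_input_grad = False
                break

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
            if dy is None:
                break

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield f"{i}:{name}", layer, name

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {key: layer.params[name] for key, layer, name in self.parameters()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                state[f"{i}:running_mean"] = layer.running_mean
                state[f"{i}:running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.parameters():
            layer.params[name] = np.asarray(state[key], dtype=np.float32)
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(state[f"{i}:running_mean"], dtype=np.float32)
                layer.running_var = np.asarray(state[f"{i}:running_var"], dtype=np.float32)


class Adam:
    """Adam with bias correction (Kingma & Ba defaults)."""

    def __init__(
        self,
        network: Network,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.network = network
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {key: np.zeros_like(layer.params[name]) for key, layer, name in network.parameters()}
        self.v = {key: np.zeros_like(layer.params[name]) for key, layer, name in network.parameters()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        correction = self.lr * math.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for key, layer, name in self.network.parameters():
            g = layer.grads[name]
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            layer.params[name] = layer.params[name] - correction * self.m[key] / (
                np.sqrt(self.v[key]) + self.eps
            )
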