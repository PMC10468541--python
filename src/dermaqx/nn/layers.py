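"""Minimal NumPy neural-network layers with explicit forward/backward passes.

The package trains small convolutional networks on CPU; all layers keep the
caches needed for backpropagation and expose their parameters as
:class:`Parameter` objects so a single optimizer can update them. Arrays are
float32 throughout; convolution uses an im2col lowering so the inner loop is
a single BLAS matmul.
"""

from __future__ import annotations

import math

import numpy as np


class Parameter:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: forward(x, train) -> y, backward(dy) -> dx."""

    def parameters(self) -> list[Parameter]:
        return []

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable buffers (e.g. batch-norm running statistics)."""
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Lower (N, C, H, W) to (N*Ho*Wo, C*k*k) patches."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    n, c, ho, wo, _, _ = win.shape
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * k * k
    )
    return cols, ho, wo


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int, ho: int, wo: int):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dwin = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                dwin[:, :, :, :, i, j]
            )
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, *, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator, name: str = "conv"):
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        fan_in = cin * k * k
        self.weight = Parameter(f"{name}.weight", _he_init(rng, fan_in, (cout, fan_in)))
        self.bias = Parameter(f"{name}.bias", np.zeros(cout, dtype=np.float32))
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        out = cols @ self.weight.value.T + self.bias.value
        n = x.shape[0]
        self._cache = (cols, x.shape, ho, wo)
        return np.ascontiguousarray(
            out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        )

    def backward(self, dy):
        cols, xshape, ho, wo = self._cache
        n = xshape[0]
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.weight.grad += dy2.T @ cols
        self.bias.grad += dy2.sum(axis=0)
        dcols = dy2 @ self.weight.value
        return _col2im(dcols, xshape, self.k, self.stride, self.pad, ho, wo)


class _BatchNormBase(Layer):
    def __init__(self, num_features: int, *, momentum: float = 0.1,
                 eps: float = 1e-5, name: str = "bn"):
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(f"{name}.gamma", np.ones(num_features, dtype=np.float32))
        self.beta = Parameter(f"{name}.beta", np.zeros(num_features, dtype=np.float32))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self):
        return {
            f"{self.gamma.name.rsplit('.', 1)[0]}.running_mean": self.running_mean,
            f"{self.gamma.name.rsplit('.', 1)[0]}.running_var": self.running_var,
        }

    # subclasses define the reduction axes and broadcast shape
    _axes: tuple[int, ...]

    def _bshape(self, x):
        raise NotImplementedError

    def forward(self, x, train=False):
        bs = self._bshape(x)
        if train:
            mean = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bs)) * inv.reshape(bs)
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value.reshape(bs) * xhat + self.beta.value.reshape(bs)

    def backward(self, dy):
        xhat, inv, train, xshape = self._cache
        bs = self._bshape(dy)
        self.gamma.grad += (dy * xhat).sum(axis=self._axes)
        self.beta.grad += dy.sum(axis=self._axes)
        g = self.gamma.value.reshape(bs)
        if not train:
            return dy * g * inv.reshape(bs)
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=self._axes).reshape(bs)
            - xhat * (dxhat * xhat).mean(axis=self._axes).reshape(bs)
        ) * inv.reshape(bs)
        return dx.astype(np.float32)


class BatchNorm2d(_BatchNormBase):
    _axes = (0, 2, 3)

    def _bshape(self, x):
        return (1, -1, 1, 1)


class BatchNorm1d(_BatchNormBase):
    _axes = (0,)

    def _bshape(self, x):
        return (1, -1)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, din: int, dout: int, *, rng: np.random.Generator,
                 name: str = "linear"):
        self.weight = Parameter(f"{name}.weight", _he_init(rng, din, (dout, din)))
        self.bias = Parameter(f"{name}.bias", np.zeros(dout, dtype=np.float32))
        self._x = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class Dropout(Layer):
    """Inverted dropout; masks are drawn from the generator passed at
    construction so the whole training run is reproducible from one seed."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def state(self):
        out: dict[str, np.ndarray] = {}
        for l in self.layers:
            out.update(l.state())
        return out

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy
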