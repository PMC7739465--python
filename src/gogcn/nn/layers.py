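"""Layer primitives with explicit forward/backward passes.

Each layer keeps its parameters in ``params`` and the gradients of the
last backward call in ``grads`` (same keys). ``forward(x, train=...)``
caches whatever the backward pass needs; ``backward(gout)`` returns the
gradient with respect to the layer input. All layers are deterministic in
evaluation mode.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


def sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x):
    """log(1 + exp(x)), stable for large |x|."""
    return np.logaddexp(0.0, x)


class Layer:
    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Affine map ``y = x W + b`` with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.params = {
            "W": rng.uniform(-limit, limit, size=(n_in, n_out)).astype(dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gout):
        self.grads["W"][...] = self._x.T @ gout
        self.grads["b"][...] = gout.sum(axis=0)
        return gout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x, train: bool = False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        return gout * self._mask


class BatchNorm1d(Layer):
    """Normalize each feature channel over the batch (and positions).

    Accepts ``(n, features)`` or ``(n, positions, features)`` input;
    statistics are taken over all leading axes. Running statistics are
    kept with exponential smoothing for evaluation mode.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.params = {
            "gamma": np.ones(n_features, dtype=dtype),
            "beta": np.zeros(n_features, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)

    def forward(self, x, train: bool = False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        self._axes = axes
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, gout):
        axes = self._axes
        self.grads["gamma"][...] = (gout * self._xhat).sum(axis=axes)
        self.grads["beta"][...] = gout.sum(axis=axes)
        g = gout * self.params["gamma"]
        if not self._train:
            return g / self._std
        m = np.prod([gout.shape[a] for a in axes])
        # standard batch-norm backward through the batch statistics
        return (
            g - g.mean(axis=axes) - self._xhat * (g * self._xhat).mean(axis=axes)
        ) / self._std


class Conv1dOneHot(Layer):
    """1D convolution over a one-hot encoded sequence, valid padding.

    Input ``(n, length, channels)``; output ``(n, p, filters)`` with
    ``p = (length - h) // stride + 1`` (``length - h + 1`` at stride 1).
    Implemented as an im2col matrix product; windows are materialized with
    stride tricks, so no copy is made before the GEMM.
    """

    def __init__(self, h: int, channels: int, filters: int,
                 rng: np.random.Generator, stride: int = 1, dtype=np.float32):
        super().__init__()
        self.h = h
        self.channels = channels
        self.filters = filters
        self.stride = stride
        fan_in = h * channels
        limit = np.sqrt(6.0 / (fan_in + filters))
        self.params = {
            "W": rng.uniform(-limit, limit, size=(fan_in, filters)).astype(dtype),
            "b": np.zeros(filters, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _im2col(self, x):
        n, length, c = x.shape
        if length < self.h:
            raise ValueError(
                f"sequence length {length} shorter than kernel size {self.h}"
            )
        p = (length - self.h) // self.stride + 1
        sn, sl, sc = x.strides
        windows = as_strided(
            x,
            shape=(n, p, self.h, c),
            strides=(sn, sl * self.stride, sl, sc),
            writeable=False,
        )
        return windows.reshape(n, p, self.h * c)

    def forward(self, x, train: bool = False):
        cols = self._im2col(np.ascontiguousarray(x))
        self._cols = cols
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, gout):
        n, p, f = gout.shape
        cols = self._cols.reshape(n * p, -1)
        self.grads["W"][...] = cols.T @ gout.reshape(n * p, f)
        self.grads["b"][...] = gout.sum(axis=(0, 1))
        return None  # gradient w.r.t. the one-hot input is never needed


class GlobalMaxPool(Layer):
    """Max over the position axis of ``(n, p, filters)`` input."""

    def forward(self, x, train: bool = False):
        self._arg = x.argmax(axis=1)
        self._shape = x.shape
        n, _, f = x.shape
        return x[np.arange(n)[:, None], self._arg, np.arange(f)[None, :]]

    def backward(self, gout):
        n, p, f = self._shape
        gx = np.zeros(self._shape, dtype=gout.dtype)
        gx[np.arange(n)[:, None], self._arg, np.arange(f)[None, :]] = gout
        return gx
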