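"""Dense, convolutional, normalization and regularization layers.

Every layer implements ``forward(x)`` caching what its ``backward(grad)``
needs; ``backward`` accumulates into ``Parameter.grad`` and returns the
gradient with respect to its input.
"""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter


class Linear(Module):
    """Affine map ``y = x @ W + b`` applied over the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.W = Parameter(rng.uniform(-bound, bound, (d_in, d_out)).astype(dtype))
        self.b = Parameter(np.zeros(d_out, dtype=dtype))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        d_in, d_out = self.W.shape
        self.W.grad += x.reshape(-1, d_in).T @ grad.reshape(-1, d_out)
        self.b.grad += grad.reshape(-1, d_out).sum(axis=0)
        return grad @ self.W.data.T


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Conv1d(Module):
    """Strided 1-D convolution over channels-first input ``(B, C_in, T)``.

    Implemented as im2col + matmul: patches of shape ``(C_in * k)`` are
    gathered at each output position and multiplied by a ``(C_in*k, C_out)``
    weight matrix.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator = None,
        dtype=np.float32,
    ):
        super().__init__()
        fan_in = c_in * kernel
        # He initialization: the conv feeds a ReLU
        self.W = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out)).astype(dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self._cols = None
        self._x_shape = None

    def out_length(self, t: int) -> int:
        return (t + 2 * self.padding - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, T = x.shape
        if T + 2 * self.padding < self.kernel:
            raise ValueError(
                f"input length {T} too short for kernel {self.kernel} with padding {self.padding}"
            )
        k, st, p = self.kernel, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        t_out = self.out_length(T)
        s0, s1, s2 = xp.strides
        patches = np.lib.stride_tricks.as_strided(
            xp, shape=(B, t_out, C, k), strides=(s0, s2 * st, s1, s2), writeable=False
        )
        cols = patches.reshape(B, t_out, C * k)
        y = cols @ self.W.data + self.b.data          # (B, t_out, c_out)
        self._cols = cols
        self._x_shape = (B, C, T, xp.shape[-1], t_out)
        return y.transpose(0, 2, 1)                   # (B, c_out, t_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, T, Tp, t_out = self._x_shape
        k, st, p = self.kernel, self.stride, self.padding
        g = np.ascontiguousarray(grad.transpose(0, 2, 1))      # (B, t_out, c_out)
        cols = self._cols.reshape(-1, C * k)
        self.W.grad += cols.T @ g.reshape(-1, self.c_out)
        self.b.grad += g.reshape(-1, self.c_out).sum(axis=0)
        gcols = (g @ self.W.data.T).reshape(B, t_out, C, k)
        gxp = np.zeros((B, C, Tp), dtype=grad.dtype)
        for j in range(k):
            gxp[:, :, j : j + st * t_out : st] += gcols[:, :, :, j].transpose(0, 2, 1)
        return gxp[:, :, p : Tp - p] if p else gxp


class BatchNorm1d(Module):
    """Batch normalization over (batch, time) for channels-first input."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv)
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        gxhat = grad * self.gamma.data[None, :, None]
        if not self.training:
            return gxhat * inv[None, :, None]
        B, C, T = grad.shape
        n = B * T
        s1 = gxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv[None, :, None] / n) * (n * gxhat - s1 - xhat * s2)


class LayerNorm(Module):
    """Layer normalization over the last axis."""

    def __init__(self, d: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(d, dtype=dtype))
        self.beta = Parameter(np.zeros(d, dtype=dtype))
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        d = xhat.shape[-1]
        axes = tuple(range(grad.ndim - 1))
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gxhat = grad * self.gamma.data
        s1 = gxhat.sum(axis=-1, keepdims=True)
        s2 = (gxhat * xhat).sum(axis=-1, keepdims=True)
        return (inv / d) * (d * gxhat - s1 - xhat * s2)
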