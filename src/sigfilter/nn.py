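"""Minimal NumPy neural-network layers with hand-written backprop.

Only what the basecaller needs: 1-D convolution (grouped, pointwise and
strided, with "same" padding), batch normalization, ReLU, log-softmax and a
sequential container, plus Adam with decoupled weight decay. Tensors are
``(batch, channels, time)`` float32. Gradients are accumulated into
``Param.grad`` by ``backward`` and are checked against finite differences
in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

try:  # JIT kernels for the depthwise convolution inner loops
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:
    @njit(cache=True)
    def _dw_forward(xp, w, out):  # pragma: no cover
        b, c, tp = xp.shape
        k = w.shape[1]
        t = out.shape[2]
        for i in range(b):
            for ch in range(c):
                for j in range(t):
                    acc = 0.0
                    for q in range(k):
                        acc += w[ch, q] * xp[i, ch, j + q]
                    out[i, ch, j] = acc

    @njit(cache=True)
    def _dw_backward(xp, w, dy, dw, dxp):  # pragma: no cover
        b, c, tp = xp.shape
        k = w.shape[1]
        t = dy.shape[2]
        for i in range(b):
            for ch in range(c):
                for j in range(t):
                    g = dy[i, ch, j]
                    for q in range(k):
                        dw[ch, q] += g * xp[i, ch, j + q]
                        dxp[i, ch, j + q] += g * w[ch, q]


@dataclass
class Param:
    name: str
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_padding(t: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(out_len, pad_left, pad_right) for 'same' conv: out = ceil(t/stride)."""
    out = -(-t // stride)
    needed = max(0, (out - 1) * stride + kernel - t)
    return out, needed // 2, needed - needed // 2


class Conv1d(Layer):
    """Grouped 1-D convolution, 'same' padding, optional stride and bias.

    ``groups == in_channels == out_channels`` gives a depthwise convolution;
    ``kernel == 1`` a pointwise one. He-initialised.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 groups: int = 1, bias: bool = True, *, name: str = "conv",
                 rng: np.random.Generator | None = None):
        if c_in % groups or c_out % groups:
            raise ValueError(
                f"channel counts ({c_in}->{c_out}) must be divisible by groups={groups}"
            )
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.groups = kernel, stride, groups
        fan_in = (c_in // groups) * kernel
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                       size=(groups, c_out // groups, c_in // groups, kernel))
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(c_out)) if bias else None
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    @property
    def _is_depthwise(self) -> bool:
        return (self.groups == self.c_in == self.c_out and self.stride == 1)

    @property
    def _is_pointwise(self) -> bool:
        return self.kernel == 1 and self.groups == 1 and self.stride == 1

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, t = x.shape
        out_t, pl, pr = _same_padding(t, self.kernel, self.stride)
        if self._is_pointwise:
            w = self.weight.value[0, :, :, 0]
            y = np.matmul(w[None], x)
            if training:
                self._cache = ("pw", x)
        elif self._is_depthwise:
            xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
            w = self.weight.value[:, 0, 0, :]  # (C, K)
            y = np.empty((b, c, out_t), dtype=np.float32)
            if _HAVE_NUMBA:
                _dw_forward(xp, w, y)
            else:
                y[...] = 0.0
                for j in range(self.kernel):
                    y += w[None, :, j, None] * xp[:, :, j:j + out_t]
            if training:
                self._cache = ("dw", xp, x.shape, (pl, pr), out_t)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
            win = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
            win = win[:, :, :out_t, :]
            g = self.groups
            wing = win.reshape(b, g, c // g, out_t, self.kernel)
            y = np.einsum("bgitk,goik->bgot", wing, self.weight.value,
                          optimize=True)
            y = y.reshape(b, self.c_out, out_t)
            if training:
                self._cache = ("gen", wing, x.shape, (pl, pr), out_t)
        if self.bias is not None:
            y = y + self.bias.value[None, :, None]
        return y.astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2))
        kind = self._cache[0]
        if kind == "pw":
            _, x = self._cache
            w = self.weight.value[0, :, :, 0]
            self.weight.grad[0, :, :, 0] += np.matmul(
                dy, x.transpose(0, 2, 1)).sum(axis=0)
            return np.matmul(w.T[None], dy).astype(np.float32, copy=False)
        if kind == "dw":
            _, xp, x_shape, (pl, pr), out_t = self._cache
            b, c, t = x_shape
            w = self.weight.value[:, 0, 0, :]
            dxp = np.zeros_like(xp)
            if _HAVE_NUMBA:
                dy32 = np.ascontiguousarray(dy, dtype=np.float32)
                dw = np.zeros_like(w)
                _dw_backward(xp, w, dy32, dw, dxp)
                self.weight.grad[:, 0, 0, :] += dw
            else:
                for j in range(self.kernel):
                    self.weight.grad[:, 0, 0, j] += (
                        dy * xp[:, :, j:j + out_t]).sum(axis=(0, 2))
                    dxp[:, :, j:j + out_t] += w[None, :, j, None] * dy
            return dxp[:, :, pl:pl + t].astype(np.float32, copy=False)
        _, wing, x_shape, (pl, pr), out_t = self._cache
        b, c, t = x_shape
        g = self.groups
        dyg = dy.reshape(b, g, self.c_out // g, out_t)
        self.weight.grad += np.einsum("bgitk,bgot->goik", wing, dyg,
                                      optimize=True)
        dwin = np.einsum("bgot,goik->bgitk", dyg, self.weight.value,
                         optimize=True)
        dwin = dwin.reshape(b, c, out_t, self.kernel)
        dxp = np.zeros((b, c, t + pl + pr), dtype=np.float32)
        s = self.stride
        for j in range(self.kernel):
            dxp[:, :, j:j + s * out_t:s] += dwin[:, :, :, j]
        return dxp[:, :, pl:pl + t]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, *, name: str = "bn"):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.weight", np.ones(channels))
        self.beta = Param(f"{name}.bias", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            n = x.shape[0] * x.shape[2]
            mean = x.mean(axis=(0, 2))
            msq = np.einsum("bct,bct->c", x, x, optimize=True) / n
            var = np.maximum(msq - mean * mean, 0.0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = x - mean[None, :, None]
        xhat *= inv_std[None, :, None]
        y = xhat * self.gamma.value[None, :, None]
        y += self.beta.value[None, :, None]
        if training:
            self._cache = (xhat, inv_std)
        return y.astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dy.shape[0] * dy.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.value[None, :, None] * inv_std[None, :, None]
        mean_dy = dy.sum(axis=(0, 2))[None, :, None] / n
        mean_dy_xhat = (dy * xhat).sum(axis=(0, 2))[None, :, None] / n
        return (g * (dy - mean_dy - xhat * mean_dy_xhat)).astype(np.float32)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class LogSoftmax(Layer):
    """Log-softmax over the channel axis of (batch, channels, time)."""

    def __init__(self) -> None:
        self._probs = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        m = x.max(axis=1, keepdims=True)
        z = x - m
        lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
        y = z - lse
        self._probs = np.exp(y)  # needed by backward; cheap either way
        return y.astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (dy - self._probs * dy.sum(axis=1, keepdims=True)).astype(np.float32)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied directly to the weights (not through the
    gradient moments) and skips batch-norm scale/shift and biases,
    following common practice.
    """

    def __init__(self, params: list[Param], lr: float = 2e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.eps, self.weight_decay = eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            if self.weight_decay and p.value.ndim > 1:
                p.value *= 1.0 - lr * self.weight_decay
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)
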