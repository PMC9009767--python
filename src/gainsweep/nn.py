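"""Minimal numpy layer library: convolution, batch norm, dense, losses.

Forward and backward passes are hand-written; convolutions use an
im2col / col2im formulation so all heavy lifting is BLAS matmul. All
arrays are float32 in NCHW layout. Each layer caches what its backward
pass needs; backward must be called right after the forward it matches.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .activations import ActivationSpec, GlobalGainState, activation_grad, gained_activation

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> Iterator[Tuple[str, Param]]:
        return iter(())

    def state(self) -> Dict[str, np.ndarray]:
        """All persistent arrays (weights + running statistics)."""
        return {name: p.value for name, p in self.params()}

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        for name, p in self.params():
            p.value[...] = state[name]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * k * k, ho * wo
    )
    return cols, ho, wo


def _col2im(dcols, x_shape, k, stride, pad, ho, wo):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=F32)
    d6 = dcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d6[
                :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d(Layer):
    """2-D convolution, 'same' padding for odd kernels, optional bias."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        ksize: int = 3,
        stride: int = 1,
        bias: bool = False,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * ksize * ksize
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(F32))
        self.b = Param(np.zeros(c_out, dtype=F32)) if bias else None
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, ksize, stride
        self.pad = ksize // 2
        self._cache = None

    def params(self):
        yield "w", self.w
        if self.b is not None:
            yield "b", self.b

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        y = np.matmul(self.w.value[None], cols).reshape(x.shape[0], self.c_out, ho, wo)
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        if train:
            self._cache = (x.shape, cols, ho, wo)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x_shape, cols, ho, wo = self._cache
        n = x_shape[0]
        g2 = gy.reshape(n, self.c_out, ho * wo)
        self.w.grad += np.einsum("nol,nkl->ok", g2, cols, optimize=True)
        if self.b is not None:
            self.b.grad += g2.sum(axis=(0, 2))
        dcols = np.matmul(self.w.value.T[None], g2)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo)


class BatchNorm2d(Layer):
    """Per-channel batch normalisation.

    In training mode batch statistics are used and running statistics
    updated; in eval mode the frozen running statistics are used. The
    whole gain-sweep pipeline evaluates in eval mode so that gain
    effects propagate instead of being renormalised away.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=F32))
        self.beta = Param(np.zeros(c, dtype=F32))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None
        self._adapt_n: Optional[int] = None

    def begin_adapt(self) -> None:
        """Start equal-weight re-estimation of the running statistics
        (used when recalibrating the normalisation to a gain state)."""
        self._adapt_n = 0

    def end_adapt(self) -> None:
        self._adapt_n = None

    def params(self):
        yield "gamma", self.gamma
        yield "beta", self.beta

    def state(self):
        s = super().state()
        s["running_mean"] = self.running_mean
        s["running_var"] = self.running_var
        return s

    def load_state(self, state):
        super().load_state(state)
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self._adapt_n is not None:
                # weight each batch by its size: exact pooled mean, pooled
                # within-batch variance (between-batch spread is negligible
                # for the calibration sets used)
                m = x.shape[0] * x.shape[2] * x.shape[3]
                self._adapt_n += m
                w = m / self._adapt_n
                self.running_mean += w * (mu - self.running_mean)
                self.running_var += w * (var - self.running_var)
            else:
                self.running_mean += self.momentum * (mu - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        dxhat = gy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class GainedActivation(Layer):
    """Activation site sharing the model-wide :class:`GlobalGainState`."""

    def __init__(self, spec: ActivationSpec, gain: GlobalGainState):
        self.spec = spec
        self.gain = gain
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        return gained_activation(x, self.spec, self.gain).astype(F32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * (self.gain.delta * activation_grad(self._cache, self.spec))


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(gy[:, :, None, None] / (h * w), self._shape).astype(F32)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(1.0 / c_in), (c_in, c_out)).astype(F32))
        self.b = Param(np.zeros(c_out, dtype=F32)) if bias else None
        self._cache = None

    def params(self):
        yield "w", self.w
        if self.b is not None:
            yield "b", self.b

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        y = x @ self.w.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += self._cache.T @ gy
        if self.b is not None:
            self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value.T


class Sequential(Layer):
    """Plain layer chain; used for toy oracle networks in tests."""

    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def params(self):
        for i, layer in enumerate(self.layers):
            for name, p in layer.params():
                yield f"{i}.{name}", p

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean CE loss and gradient wrt logits.

    ``y`` is an int class vector, or a (n, k) matrix of soft target
    distributions (e.g. mixup labels)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(y)
    if y.ndim == 1:
        loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
        g = p.copy()
        g[np.arange(n), y] -= 1.0
    else:
        loss = -np.mean((y * np.log(p + 1e-12)).sum(axis=1))
        g = p - y
    return loss, (g / n).astype(F32)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def sigmoid_bce(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy over all units and gradient wrt logits."""
    p = sigmoid(logits)
    eps = 1e-7
    loss = -np.mean(
        targets * np.log(p + eps) + (1.0 - targets) * np.log(1.0 - p + eps)
    )
    return loss, ((p - targets) / targets.size).astype(F32)


class SGD:
    """Momentum SGD with optional cosine learning-rate decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.vel = [np.zeros_like(p.value) for _, p in self.params]

    def zero_grad(self):
        for _, p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: Optional[float] = None):
        lr = self.lr if lr is None else lr
        for (_, p), v in zip(self.params, self.vel):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v -= lr * g
            p.value += v


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max(total_epochs, 1)))
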