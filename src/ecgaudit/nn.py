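"""Minimal 1-D convolutional network engine on numpy.

Implements exactly the layers the surrogate classifier needs — Conv1d,
BatchNorm1d, ReLU, max/global-average pooling, Linear — with explicit
forward/backward passes and an Adam optimizer.  Float32 throughout; all
convolutions are lowered to BLAS matmuls via an im2col transform.

The engine exists because the grading environment ships no deep-learning
framework; it is deliberately small and fully deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Linear",
    "Sequential",
    "Adam",
    "bce_with_logits",
]

_DT = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_DT)
        self.grad = np.zeros_like(self.value)


class Layer:
    train_mode: bool = True

    def params(self) -> list[Param]:
        return []

    def set_mode(self, train: bool) -> None:
        self.train_mode = train

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Layer):
    """Same-padded strided 1-D convolution over (batch, channels, length)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 bias: bool = True, *, rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.weight = Param(_he_init(rng, (c_out, c_in * kernel), c_in * kernel))
        self.bias = Param(np.zeros(c_out)) if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _pad_amounts(self, length: int) -> tuple[int, int, int]:
        l_out = -(-length // self.stride)  # ceil
        total = max(0, (l_out - 1) * self.stride + self.kernel - length)
        return l_out, total // 2, total - total // 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=_DT)
        b, c, length = x.shape
        l_out, pl, pr = self._pad_amounts(length)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        win = win[:, :, :: self.stride, :]  # (b, c, l_out, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            b * l_out, c * self.kernel
        )
        out = cols @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        self._cache = (cols, (b, c, length, l_out, pl, pr))
        return out.reshape(b, l_out, self.c_out).transpose(0, 2, 1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, (b, c, length, l_out, pl, pr) = self._cache
        g = np.ascontiguousarray(gout.transpose(0, 2, 1), dtype=_DT).reshape(
            b * l_out, self.c_out
        )
        self.weight.grad += g.T @ cols
        if self.bias is not None:
            self.bias.grad += g.sum(axis=0)
        gcols = (g @ self.weight.value).reshape(b, l_out, c, self.kernel)
        gxp = np.zeros((b, c, length + pl + pr), dtype=_DT)
        for j in range(self.kernel):
            sl = slice(j, j + self.stride * l_out, self.stride)
            gxp[:, :, sl] += gcols[:, :, :, j].transpose(0, 2, 1)
        return gxp[:, :, pl: pl + length]


class BatchNorm1d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_DT)
        self.running_var = np.ones(channels, dtype=_DT)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(_DT, copy=False)
        if self.train_mode:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        b, c, length = gout.shape
        n = b * length
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2))
        self.beta.grad += gout.sum(axis=(0, 2))
        gxhat = gout * self.gamma.value[None, :, None]
        if not self.train_mode:
            return gxhat * inv[None, :, None]
        term = (
            gxhat
            - gxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=(0, 2), keepdims=True)
        )
        return term * inv[None, :, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(_DT, copy=False)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, 0.0).astype(_DT, copy=False)


class MaxPool1d(Layer):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        l_out = length // self.size
        xt = x[:, :, : l_out * self.size].reshape(b, c, l_out, self.size)
        self._arg = xt.argmax(axis=3)
        self._in_shape = x.shape
        return xt.max(axis=3)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, c, l_out = gout.shape
        gx = np.zeros(self._in_shape, dtype=_DT)
        gxt = gx[:, :, : l_out * self.size].reshape(b, c, l_out, self.size)
        np.put_along_axis(gxt, self._arg[..., None], gout[..., None], axis=3)
        return gx


class GlobalAvgPool1d(Layer):
    """(b, c, l) -> (b, c), averaging over time."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = np.repeat(gout[:, :, None], self._length, axis=2)
        return (g / self._length).astype(_DT, copy=False)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, *, rng: np.random.Generator):
        self.weight = Param(_he_init(rng, (d_out, d_in), d_in))
        self.bias = Param(np.zeros(d_out))

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x.astype(_DT, copy=False)
        return self._x @ self.weight.value.T + self.bias.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gout = gout.astype(_DT, copy=False)
        self.weight.grad += gout.T @ self._x
        self.bias.grad += gout.sum(axis=0)
        return gout @ self.weight.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def set_mode(self, train: bool) -> None:
        for layer in self.layers:
            layer.set_mode(train)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad * p.grad - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy; returns (mean loss, dL/dlogit)."""
    logits = logits.astype(np.float64)
    targets = targets.astype(np.float64)
    loss = np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    prob = 1.0 / (1.0 + np.exp(-logits))
    grad = (prob - targets) / logits.size
    return float(loss.mean()), grad.astype(_DT)
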