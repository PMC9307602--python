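"""Minimal neural-network layers with explicit forward/backward passes.

Self-contained NumPy implementation (float32, im2col convolutions backed by
BLAS matmuls).  Each layer caches what its backward pass needs; ``backward``
returns the gradient with respect to the layer input and accumulates
parameter gradients in ``grads``.  Backward through an eval-mode forward is
supported everywhere (batch norm then uses running statistics), which is what
lets attribution code differentiate a trained model with respect to its
inputs.

Shape conventions: convolutional tensors are (N, L, C) — batch, length,
channels; dense tensors are (N, F).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "BatchNorm",
    "ReLU",
    "MaxPool1D",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adam",
]

_F32 = np.float32


class Layer:
    """Base layer: parameter/gradient dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


class Conv1D(Layer):
    """Length-preserving 1-D convolution whose kernel spans all input channels.

    The kernel covers ``l`` consecutive positions times all ``c_in`` channels
    (the "l x m" / "l x 4" kernels of the two input branches).  Zero padding of
    (l-1)//2 left and l//2 right keeps the row count unchanged.
    """

    def __init__(self, l: int, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.l, self.c_in, self.c_out = l, c_in, c_out
        self.pad_left = (l - 1) // 2
        self.pad_right = l // 2
        scale = np.sqrt(2.0 / (l * c_in))
        self.params["w"] = (rng.standard_normal((l * c_in, c_out)) * scale).astype(_F32)
        self.params["b"] = np.zeros(c_out, dtype=_F32)
        self.zero_grads()

    def _w3(self) -> np.ndarray:
        # (l*c_in, c_out) kernel viewed as (l, c_in, c_out)
        return self.params["w"].reshape(self.l, self.c_in, self.c_out)

    def forward(self, x, train, rng=None):
        n, L, c = x.shape
        if c != self.c_in:
            raise ValueError(f"Conv1D expected {self.c_in} channels, got {c}")
        self._shape = (n, L)
        # sum of shifted batched matmuls — same result as im2col @ W with far
        # less memory traffic
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        self._xp = xp
        w3 = self._w3()
        y = np.broadcast_to(self.params["b"], (n, L, self.c_out)).astype(xp.dtype)
        y = np.ascontiguousarray(y)
        for j in range(self.l):
            y += np.matmul(xp[:, j : j + L, :], w3[j])
        return y

    def backward(self, dy):
        n, L = self._shape
        w3 = self._w3()
        dw = self.grads["w"].reshape(self.l, self.c_in, self.c_out)
        self.grads["b"] += dy.sum(axis=(0, 1))
        dxp = np.zeros_like(self._xp)
        for j in range(self.l):
            xj = self._xp[:, j : j + L, :]
            dw[j] += np.tensordot(xj, dy, axes=([0, 1], [0, 1]))
            dxp[:, j : j + L, :] += np.matmul(dy, w3[j].T)
        return dxp[:, self.pad_left : self.pad_left + L, :]


class BatchNorm(Layer):
    """Batch normalization per channel (last axis), momentum 0.9, eps 1e-5.

    In eval mode running statistics are used; the eval backward pass is the
    per-sample affine gradient, with no cross-sample coupling.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=_F32)
        self.params["beta"] = np.zeros(channels, dtype=_F32)
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self.zero_grads()

    def forward(self, x, train, rng=None):
        axes = tuple(range(x.ndim - 1))
        self._train = train
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean + (1 - self.momentum) * mean).astype(_F32)
            self.running_var = (self.momentum * self.running_var + (1 - self.momentum) * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._invstd
        return self._xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.grads["gamma"] += (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        g = self.params["gamma"] * self._invstd
        if not self._train:
            return dy * g
        n = dy.size // dy.shape[-1]
        dxhat = dy * self.params["gamma"]
        return (self._invstd / n) * (
            n * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )


class ReLU(Layer):
    def forward(self, x, train, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, x.dtype.type(0.0))

    def backward(self, dy):
        return np.where(self._mask, dy, dy.dtype.type(0.0))


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis (stride == size)."""

    def __init__(self, size: int) -> None:
        super().__init__()
        self.size = size

    def forward(self, x, train, rng=None):
        n, L, c = x.shape
        if L % self.size:
            raise ValueError(f"length {L} not divisible by pool size {self.size}")
        xr = x.reshape(n, L // self.size, self.size, c)
        self._argmax = xr.argmax(axis=2)
        self._shape = (n, L, c)
        return np.take_along_axis(xr, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        n, L, c = self._shape
        dxr = np.zeros((n, L // self.size, self.size, c), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        return dxr.reshape(n, L, c)


class Flatten(Layer):
    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / f_in)
        self.params["w"] = (rng.standard_normal((f_in, f_out)) * scale).astype(_F32)
        self.params["b"] = np.zeros(f_out, dtype=_F32)
        self.zero_grads()

    def forward(self, x, train, rng=None):
        self._x = x
        return self._x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        self.grads["w"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["w"].T


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(_F32) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x, train, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()


class Adam:
    """Adam optimizer over a list of (layer, param-key) handles."""

    def __init__(self, handles: list[tuple[Layer, str]], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.handles = handles
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[k]) for layer, k in handles]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in handles]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for i, (layer, k) in enumerate(self.handles):
            g = layer.grads[k]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            layer.params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_F32)
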