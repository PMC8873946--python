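"""Minimal NumPy layers with explicit forward/backward passes.

All tensors are float32 NCHW.  Each layer caches what its backward pass needs;
`params()` exposes (name, value, grad) triples for the optimizer.  Convolution
uses one GEMM per kernel offset, which keeps memory proportional to the input
instead of the im2col matrix — important for whole-image inference.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[tuple[str, Param]]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, zero 'same' padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Param(rng.normal(0.0, scale, size=(c_out, c_in, k, k)))
        self.bias = Param(np.zeros(c_out))
        self._xp: np.ndarray | None = None

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x, train):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp
        self._shape = (n, c, h, w)
        out = np.empty((n, self.c_out, h * w), dtype=np.float32)
        out[:] = self.bias.value[None, :, None]
        wv = self.weight.value
        for ky in range(self.k):
            for kx in range(self.k):
                xs = xp[:, :, ky : ky + h, kx : kx + w].reshape(n, c, h * w)
                out += np.matmul(wv[:, :, ky, kx][None], xs)
        return out.reshape(n, self.c_out, h, w)

    def backward(self, grad):
        n, c, h, w = self._shape
        p = self.k // 2
        xp = self._xp
        g2 = grad.reshape(n, self.c_out, h * w)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        wv = self.weight.value
        for ky in range(self.k):
            for kx in range(self.k):
                xs = xp[:, :, ky : ky + h, kx : kx + w].reshape(n, c, h * w)
                self.weight.grad[:, :, ky, kx] += np.matmul(
                    g2, xs.transpose(0, 2, 1)
                ).sum(axis=0)
                dxs = np.matmul(wv[:, :, ky, kx].T[None], g2)
                dxp[:, :, ky : ky + h, kx : kx + w] += dxs.reshape(n, c, h, w)
        self._xp = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivstd[None, :, None, None]
        if train:
            self._cache = (xhat, ivstd)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, grad):
        xhat, ivstd = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.gamma.value[None, :, None, None]
        # standard batchnorm gradient
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * ivstd[None, :, None, None]
        self._cache = None
        return dx.astype(np.float32)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input sides must be even."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # split gradient evenly across ties for determinism
        self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self._shape = (n, c, h, w)
        return out

    def backward(self, grad):
        n, c, h, w = self._shape
        dxr = self._mask * grad[:, :, :, None, :, None]
        self._mask = None
        return dxr.reshape(n, c, h, w).astype(np.float32)


def _up2_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """Factor-2 bilinear upsampling along one axis (half-pixel centers)."""
    xm = np.moveaxis(x, axis, -1)
    left = np.concatenate([xm[..., :1], xm[..., :-1]], axis=-1)
    right = np.concatenate([xm[..., 1:], xm[..., -1:]], axis=-1)
    out = np.empty(xm.shape[:-1] + (2 * xm.shape[-1],), dtype=xm.dtype)
    out[..., 0::2] = 0.75 * xm + 0.25 * left
    out[..., 1::2] = 0.75 * xm + 0.25 * right
    return np.moveaxis(out, -1, axis)


def _down2_axis_grad(g: np.ndarray, axis: int) -> np.ndarray:
    """Transpose (adjoint) of `_up2_axis` for the backward pass."""
    gm = np.moveaxis(g, axis, -1)
    ge = gm[..., 0::2]
    go = gm[..., 1::2]
    dx = 0.75 * ge + 0.75 * go
    dx[..., :-1] += 0.25 * ge[..., 1:]
    dx[..., 0] += 0.25 * ge[..., 0]
    dx[..., 1:] += 0.25 * go[..., :-1]
    dx[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(dx, -1, axis)


class BilinearUp2(Layer):
    def forward(self, x, train):
        return _up2_axis(_up2_axis(x, 2), 3)

    def backward(self, grad):
        return _down2_axis_grad(_down2_axis_grad(grad, 3), 2).astype(np.float32)


class SGD:
    """Plain SGD with optional momentum."""

    def __init__(self, params: list[tuple[str, Param]], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.buffers = [np.zeros_like(p.value) for _, p in params]

    def zero_grad(self):
        for _, p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for buf, (_, p) in zip(self.buffers, self.params):
            buf *= self.momentum
            buf += p.grad
            p.value -= self.lr * buf
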