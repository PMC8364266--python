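"""Minimal CPU neural-network primitives (NHWC, NumPy).

Implements exactly the layers the translation network needs — 2-D
convolution with "same" padding, batch normalization, ReLU, 2x2 max pooling,
2x2 transposed convolution — with explicit forward/backward passes and an
Adam optimizer.  Activations are kept channels-last (B, H, W, C): every
convolution then reduces to one im2col patch-matrix copy plus a single BLAS
matmul, and the backward data pass is itself a convolution with the
spatially flipped, channel-transposed kernel, so no scatter (col2im) is
needed anywhere.

All layers operate in the dtype of their parameters (float32 by default;
float64 is used by the finite-difference gradient checks).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, H, W, C) -> (B*H*W, k*k*C) patch matrix for a same-padded conv."""
    b, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    sb, sh, sw, sc = xp.strides
    windows = as_strided(
        xp,
        shape=(b, h, w, k, k, c),
        strides=(sb, sh, sw, sh, sw, sc),
        writeable=False,
    )
    return np.ascontiguousarray(windows).reshape(b * h * w, k * k * c)


def _conv_same(x: np.ndarray, weight: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padding cross-correlation.

    ``weight`` has shape (k, k, C_in, C_out).  Returns (output, cached patch
    matrix) — the cache is reused for the weight gradient.
    """
    b, h, w, c_in = x.shape
    k, _, _, c_out = weight.shape
    if k == 1:  # pointwise conv: the patch matrix is the input itself
        cols = x.reshape(b * h * w, c_in)
    else:
        cols = _im2col(x, k)
    out = (cols @ weight.reshape(-1, c_out)).reshape(b, h, w, c_out)
    return out, cols


class Layer:
    """Base: parameters as a list of arrays, grads aligned with them."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, same padding, with bias."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype=np.float32):
        if k % 2 != 1:
            raise ValueError("same-padding convolution needs an odd kernel")
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init for ReLU stacks
        self.weight = (scale * rng.standard_normal((k, k, c_in, c_out))).astype(dtype)
        self.bias = np.zeros(c_out, dtype=dtype)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self.k = k
        self._cols: np.ndarray | None = None

    def params(self):
        return [self.weight, self.bias]

    def grads(self):
        return [self.dweight, self.dbias]

    def forward(self, x, train=True):
        out, cols = _conv_same(x, self.weight)
        self._cols = cols if train else None
        return out + self.bias

    def backward(self, dout):
        b, h, w, c_out = dout.shape
        dmat = dout.reshape(-1, c_out)
        self.dweight[...] = (self._cols.T @ dmat).reshape(self.dweight.shape)
        self.dbias[...] = dmat.sum(axis=0)
        # Backward data = conv with channel-transposed, spatially flipped kernel.
        w_t = np.ascontiguousarray(self.weight[::-1, ::-1].transpose(0, 1, 3, 2))
        dx, _ = _conv_same(dout, w_t)
        self._cols = None
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv_std = self._cache
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 1, 2))
        self.dbeta[...] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma
        mean_dxhat = dxhat.mean(axis=(0, 1, 2))
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 1, 2))
        dx = inv_std * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        self._cache = None
        return dx


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x, train=True):
        mask = x > 0
        self._mask = mask if train else None
        return x * mask

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train=True):
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = (
            x.reshape(b, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h // 2, w // 2, 4, c)
        )
        idx = xr.argmax(axis=3)
        out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        idx, (b, h, w, c) = self._cache
        dxr = np.zeros((b, h // 2, w // 2, 4, c), dtype=dout.dtype)
        np.put_along_axis(dxr, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = (
            dxr.reshape(b, h // 2, w // 2, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h, w, c)
        )
        self._cache = None
        return dx


class UpConv2x2(Layer):
    """Transposed convolution, kernel 2, stride 2 (non-overlapping)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / (c_in * 4))
        self.weight = (scale * rng.standard_normal((2, 2, c_in, c_out))).astype(dtype)
        self.bias = np.zeros(c_out, dtype=dtype)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.weight, self.bias]

    def grads(self):
        return [self.dweight, self.dbias]

    def _w2(self) -> np.ndarray:
        """Kernel rearranged to (c_in, 4 * c_out), the (u, v) pair flattened."""
        c_in, c_out = self.weight.shape[2], self.weight.shape[3]
        return self.weight.transpose(2, 0, 1, 3).reshape(c_in, 4 * c_out)

    def forward(self, x, train=True):
        b, h, w, c_in = x.shape
        c_out = self.weight.shape[3]
        # y[b, 2i+u, 2j+v, o] = sum_c x[b, i, j, c] * W[u, v, c, o]
        y = (x.reshape(-1, c_in) @ self._w2()).reshape(b, h, w, 2, 2, c_out)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(b, 2 * h, 2 * w, c_out)
        self._x = x if train else None
        return y + self.bias

    def backward(self, dout):
        b, h2, w2, c_out = dout.shape
        h, w = h2 // 2, w2 // 2
        c_in = self.weight.shape[2]
        dr = (
            dout.reshape(b, h, 2, w, 2, c_out)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b * h * w, 4 * c_out)
        )
        xm = self._x.reshape(-1, c_in)
        dw2 = xm.T @ dr  # (c_in, 4*c_out)
        self.dweight[...] = dw2.reshape(c_in, 2, 2, c_out).transpose(1, 2, 0, 3)
        self.dbias[...] = dout.sum(axis=(0, 1, 2))
        dx = (dr @ self._w2().T).reshape(b, h, w, c_in)
        self._x = None
        return dx


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr=1e-3, beta1=0.975, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
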