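"""Minimal 3D CNN building blocks on NumPy, with backprop.

A compact CPU engine sufficient for desk-scale volumetric extractors:
3D convolution (im2col + matmul), batch normalization, ReLU, 2x max
pooling, global average pooling, a linear head, softmax cross-entropy and
Adam. Layers expose ``forward(x, train)`` / ``backward(dout)`` and collect
``(param, grad)`` pairs; everything is float32 and deterministic given the
initialization RNG.

Tensor layout is (batch, channels, depth, height, width).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def params(self) -> list[list]:
        """List of [param_array, grad_array] pairs (mutated in place)."""
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """k^3 convolution with 'same' padding and integer stride."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        fan_in = c_in * kernel ** 3
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.w = (rng.standard_normal((c_out, fan_in)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2

    def params(self):
        return [[self.w, self.dw], [self.b, self.db]]

    def _out_shape(self, d: int) -> int:
        return (d + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x, train):
        b, c, *sp = x.shape
        p, s, k = self.pad, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        win = win[:, :, ::s, ::s, ::s]  # (B,C,D',H',W',k,k,k)
        out_sp = win.shape[2:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
            b * int(np.prod(out_sp)), c * k ** 3)
        self._cols = cols
        self._x_shape = x.shape
        self._out_sp = out_sp
        out = cols @ self.w.T + self.b
        return np.ascontiguousarray(
            out.reshape(b, *out_sp, self.c_out).transpose(0, 4, 1, 2, 3))

    def backward(self, dout):
        b = dout.shape[0]
        k, s, p = self.k, self.stride, self.pad
        dflat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, self.c_out)
        self.dw[...] = (dflat.T @ self._cols).astype(np.float32)
        self.db[...] = dflat.sum(0).astype(np.float32)
        dcols = (dflat @ self.w).reshape(b, *self._out_sp, self.c_in, k, k, k)
        dcols = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)  # (B,C,D',H',W',k,k,k)
        _, _, d, h, w = self._x_shape
        dxp = np.zeros((b, self.c_in, d + 2 * p, h + 2 * p, w + 2 * p),
                       dtype=np.float32)
        od, oh, ow = self._out_sp
        for a in range(k):
            for bb in range(k):
                for cc in range(k):
                    dxp[:, :, a:a + s * od:s, bb:bb + s * oh:s, cc:cc + s * ow:s] += \
                        dcols[..., a, bb, cc]
        return dxp[:, :, p:p + d, p:p + h, p:p + w]


class BatchNorm3d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [[self.gamma, self.dgamma], [self.beta, self.dbeta]]

    def forward(self, x, train):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._xhat, self._inv, self._n = xhat, inv, x.size // x.shape[1]
        return (self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)).astype(np.float32)

    def backward(self, dout):
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        xhat, inv, n = self._xhat, self._inv, self._n
        self.dgamma[...] = (dout * xhat).sum(axis=axes).astype(np.float32)
        self.dbeta[...] = dout.sum(axis=axes).astype(np.float32)
        dxhat = dout * self.gamma.reshape(shape)
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)) * inv.reshape(shape)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool3d(Layer):
    """2x2x2 max pooling (floor division; trailing odd voxels dropped)."""

    def forward(self, x, train):
        b, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xt = x[:, :, :2 * d2, :2 * h2, :2 * w2]
        win = xt.reshape(b, c, d2, 2, h2, 2, w2, 2)
        out = win.max(axis=(3, 5, 7))
        self._win_shape = win.shape
        self._x_shape = x.shape
        self._mask = win == out[:, :, :, None, :, None, :, None]
        return out

    def backward(self, dout):
        grad = self._mask * dout[:, :, :, None, :, None, :, None]
        b, c, d, h, w = self._x_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        dx = np.zeros(self._x_shape, dtype=np.float32)
        dx[:, :, :2 * d2, :2 * h2, :2 * w2] = grad.reshape(b, c, 2 * d2, 2 * h2, 2 * w2)
        return dx


class AvgPool3d(Layer):
    """2x2x2 average pooling (floor division)."""

    def forward(self, x, train):
        b, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xt = x[:, :, :2 * d2, :2 * h2, :2 * w2]
        self._x_shape = x.shape
        return xt.reshape(b, c, d2, 2, h2, 2, w2, 2).mean(axis=(3, 5, 7))

    def backward(self, dout):
        b, c, d, h, w = self._x_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        dx = np.zeros(self._x_shape, dtype=np.float32)
        g = np.broadcast_to(
            dout[:, :, :, None, :, None, :, None] / 8.0,
            (b, c, d2, 2, h2, 2, w2, 2),
        )
        dx[:, :, :2 * d2, :2 * h2, :2 * w2] = g.reshape(b, c, 2 * d2, 2 * h2, 2 * w2)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._x_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout):
        b, c, d, h, w = self._x_shape
        return np.broadcast_to(
            dout[:, :, None, None, None] / (d * h * w), self._x_shape
        ).astype(np.float32)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / n_in)
        self.w = (rng.standard_normal((n_out, n_in)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [[self.w, self.dw], [self.b, self.db]]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout):
        self.dw[...] = (dout.T @ self._x).astype(np.float32)
        self.db[...] = dout.sum(0).astype(np.float32)
        return dout @ self.w


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[list], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] += (1 - self.b1) * (g - self.m[i])
            self.v[i] += (1 - self.b2) * (g * g - self.v[i])
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
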