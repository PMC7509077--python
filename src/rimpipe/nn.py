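"""Minimal NumPy engine for small 3D convolutional networks.

Implements exactly the pieces the rim-classification architecture needs:
3D 'same' convolution (im2col + GEMM), batch normalisation, tanh,
2x2x2 max-pooling with floor division on odd extents, dense layers, a
softmax cross-entropy head, Xavier initialisation and the Adam optimiser.
Tensors are laid out ``(batch, channels, depth, height, width)`` in
float32.  Forward passes cache what the analytic backward pass needs;
gradients are exercised against numerical differentiation in the test
suite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
DTYPE = np.float32


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, D, H, W) -> (B, C*27, D*H*W) for a 3^3 'same' window.

    Built by 27 contiguous slab copies of the zero-padded input, which is
    far cheaper than a permuted gather at these sizes.
    """
    B, C, D, H, W = x.shape
    xp = np.zeros((B, C, D + 2, H + 2, W + 2), dtype=DTYPE)
    xp[:, :, 1:-1, 1:-1, 1:-1] = x
    col = np.empty((B, C, 27, D, H, W), dtype=DTYPE)
    k = 0
    for dz in range(3):
        for dy in range(3):
            for dx in range(3):
                col[:, :, k] = xp[:, :, dz:dz + D, dy:dy + H, dx:dx + W]
                k += 1
    return col.reshape(B, C * 27, D * H * W)


class Conv3dSame(Layer):
    """3x3x3 convolution with unit zero-padding (spatial size preserved).

    ``input_grad=False`` marks an input layer whose backward pass does not
    need the gradient with respect to its input.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 input_grad: bool = True):
        self.c_in, self.c_out = c_in, c_out
        self.input_grad = input_grad
        w = xavier_uniform(rng, (c_out, c_in, 3, 3, 3),
                           fan_in=c_in * 27, fan_out=c_out * 27)
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(c_out, dtype=DTYPE))
        self._col: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, D, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {C}")
        col = _im2col(x)
        wm = self.w.value.reshape(self.c_out, -1)
        out = np.matmul(wm, col)                   # (B, c_out, P)
        out += self.b.value[:, None]
        if training:
            self._col, self._xshape = col, x.shape
        return out.reshape(B, self.c_out, D, H, W)

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, _, D, H, W = self._xshape
        gm = g.reshape(B, self.c_out, -1)
        # batched GEMM then reduce over the batch axis
        dw = np.matmul(gm, self._col.transpose(0, 2, 1)).sum(axis=0)
        self.w.grad += dw.reshape(self.w.value.shape)
        self.b.grad += gm.sum(axis=(0, 2))
        self._col = None
        if not self.input_grad:
            return np.zeros(self._xshape, dtype=DTYPE)
        # gradient w.r.t. input: correlate g with the spatially flipped,
        # channel-transposed kernel (itself a 'same' convolution)
        wb = self.w.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        gcol = _im2col(np.ascontiguousarray(gm.reshape(g.shape)))
        dx = np.matmul(wb.reshape(self.c_in, -1), gcol)
        return dx.reshape(self._xshape)


class BatchNorm3d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        if training:
            self._cache = (xhat, invstd)
        return (self.gamma.value.reshape(shape) * xhat
                + self.beta.value.reshape(shape)).astype(DTYPE)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        n = g.shape[0] * g.shape[2] * g.shape[3] * g.shape[4]
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        coeff = (self.gamma.value * invstd / n).reshape(shape)
        return (coeff * (n * g - dbeta.reshape(shape)
                         - xhat * dgamma.reshape(shape))).astype(DTYPE)


class Tanh(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.tanh(x)
        self._out = out if training else None
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        out, self._out = self._out, None
        return (g * (1.0 - out * out)).astype(DTYPE)


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2; odd trailing planes are dropped
    (floor division), so 28 -> 14 -> 7 -> 3."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, D, H, W = x.shape
        d, h, w = D // 2, H // 2, W // 2
        xc = x[:, :, :d * 2, :h * 2, :w * 2]
        r = xc.reshape(B, C, d, 2, h, 2, w, 2)
        r = np.ascontiguousarray(r.transpose(0, 1, 2, 4, 6, 3, 5, 7))
        r = r.reshape(B, C, d, h, w, 8)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (x.shape, idx)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        (B, C, D, H, W), idx = self._cache
        self._cache = None
        d, h, w = D // 2, H // 2, W // 2
        r = np.zeros((B, C, d, h, w, 8), dtype=DTYPE)
        np.put_along_axis(r, idx[..., None], g[..., None], axis=-1)
        r = r.reshape(B, C, d, h, w, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dx = np.zeros((B, C, D, H, W), dtype=DTYPE)
        dx[:, :, :d * 2, :h * 2, :w * 2] = r.reshape(B, C, d * 2, h * 2, w * 2)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Parameter(xavier_uniform(rng, (n_out, n_in), n_in, n_out))
        self.b = Parameter(np.zeros(n_out, dtype=DTYPE))

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x if training else None
        return x @ self.w.value.T + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        self.w.grad += g.T @ x
        self.b.grad += g.sum(axis=0)
        return (g @ self.w.value).astype(DTYPE)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy loss, gradient w.r.t. logits, class probabilities."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(probs[np.arange(n), labels] + eps).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(DTYPE), probs


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad * p.grad
            p.value -= (self.lr * (m / b1t)
                        / (np.sqrt(v / b2t) + self.eps)).astype(DTYPE)
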