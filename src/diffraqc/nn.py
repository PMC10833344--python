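"""A small, self-contained neural-network layer library on numpy.

Implements exactly what the quadrant models need — 2-D convolution, batch
normalization, rectified linear units, dropout, pooling, fully connected
layers — with explicit forward/backward passes and a stochastic
gradient-descent optimizer with momentum and weight decay.  Everything is
deterministic given a seeded ``numpy.random.Generator`` on one thread.

Convolutions use an im2col lowering: patches are gathered with
``sliding_window_view`` and the contraction is a single BLAS matmul, which
keeps desk-scale training fast on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Conv2d", "BatchNorm2d", "ReLU", "Dropout",
    "BlockMeanPool", "GlobalAvgPool", "Flatten", "Linear", "Sequential",
    "SGD",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Layer):
    """2-D convolution, NCHW layout, square kernel, zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int = 0, bias: bool = False, *,
                 rng: np.random.Generator, name: str = "conv"):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride, self.pad = stride, pad
        self.weight = Param(_he_init(rng, (c_out, c_in, k, k), c_in * k * k),
                            name + ".weight")
        self.bias = Param(np.zeros(c_out), name + ".bias") if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias else [])

    def forward(self, x, train=False):
        s, k, p = self.stride, self.k, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        b, c, h, w = x.shape
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        # (B, C, Ho, Wo, k, k) view, then one matmul
        cols = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))
        flat = cols.reshape(b * ho * wo, c * k * k)
        wmat = self.weight.value.reshape(self.c_out, c * k * k)
        out = flat @ wmat.T
        if self.bias:
            out += self.bias.value
        self._cache = (flat, x.shape, (b, ho, wo))
        return out.reshape(b, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, gout):
        flat, xshape, (b, ho, wo) = self._cache
        s, k, p = self.stride, self.k, self.pad
        c = self.c_in
        g = np.ascontiguousarray(gout.transpose(0, 2, 3, 1)).reshape(b * ho * wo, self.c_out)
        self.weight.grad += (g.T @ flat).reshape(self.weight.value.shape)
        if self.bias:
            self.bias.grad += g.sum(axis=0)
        gflat = g @ self.weight.value.reshape(self.c_out, c * k * k)
        gcols = gflat.reshape(b, ho, wo, c, k, k)
        gx = np.zeros(xshape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gx[:, :, i:i + s * ho:s, j:j + s * wo:s] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            gx = gx[:, :, p:-p, p:-p]
        return gx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with affine scale/shift."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(c), name + ".weight")
        self.beta = Param(np.zeros(c), name + ".bias")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gout):
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        gscaled = gout * self.gamma.value[None, :, None, None]
        if not train:
            return gscaled * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        gsum = gscaled.sum(axis=(0, 2, 3))[None, :, None, None]
        gxhat_sum = (gscaled * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return inv[None, :, None, None] / m * (m * gscaled - gsum - xhat * gxhat_sum)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p, self.rng = p, rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        return gout * self._mask


class BlockMeanPool(Layer):
    """Parameter-free mean pooling over non-overlapping f x f blocks.

    Acts as a fixed downscaling stem; inputs whose spatial dims are not
    multiples of ``f`` are zero-padded at the bottom/right.
    """

    def __init__(self, f: int):
        self.f = f

    def forward(self, x, train=False):
        f = self.f
        b, c, h, w = x.shape
        ph, pw = (-h) % f, (-w) % f
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        self._shape = (b, c, h, w)
        hb, wb = x.shape[2] // f, x.shape[3] // f
        return x.reshape(b, c, hb, f, wb, f).mean(axis=(3, 5))

    def backward(self, gout):
        f = self.f
        b, c, h, w = self._shape
        g = np.repeat(np.repeat(gout, f, axis=2), f, axis=3) / (f * f)
        return g[:, :, :h, :w]


class MaxPool2d(Layer):
    """Max pooling with square window, stride and zero padding."""

    def __init__(self, k: int, stride: int, pad: int = 0):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train=False):
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                       constant_values=-np.inf)
        b, c, h, w = x.shape
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        cols = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = cols.reshape(b, c, ho, wo, k * k)
        self._arg = flat.argmax(axis=-1)
        self._geom = (x.shape, (b, c, ho, wo))
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gout):
        k, s, p = self.k, self.stride, self.pad
        xshape, (b, c, ho, wo) = self._geom
        gx = np.zeros(xshape, dtype=np.float32)
        ki, kj = np.divmod(self._arg, k)
        bi, ci, hi, wi = np.indices((b, c, ho, wo), sparse=False)
        np.add.at(gx, (bi, ci, hi * s + ki, wi * s + kj), gout)
        if p:
            gx = gx[:, :, p:-p, p:-p]
        return gx


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        b, c, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None] / (h * w), self._shape).copy()


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator,
                 bias: bool = True, name: str = "fc"):
        self.weight = Param(_he_init(rng, (n_out, n_in), n_in), name + ".weight")
        self.bias = Param(np.zeros(n_out), name + ".bias") if bias else None
        self._x = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias else [])

    def forward(self, x, train=False):
        self._x = x
        out = x @ self.weight.value.T
        if self.bias:
            out += self.bias.value
        return out

    def backward(self, gout):
        self.weight.grad += gout.T @ self._x
        if self.bias:
            self.bias.grad += gout.sum(axis=0)
        return gout @ self.weight.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


class SGD:
    """Stochastic gradient descent with momentum and weight decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._velocity = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v
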