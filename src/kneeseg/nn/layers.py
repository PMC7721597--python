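"""Minimal numpy layer library with hand-written backward passes.

Implements exactly the blocks the image-to-image networks need: strided 2D
convolutions (im2col), transposed convolutions (the convolution adjoint),
batch normalisation and the usual pointwise activations.  Every layer caches
what its backward pass needs during ``forward`` and accumulates parameter
gradients into ``Parameter.grad``.

Tensors are NCHW float64 throughout; batch size is typically 1 (which makes
batch norm behave like instance norm, matching the training regime used for
the segmentation networks).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _im2col(x: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    n, c, h, w = x.shape
    ho = (h - k) // s + 1
    wo = (w - k) // s + 1
    sn, sc, sh, sw = x.strides
    win = as_strided(x, (n, c, k, k, ho, wo), (sn, sc, sh, sw, sh * s, sw * s))
    return win.reshape(n, c * k * k, ho * wo)


def _col2im(cols: np.ndarray, xshape, k: int, s: int, p: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patches back onto the image grid."""
    n, c, h, w = xshape
    hp, wp = h + 2 * p, w + 2 * p
    ho = (hp - k) // s + 1
    wo = (wp - k) // s + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + s * ho:s, j:j + s * wo:s] += cols[:, :, i, j]
    if p:
        out = out[:, :, p:hp - p, p:wp - p]
    return out


class Layer:
    """Base class: forward caches, backward returns grad w.r.t. input."""

    training = True

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 init_std: float = 0.02):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, padding
        self.weight = Parameter(rng.normal(0.0, init_std,
                                           (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))
        self._cols = None
        self._xshape = None

    def parameters(self):
        return [self.weight, self.bias]

    def out_size(self, h: int) -> int:
        return (h + 2 * self.p - self.k) // self.s + 1

    def forward(self, x):
        n, _, h, w = x.shape
        cols = _im2col(x, self.k, self.s, self.p)
        self._cols, self._xshape = cols, x.shape
        wmat = self.weight.value.reshape(self.out_ch, -1)
        y = np.einsum("of,nfl->nol", wmat, cols, optimize=True)
        ho, wo = self.out_size(h), self.out_size(w)
        return y.reshape(n, self.out_ch, ho, wo) + self.bias.value[None, :, None, None]

    def backward(self, gy):
        n = gy.shape[0]
        gmat = gy.reshape(n, self.out_ch, -1)
        self.bias.grad += gmat.sum(axis=(0, 2))
        self.weight.grad += np.einsum("nol,nfl->of", gmat, self._cols,
                                      optimize=True).reshape(self.weight.value.shape)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        gcols = np.einsum("of,nol->nfl", wmat, gmat, optimize=True)
        return _col2im(gcols, self._xshape, self.k, self.s, self.p)


class ConvTranspose2d(Layer):
    """Fractionally-strided convolution; forward is the adjoint of Conv2d."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 init_std: float = 0.02):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, padding
        self.weight = Parameter(rng.normal(0.0, init_std,
                                           (in_ch, out_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))
        self._x = None
        self._gycols = None

    def parameters(self):
        return [self.weight, self.bias]

    def out_size(self, h: int) -> int:
        return (h - 1) * self.s - 2 * self.p + self.k

    def forward(self, x):
        self._x = x
        n, _, h, w = x.shape
        ho, wo = self.out_size(h), self.out_size(w)
        xmat = x.reshape(n, self.in_ch, h * w)
        wmat = self.weight.value.reshape(self.in_ch, -1)  # (Cin, Cout*k*k)
        cols = np.einsum("if,nil->nfl", wmat, xmat, optimize=True)
        y = _col2im(cols, (n, self.out_ch, ho, wo), self.k, self.s, self.p)
        return y + self.bias.value[None, :, None, None]

    def backward(self, gy):
        n, _, h, w = self._x.shape
        self.bias.grad += gy.sum(axis=(0, 2, 3))
        gycols = _im2col(gy, self.k, self.s, self.p)  # (N, Cout*k*k, H*W)
        xmat = self._x.reshape(n, self.in_ch, h * w)
        self.weight.grad += np.einsum("nil,nfl->if", xmat, gycols,
                                      optimize=True).reshape(self.weight.value.shape)
        wmat = self.weight.value.reshape(self.in_ch, -1)
        gx = np.einsum("if,nfl->nil", wmat, gycols, optimize=True)
        return gx.reshape(self._x.shape)


class BatchNorm2d(Layer):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, gy):
        xhat, inv = self._cache
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not self.training:
            return gy * g * inv[None, :, None, None]
        gxhat = gy * g
        term = (gxhat - gxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m)
        return term * inv[None, :, None, None]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy):
        return gy * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; off unless p > 0 and training."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x):
        if not self.training or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Identity(Layer):
    def forward(self, x):
        return x

    def backward(self, gy):
        return gy


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for l in self.layers:
            if isinstance(l, Sequential):
                l.set_training(flag)
            else:
                l.training = flag

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy
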