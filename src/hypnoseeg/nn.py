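"""Minimal NumPy neural-network layers with hand-written backprop.

Implements exactly the pieces the classifier zoo needs: temporal 2-D
convolution (kernels of shape (1, k) over a channels x time map), depthwise
convolution with a per-channel depth multiplier, batch normalization, ELU,
average pooling over time, dropout, dense layers, and softmax cross-entropy
with class weights, plus an Adam optimizer. Convolutions are lowered to
BLAS matmuls via im2col, which keeps full-batch training of the compact
EEG models to seconds on one CPU.

All layers follow the same contract: ``forward(x, train)`` caches whatever
``backward(grad_out)`` needs; ``backward`` accumulates parameter gradients
in ``Param.grad`` and returns the input gradient.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError

DTYPE = np.float64


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "", dtype=None):
        self.value = np.asarray(value, dtype=dtype or DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class TemporalConv2d(Layer):
    """Conv over (n, c_in, h, t) with kernel (1, k) and time padding.

    ``is_first`` marks the network's input layer, whose input gradient is
    never consumed and therefore skipped.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, pad: int, rng, dtype=None):
        self.in_ch, self.out_ch, self.k, self.pad = in_ch, out_ch, k, pad
        self.is_first = False
        scale = np.sqrt(2.0 / (in_ch * k))
        self.W = Param(rng.standard_normal((out_ch, in_ch, k)) * scale, "conv.W", dtype)
        self.b = Param(np.zeros(out_ch), "conv.b", dtype)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        n, c, h, t = x.shape
        if c != self.in_ch:
            raise ValidationError(
                f"TemporalConv2d expected {self.in_ch} input channels, got {c}"
            )
        xp = np.pad(x, ((0, 0),) * 3 + ((self.pad, self.pad),)) if self.pad else x
        tw = xp.shape[3] - self.k + 1
        win = sliding_window_view(xp, self.k, axis=3)  # n,c,h,tw,k
        cols = win.transpose(0, 2, 3, 1, 4).reshape(n * h * tw, c * self.k)
        Wm = self.W.value.reshape(self.out_ch, c * self.k)
        y = cols @ Wm.T + self.b.value
        self._cache = (cols, x.shape, tw)
        return np.ascontiguousarray(
            y.reshape(n, h, tw, self.out_ch).transpose(0, 3, 1, 2)
        )

    def backward(self, g):
        cols, xshape, tw = self._cache
        n, c, h, t = xshape
        g2 = g.transpose(0, 2, 3, 1).reshape(n * h * tw, self.out_ch)
        self.W.grad += (g2.T @ cols).reshape(self.W.value.shape)
        self.b.grad += g2.sum(axis=0)
        if self.is_first:
            return None
        gcols = (g2 @ self.W.value.reshape(self.out_ch, -1)).reshape(
            n, h, tw, c, self.k
        ).transpose(0, 3, 1, 2, 4)  # n,c,h,tw,k
        gxp = np.zeros((n, c, h, t + 2 * self.pad), dtype=g.dtype)
        for kk in range(self.k):
            gxp[:, :, :, kk : kk + tw] += gcols[:, :, :, :, kk]
        return gxp[:, :, :, self.pad : self.pad + t] if self.pad else gxp


class DepthwiseTemporalConv2d(Layer):
    """Per-channel (grouped, groups = in_ch) conv with depth multiplier.

    Kernel (1, k), valid mode (no padding): time length t -> t - k + 1.
    Output channel c*mult + m is input channel c convolved with its m-th
    kernel.
    """

    def __init__(self, in_ch: int, mult: int, k: int, rng, dtype=None):
        self.in_ch, self.mult, self.k = in_ch, mult, k
        scale = np.sqrt(2.0 / k)
        self.W = Param(rng.standard_normal((in_ch, k, mult)) * scale, "dwconv.W", dtype)
        self.b = Param(np.zeros(in_ch * mult), "dwconv.b", dtype)

    @property
    def out_ch(self) -> int:
        return self.in_ch * self.mult

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        n, c, h, t = x.shape
        if c != self.in_ch:
            raise ValidationError(
                f"DepthwiseTemporalConv2d expected {self.in_ch} channels, got {c}"
            )
        tw = t - self.k + 1
        if tw < 1:
            raise ValidationError(
                f"time length {t} shorter than depthwise kernel {self.k}"
            )
        # shift-and-add over the (small) kernel: avoids materializing the
        # k-times-larger im2col tensor
        W = self.W.value
        y = np.zeros((n, c, self.mult, h, tw), dtype=x.dtype)
        for kk in range(self.k):
            y += x[:, :, None, :, kk : kk + tw] * W[None, :, kk, :, None, None]
        y = y.reshape(n, c * self.mult, h, tw) + self.b.value[None, :, None, None]
        self._cache = (x, tw)
        return y

    def backward(self, g):
        x, tw = self._cache
        n, c, h, t = x.shape
        g5 = g.reshape(n, c, self.mult, h, tw)
        self.b.grad += g.sum(axis=(0, 2, 3))
        W = self.W.value
        # batched matmuls: channel-major layouts so BLAS does the reductions
        g3 = np.ascontiguousarray(g5.transpose(1, 0, 3, 4, 2)).reshape(
            c, n * h * tw, self.mult
        )
        xt = np.ascontiguousarray(x.transpose(1, 0, 2, 3))  # c,n,h,t
        gx = np.zeros_like(x)
        for kk in range(self.k):
            xk = xt[:, :, :, kk : kk + tw].reshape(c, 1, n * h * tw)
            self.W.grad[:, kk, :] += (xk @ g3)[:, 0, :]
            gx[:, :, :, kk : kk + tw] += np.einsum(
                "ncmht,cm->ncht", g5, W[:, kk, :]
            )
        return gx


class BatchNorm(Layer):
    """Batch normalization over all axes except the feature axis.

    ``feature_axis=1`` covers both the (n, features) dense case and the
    (n, c, h, t) convolutional case. Training mode uses biased batch
    statistics (1/m) and updates exponential running statistics; eval mode
    normalizes with the running statistics.
    """

    def __init__(
        self, n_features: int, eps: float = 1e-5, momentum: float = 0.1, dtype=None
    ):
        if not eps > 0:
            raise ValidationError("batch-norm eps must be positive")
        self.n_features = n_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(n_features), "bn.gamma", dtype)
        self.beta = Param(np.zeros(n_features), "bn.beta", dtype)
        self.running_mean = np.zeros(n_features, dtype=dtype or DTYPE)
        self.running_var = np.ones(n_features, dtype=dtype or DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def _shape(self, x):
        shape = [1] * x.ndim
        shape[1 if x.ndim > 1 else 0] = self.n_features
        return tuple(shape)

    def forward(self, x, train):
        axis = tuple(i for i in range(x.ndim) if i != (1 if x.ndim > 1 else 0))
        m = x.size // self.n_features
        shape = self._shape(x)
        if train:
            if m < 2:
                raise ValidationError(
                    "batch normalization needs at least 2 samples per "
                    "feature in train mode"
                )
            mu = x.mean(axis=axis)
            var = x.var(axis=axis)  # biased, 1/m
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(shape)) * inv_std.reshape(shape)
        self._cache = (xhat, inv_std, axis, shape, m, train)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, g):
        xhat, inv_std, axis, shape, m, train = self._cache
        self.gamma.grad += (g * xhat).sum(axis=axis)
        self.beta.grad += g.sum(axis=axis)
        gxhat = g * self.gamma.value.reshape(shape)
        if not train:
            return gxhat * inv_std.reshape(shape)
        term = (
            gxhat
            - gxhat.mean(axis=axis, keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=axis, keepdims=True)
        )
        return term * inv_std.reshape(shape)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train):
        pos = x > 0
        y = np.where(pos, x, self.alpha * np.expm1(np.minimum(x, 0)))
        self._cache = (pos, y)
        return y

    def backward(self, g):
        pos, y = self._cache
        return g * np.where(pos, np.asarray(1.0, dtype=g.dtype), y + self.alpha)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class AvgPoolTime(Layer):
    """Average pooling (1, p) over the time axis, floor division."""

    def __init__(self, p: int):
        self.p = p

    def forward(self, x, train):
        n, c, h, t = x.shape
        tw = t // self.p
        self._tshape = x.shape
        y = x[..., : tw * self.p].reshape(n, c, h, tw, self.p).mean(axis=-1)
        return y

    def backward(self, g):
        n, c, h, t = self._tshape
        tw = t // self.p
        gx = np.zeros(self._tshape, dtype=g.dtype)
        gx[..., : tw * self.p] = np.repeat(g / self.p, self.p, axis=-1)
        return gx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, p: float, rng):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (
            (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        ).astype(x.dtype)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng, dtype=None):
        scale = np.sqrt(2.0 / d_in)
        self.W = Param(rng.standard_normal((d_out, d_in)) * scale, "dense.W", dtype)
        self.b = Param(np.zeros(d_out), "dense.b", dtype)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, g):
        self.W.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Weighted softmax cross-entropy; returns (loss, grad wrt logits)."""
    n = logits.shape[0]
    p = softmax(logits)
    w = (
        np.ones(n, dtype=logits.dtype)
        if class_weights is None
        else np.asarray(class_weights, dtype=logits.dtype)[y]
    )
    wsum = w.sum()
    loss = float(-(w * np.log(p[np.arange(n), y] + 1e-12)).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, grad


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def get_weights(model: Layer) -> list[np.ndarray]:
    out = [p.value.copy() for p in model.params()]
    for layer in getattr(model, "layers", []):
        if isinstance(layer, BatchNorm):
            out.append(layer.running_mean.copy())
            out.append(layer.running_var.copy())
    return out


def set_weights(model: Layer, weights: list[np.ndarray]) -> None:
    params = model.params()
    for p, w in zip(params, weights[: len(params)]):
        p.value = w.copy()
    extra = weights[len(params) :]
    i = 0
    for layer in getattr(model, "layers", []):
        if isinstance(layer, BatchNorm):
            layer.running_mean = extra[i].copy()
            layer.running_var = extra[i + 1].copy()
            i += 2
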