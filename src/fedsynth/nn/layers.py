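"""Minimal layer zoo with explicit forward/backward passes.

Data layout is NHWC throughout (batch, height, width, channels), matching the
(S, S, 1) image convention used by the preprocessing pipeline.  Convolutions
use TensorFlow-style ``same`` padding: for stride ``s`` the output side is
``ceil(H / s)`` and any odd padding goes on the bottom/right.

Every layer exposes

* ``params``  — dict of trainable arrays (may be empty),
* ``state``   — dict of non-trainable arrays that still travel with the
  weights (batch-norm running statistics),
* ``grads``   — gradients of the last backward pass, keyed like ``params``,
* ``forward(x, train)`` / ``backward(dy)``.

Gradients are *overwritten* (not accumulated) on each backward call.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Reshape",
    "Flatten",
    "Conv2D",
    "ConvTranspose2D",
    "BatchNorm",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
]


class Layer:
    """Base class; stateless layers only need forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(size: int, stride: int, k: int) -> tuple[int, int, int]:
    """Return (out_size, pad_begin, pad_end) for TF-style same padding."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    beg = total // 2
    return out, beg, total - beg


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N, Hp, Wp, C) padded input -> (N*oh*ow, k*k*C) patch matrix."""
    n, _, _, c = xp.shape
    cols = np.empty((n, oh, ow, k, k, c), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = xp[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :]
    return cols.reshape(n * oh * ow, k * k * c)


def _col2im(
    cols: np.ndarray,
    n: int,
    oh: int,
    ow: int,
    k: int,
    stride: int,
    hp: int,
    wp: int,
    c: int,
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back onto the padded grid."""
    xp = np.zeros((n, hp, wp, c), dtype=cols.dtype)
    cols = cols.reshape(n, oh, ow, k, k, c)
    for i in range(k):
        for j in range(k):
            xp[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :] += cols[:, :, :, i, j, :]
    return xp


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, w_std: float = 0.02):
        super().__init__()
        self.params = {
            "W": rng.normal(0.0, w_std, size=(n_in, n_out)).astype(np.float64),
            "b": np.zeros(n_out),
        }

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads = {"W": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["W"].T


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Flatten(Reshape):
    def __init__(self):
        Layer.__init__(self)

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)


class Conv2D(Layer):
    """Strided convolution with same padding (the DCGAN downsampling block)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 4, stride: int = 2, w_std: float = 0.02):
        super().__init__()
        self.k, self.stride = kernel, stride
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "W": rng.normal(0.0, w_std, size=(kernel * kernel * c_in, c_out)),
            "b": np.zeros(c_out),
        }

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"Conv2D expected {self.c_in} channels, got {c}")
        oh, pb, pe = _same_pad(h, self.stride, self.k)
        ow, qb, qe = _same_pad(w, self.stride, self.k)
        xp = np.pad(x, ((0, 0), (pb, pe), (qb, qe), (0, 0)))
        self._geom = (n, h, w, oh, ow, pb, qb, xp.shape[1], xp.shape[2])
        self._cols = _im2col(xp, self.k, self.stride, oh, ow)
        y = self._cols @ self.params["W"] + self.params["b"]
        return y.reshape(n, oh, ow, self.c_out)

    def backward(self, dy):
        n, h, w, oh, ow, pb, qb, hp, wp = self._geom
        dyf = dy.reshape(-1, self.c_out)
        self.grads = {"W": self._cols.T @ dyf, "b": dyf.sum(axis=0)}
        dcols = dyf @ self.params["W"].T
        dxp = _col2im(dcols, n, oh, ow, self.k, self.stride, hp, wp, self.c_in)
        return dxp[:, pb : pb + h, qb : qb + w, :]


class ConvTranspose2D(Layer):
    """Fractionally-strided convolution doubling (for stride 2) the spatial side.

    Implemented as the exact adjoint of :class:`Conv2D` with the same geometry,
    so output side = input side * stride.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 4, stride: int = 2, w_std: float = 0.02):
        super().__init__()
        self.k, self.stride = kernel, stride
        self.c_in, self.c_out = c_in, c_out
        # W maps k*k output-channel patches <-> input channels (conv adjoint)
        self.params = {
            "W": rng.normal(0.0, w_std, size=(kernel * kernel * c_out, c_in)),
            "b": np.zeros(c_out),
        }

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"ConvTranspose2D expected {self.c_in} channels, got {c}")
        oh, ow = h * self.stride, w * self.stride
        _, pb, pe = _same_pad(oh, self.stride, self.k)
        _, qb, qe = _same_pad(ow, self.stride, self.k)
        hp, wp = oh + pb + pe, ow + qb + qe
        self._x = x
        self._geom = (n, h, w, oh, ow, pb, qb, hp, wp)
        patches = x.reshape(n * h * w, c) @ self.params["W"].T
        yp = _col2im(patches, n, h, w, self.k, self.stride, hp, wp, self.c_out)
        return yp[:, pb : pb + oh, qb : qb + ow, :] + self.params["b"]

    def backward(self, dy):
        n, h, w, oh, ow, pb, qb, hp, wp = self._geom
        dyp = np.pad(dy, ((0, 0), (pb, hp - pb - oh), (qb, wp - qb - ow), (0, 0)))
        dpatches = _im2col(dyp, self.k, self.stride, h, w)
        xf = self._x.reshape(n * h * w, self.c_in)
        self.grads = {
            "W": dpatches.T @ xf,
            "b": dy.sum(axis=(0, 1, 2)),
        }
        return (dpatches @ self.params["W"]).reshape(n, h, w, self.c_in)


class BatchNorm(Layer):
    """Per-channel batch normalisation over (N, H, W) with running statistics.

    Running mean/var live in ``state`` so they are federated (averaged) along
    with the trainable weights, and are used at evaluation time.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.state = {"running_mean": np.zeros(channels), "running_var": np.ones(channels)}

    def forward(self, x, train=True):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.state["running_mean"] = m * self.state["running_mean"] + (1 - m) * mean
            self.state["running_var"] = m * self.state["running_var"] + (1 - m) * var
        else:
            mean = self.state["running_mean"]
            var = self.state["running_var"]
        self._axes = axes
        self._train = train
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._n = int(np.prod([x.shape[a] for a in axes]))
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        axes = self._axes
        self.grads = {
            "gamma": (dy * self._xhat).sum(axis=axes),
            "beta": dy.sum(axis=axes),
        }
        g = self.params["gamma"]
        if not self._train:
            return dy * g / self._std
        n = self._n
        dxhat = dy * g
        # standard batch-norm backward through batch statistics
        return (
            dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)
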