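"""Layers with forward/backward passes on plain numpy arrays.

Conventions: ``forward(x, train)`` caches whatever ``backward(dy)`` needs;
``backward`` returns the gradient w.r.t. the input and accumulates parameter
gradients into ``Param.grad``. Convolutions use NCHW layout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[Param]:
        return []


def glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng=None, bias: bool = True):
        rng = rng or np.random.default_rng(0)
        self.W = Param(glorot(rng, (d_in, d_out), d_in, d_out), "W")
        self.b = Param(np.zeros(d_out), "b") if bias else None

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        if self.b is not None:
            self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    @property
    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train=False):
        self._neg = x <= 0
        self._expm = self.alpha * (np.exp(np.minimum(x, 0.0)) - 1.0)
        return np.where(self._neg, self._expm, x)

    def backward(self, dy):
        return dy * np.where(self._neg, self._expm + self.alpha, 1.0)


class Square(Layer):
    def forward(self, x, train=False):
        self._x = x
        return x**2

    def backward(self, dy):
        return dy * 2.0 * self._x


class SafeLog(Layer):
    """log(max(x, eps)); pairs with Square as a variance-like nonlinearity."""

    def __init__(self, eps: float = 1e-7):
        self.eps = eps

    def forward(self, x, train=False):
        self._xc = np.maximum(x, self.eps)
        self._clip = x < self.eps
        return np.log(self._xc)

    def backward(self, dy):
        return np.where(self._clip, 0.0, dy / self._xc)


class Dropout(Layer):
    def __init__(self, rate: float, rng=None):
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Transpose(Layer):
    def __init__(self, perm):
        self.perm = tuple(perm)
        self.inv = tuple(np.argsort(perm))

    def forward(self, x, train=False):
        return np.ascontiguousarray(x.transpose(self.perm))

    def backward(self, dy):
        return np.ascontiguousarray(dy.transpose(self.inv))


class AsConvInput(Layer):
    """Reshape (n, channels, samples) windows for convolution.

    ``maps=False`` -> (n, 1, channels, samples): EEG as a one-map image
    (temporal+spatial 2D convnets). ``maps=True`` -> (n, channels, 1,
    samples): each EEG channel as a feature map (1D temporal convolution).
    """

    def __init__(self, maps: bool = False):
        self.maps = maps

    def forward(self, x, train=False):
        n, c, s = x.shape
        self._shape = x.shape
        return x.reshape(n, c, 1, s) if self.maps else x.reshape(n, 1, c, s)

    def backward(self, dy):
        return dy.reshape(self._shape)


def _pad_amounts(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k // 2


class Conv2D(Layer):
    def __init__(self, c_in, c_out, kh, kw, rng=None, bias=True, padding="valid"):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kh * kw
        self.W = Param(glorot(rng, (c_out, c_in, kh, kw), fan_in, c_out * kh * kw), "W")
        self.b = Param(np.zeros(c_out), "b") if bias else None
        self.kh, self.kw, self.padding = kh, kw, padding

    def _pad(self, x):
        if self.padding == "valid":
            return x, (0, 0, 0, 0)
        pt, pb = _pad_amounts(self.kh)
        pl, pr = _pad_amounts(self.kw)
        return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr))), (pt, pb, pl, pr)

    def forward(self, x, train=False):
        xp, self._padspec = self._pad(x)
        if xp.shape[2] < self.kh or xp.shape[3] < self.kw:
            raise ValueError(
                f"input spatial size {x.shape[2:]} too small for kernel "
                f"({self.kh}, {self.kw})"
            )
        self._view = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        self._xp_shape = xp.shape
        y = np.tensordot(self._view, self.W.value, axes=([1, 4, 5], [1, 2, 3]))
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        return y

    def backward(self, dy):
        n, co, oh, ow = dy.shape
        self.W.grad += np.tensordot(dy, self._view, axes=([0, 2, 3], [0, 2, 3]))
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros(self._xp_shape)
        for i in range(self.kh):
            for j in range(self.kw):
                contrib = np.tensordot(dy, self.W.value[:, :, i, j], axes=([1], [0]))
                dxp[:, :, i:i + oh, j:j + ow] += contrib.transpose(0, 3, 1, 2)
        pt, pb, pl, pr = self._padspec
        h, w = self._xp_shape[2], self._xp_shape[3]
        return dxp[:, :, pt:h - pb or None, pl:w - pr or None]

    @property
    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class DepthwiseConv2D(Layer):
    """One spatial kernel per input map, ``depth_mult`` outputs per map."""

    def __init__(self, c_in, depth_mult, kh, kw, rng=None, bias=False,
                 padding="valid"):
        rng = rng or np.random.default_rng(0)
        fan_in = kh * kw
        self.W = Param(
            glorot(rng, (c_in, depth_mult, kh, kw), fan_in, depth_mult * kh * kw),
            "W",
        )
        self.b = Param(np.zeros(c_in * depth_mult), "b") if bias else None
        self.c_in, self.depth_mult = c_in, depth_mult
        self.kh, self.kw, self.padding = kh, kw, padding

    def _pad(self, x):
        if self.padding == "valid":
            return x, (0, 0, 0, 0)
        pt, pb = _pad_amounts(self.kh)
        pl, pr = _pad_amounts(self.kw)
        return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr))), (pt, pb, pl, pr)

    def forward(self, x, train=False):
        xp, self._padspec = self._pad(x)
        self._view = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        self._xp_shape = xp.shape
        y = np.einsum("nchwij,cdij->ncdhw", self._view, self.W.value, optimize=True)
        n, c, d, oh, ow = y.shape
        y = y.reshape(n, c * d, oh, ow)
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        return np.ascontiguousarray(y)

    def backward(self, dy):
        n, _, oh, ow = dy.shape
        dyr = dy.reshape(n, self.c_in, self.depth_mult, oh, ow)
        self.W.grad += np.einsum("ncdhw,nchwij->cdij", dyr, self._view,
                                 optimize=True)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros(self._xp_shape)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i:i + oh, j:j + ow] += np.einsum(
                    "ncdhw,cd->nchw", dyr, self.W.value[:, :, i, j], optimize=True
                )
        pt, pb, pl, pr = self._padspec
        h, w = self._xp_shape[2], self._xp_shape[3]
        return dxp[:, :, pt:h - pb or None, pl:w - pr or None]

    @property
    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class _Pool2D(Layer):
    def __init__(self, ph, pw):
        self.ph, self.pw = ph, pw

    def _tile(self, x):
        n, c, h, w = x.shape
        oh, ow = h // self.ph, w // self.pw
        if oh == 0 or ow == 0:
            raise ValueError(
                f"input spatial size ({h}, {w}) smaller than pool "
                f"({self.ph}, {self.pw})"
            )
        self._in_shape = x.shape
        xc = x[:, :, : oh * self.ph, : ow * self.pw]
        return xc.reshape(n, c, oh, self.ph, ow, self.pw), (n, c, oh, ow)


class MaxPool2D(_Pool2D):
    def forward(self, x, train=False):
        xr, (n, c, oh, ow) = self._tile(x)
        y = xr.max(axis=(3, 5))
        mask = xr == y[:, :, :, None, :, None]
        # ties share the gradient equally
        self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        return y

    def backward(self, dy):
        dxr = self._mask * dy[:, :, :, None, :, None]
        n, c, h, w = self._in_shape
        oh, ow = dxr.shape[2], dxr.shape[4]
        dx = np.zeros(self._in_shape)
        dx[:, :, : oh * self.ph, : ow * self.pw] = dxr.reshape(
            n, c, oh * self.ph, ow * self.pw
        )
        return dx


class AvgPool2D(_Pool2D):
    def forward(self, x, train=False):
        xr, _ = self._tile(x)
        return xr.mean(axis=(3, 5))

    def backward(self, dy):
        n, c, h, w = self._in_shape
        oh, ow = dy.shape[2], dy.shape[3]
        dxr = np.broadcast_to(
            dy[:, :, :, None, :, None] / (self.ph * self.pw),
            (n, c, oh, self.ph, ow, self.pw),
        )
        dx = np.zeros(self._in_shape)
        dx[:, :, : oh * self.ph, : ow * self.pw] = dxr.reshape(
            n, c, oh * self.ph, ow * self.pw
        )
        return dx


class GlobalAvgPool2D(Layer):
    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._in_shape
        return np.broadcast_to(
            dy[:, :, None, None] / (h * w), self._in_shape
        ).copy()


class BatchNorm(Layer):
    """Batch normalization over all axes except the feature axis (1)."""

    def __init__(self, n_features, momentum=0.9, eps=1e-5):
        self.gamma = Param(np.ones(n_features), "gamma")
        self.beta = Param(np.zeros(n_features), "beta")
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum, self.eps = momentum, eps

    def _bshape(self, ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, train=False):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x.ndim)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).reshape(shape)
        self._xhat = (x - mu.reshape(shape)) / self._std
        self._axes, self._shape = axes, shape
        self._m = x.size // x.shape[1]
        return self.gamma.value.reshape(shape) * self._xhat + self.beta.value.reshape(
            shape
        )

    def backward(self, dy):
        axes, shape, m = self._axes, self._shape, self._m
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value.reshape(shape)
        # combined batch-norm gradient (training statistics)
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(shape)
        )
        return term / self._std

    @property
    def params(self):
        return [self.gamma, self.beta]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Single LSTM layer over (n, T, d_in) sequences; gate order i, f, g, o.

    Forget-gate bias initialized to 1. ``return_sequences`` controls whether
    the full hidden sequence (n, T, H) or the final state (n, H) is emitted.
    """

    def __init__(self, d_in, hidden, rng=None, return_sequences=False):
        rng = rng or np.random.default_rng(0)
        h = hidden
        self.Wx = Param(glorot(rng, (d_in, 4 * h), d_in + h, 4 * h), "Wx")
        self.Wh = Param(glorot(rng, (h, 4 * h), d_in + h, 4 * h), "Wh")
        b = np.zeros(4 * h)
        b[h: 2 * h] = 1.0
        self.b = Param(b, "b")
        self.hidden = h
        self.return_sequences = return_sequences

    def forward(self, x, train=False):
        n, T, d = x.shape
        h = self.hidden
        xw = x.reshape(n * T, d) @ self.Wx.value
        xw = xw.reshape(n, T, 4 * h) + self.b.value
        ht = np.zeros((n, h))
        ct = np.zeros((n, h))
        self._x = x
        self._cache = []
        hs = np.empty((n, T, h))
        for t in range(T):
            z = xw[:, t] + ht @ self.Wh.value
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h: 2 * h])
            g = np.tanh(z[:, 2 * h: 3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c_prev, h_prev = ct, ht
            ct = f * c_prev + i * g
            tc = np.tanh(ct)
            ht = o * tc
            hs[:, t] = ht
            self._cache.append((i, f, g, o, c_prev, h_prev, tc))
        self._hs = hs
        return hs if self.return_sequences else ht

    def backward(self, dy):
        x = self._x
        n, T, d = x.shape
        h = self.hidden
        dWx = np.zeros_like(self.Wx.value)
        dWh = np.zeros_like(self.Wh.value)
        db = np.zeros_like(self.b.value)
        dx = np.empty_like(x)
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = self._cache[t]
            if self.return_sequences:
                dh = dh_next + dy[:, t]
            else:
                dh = dh_next + (dy if t == T - 1 else 0.0)
            do = dh * tc
            dct = dh * o * (1.0 - tc**2) + dc_next
            di, dg, df = dct * g, dct * i, dct * c_prev
            # gate order in weights is (i, f, g, o) matching the forward slicing
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dct * f
        self.Wx.grad += dWx
        self.Wh.grad += dWh
        self.b.grad += db
        return dx

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]


class Parallel(Layer):
    """Run branches on the same input, concatenate outputs along axis 1."""

    def __init__(self, branches):
        self.branches = list(branches)

    def forward(self, x, train=False):
        outs = [b.forward(x, train=train) for b in self.branches]
        self._widths = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        dx = None
        start = 0
        for b, w in zip(self.branches, self._widths):
            d = b.backward(dy[:, start:start + w])
            dx = d if dx is None else dx + d
            start += w
        return dx

    @property
    def params(self):
        return [p for b in self.branches for p in b.params]
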