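"""Minimal feed-forward layers with explicit backpropagation.

Activations use a channels-last ``(batch, length, channels)`` layout so the
convolution reduces to one BLAS matmul over an im2col view.  Every layer
implements ``forward(x, train, rng)`` and ``backward(dy)``; parameters and
their gradients live in ``params`` / ``grads`` dicts so the optimizer can
treat models uniformly.  All layers work in float32 (default) or float64
(used by the numerical gradient checks in the test suite).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: stateless by default, no parameters."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]
    #: parameter names subject to L2 weight decay (weights, never biases/scales)
    decayed: tuple[str, ...] = ()

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_length(self, length: int) -> int:
        return length


class Conv1D(Layer):
    """1-D cross-correlation, stride 1, zero-padded to "same" output length.

    The weight tensor is ``(out_channels, kernel_size, in_channels)`` so a
    first-layer filter ``W[f]`` reads directly as a (positions x A,C,G,T)
    motif-like array.  Weights are He-initialised:
    std = sqrt(2 / fan_in) with fan_in = in_channels * kernel_size.
    """

    decayed = ("W",)

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32,
                 input_layer: bool = False) -> None:
        super().__init__()
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        #: first layer never needs an input gradient; skipping it is a large saving
        self.input_layer = input_layer
        self.pad_left = (kernel_size - 1) // 2
        self.pad_right = kernel_size // 2
        std = np.sqrt(2.0 / (in_channels * kernel_size))
        self.params = {
            "W": rng.normal(0.0, std, (out_channels, kernel_size, in_channels)
                            ).astype(dtype),
            "b": np.zeros(out_channels, dtype=dtype),
        }

    def im2col(self, x: np.ndarray) -> np.ndarray:
        """Unfold ``(B, L, C)`` into ``(B, L, k*C)`` patch rows ("same" padding).

        Built from k contiguous shifted-slice copies, which is much faster
        than materialising a strided sliding-window view.
        """
        B, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        # each patch (positions i..i+k-1, all channels) is one contiguous
        # run of k*C floats in the flattened (length, channel) layout
        flat = xp.reshape(B, -1)
        win = sliding_window_view(flat, self.k * C, axis=1)[:, ::C]
        return np.ascontiguousarray(win)

    def forward(self, x, train=False, rng=None, col=None):
        if col is None:
            col = self.im2col(x)
        B, L = col.shape[0], col.shape[1]
        col = col.reshape(B * L, self.k * self.cin)
        self._col, self._L = col, L
        Wf = self.params["W"].reshape(self.cout, -1)
        y = col @ Wf.T + self.params["b"]
        return y.reshape(B, L, self.cout)

    def backward(self, dy):
        B, L, F = dy.shape
        dy2 = dy.reshape(B * L, F)
        Wf = self.params["W"].reshape(F, -1)
        self.grads["W"] = (dy2.T @ self._col).reshape(self.params["W"].shape)
        self.grads["b"] = dy2.sum(axis=0)
        if self.input_layer:
            self._col = None
            return np.zeros((B, L, self.cin), dtype=dy.dtype)
        dcol = (dy2 @ Wf).reshape(B, L, self.k, self.cin)
        Lp = L + self.k - 1
        dxp = np.zeros((B, Lp, self.cin), dtype=dy.dtype)
        for j in range(self.k):
            dxp[:, j:j + L] += dcol[:, :, j]
        self._col = None
        return dxp[:, self.pad_left:self.pad_left + L]


class BatchNorm(Layer):
    """Batch normalisation per channel over the (batch, length) axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        n = int(np.prod([x.shape[a] for a in axes]))
        if train:
            x2 = x.reshape(n, x.shape[-1])
            s1 = x2.sum(axis=0)
            s2 = np.einsum("ij,ij->j", x2, x2)
            mu = (s1 / n).astype(x.dtype)
            var = np.maximum(s2 / n - (s1 / n) ** 2, 0.0).astype(x.dtype)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(x.dtype)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(x.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mu) * inv
        self._xhat, self._inv, self._axes, self._n = xhat, inv, axes, n
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv, axes, n = self._xhat, self._inv, self._axes, self._n
        d2 = dy.reshape(n, dy.shape[-1])
        x2 = xhat.reshape(n, xhat.shape[-1])
        dbeta = d2.sum(axis=0)
        dgamma = np.einsum("ij,ij->j", d2, x2)
        self.grads["gamma"] = dgamma
        self.grads["beta"] = dbeta
        g = (self.params["gamma"] * inv).astype(dy.dtype)
        dx = dy * g
        dx -= (g * dbeta / n).astype(dy.dtype)
        dx -= xhat * (g * dgamma / n).astype(dy.dtype)
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Max-pooling along the length axis with window ``pool`` and ``stride``.

    Output length is ceil(L / stride); the input is minimally right-padded
    (with zeros, which never beat a real ReLU activation thanks to leftmost
    argmax tie-breaking).  ``pool == 1`` is the identity.
    """

    def __init__(self, pool: int, stride: int | None = None) -> None:
        super().__init__()
        self.pool = pool
        self.stride = stride if stride is not None else pool

    def out_length(self, length: int) -> int:
        if self.pool == 1 and self.stride == 1:
            return length
        return -(-length // self.stride)

    def forward(self, x, train=False, rng=None):
        if self.pool == 1 and self.stride == 1:
            self._identity = True
            return x
        self._identity = False
        B, L, C = x.shape
        n_out = self.out_length(L)
        pad = (n_out - 1) * self.stride + self.pool - L
        self._shape, self._pad = (B, L, C), pad
        xp = np.pad(x, ((0, 0), (0, pad), (0, 0))) if pad else x
        if self.stride == self.pool and pad == 0:
            win = xp.reshape(B, n_out, self.pool, C)
        else:
            win = sliding_window_view(xp, self.pool, axis=1)[:, ::self.stride]
            win = np.moveaxis(win, -1, 2)  # (B, n_out, pool, C)
        self._arg = win.argmax(axis=2)
        return np.take_along_axis(win, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        if self._identity:
            return dy
        B, L, C = self._shape
        n_out = dy.shape[1]
        Lp = L + self._pad
        if self.stride == self.pool and self._pad == 0:
            dxw = np.zeros((B, n_out, self.pool, C), dtype=dy.dtype)
            np.put_along_axis(dxw, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
            dx = dxw.reshape(B, L, C)
        else:
            # overlapping windows: accumulate via bincount on flat indices
            b, o, c = np.indices(self._arg.shape, sparse=True)
            pos = o * self.stride + self._arg
            flat = ((b * Lp + pos) * C + c).ravel()
            acc = np.bincount(flat, weights=dy.ravel().astype(np.float64),
                              minlength=B * Lp * C)
            dx = acc.reshape(B, Lp, C)[:, :L].astype(dy.dtype)
        self._arg = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float) -> None:
        super().__init__()
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        u = rng.random(x.shape, dtype=np.float32)
        self._mask = ((u >= self.p) / np.float32(1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    decayed = ("W",)

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        std = np.sqrt(2.0 / d_in)
        self.params = {
            "W": rng.normal(0.0, std, (d_out, d_in)).astype(dtype),
            "b": np.zeros(d_out, dtype=dtype),
        }

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"]
        self._x = None
        return dx
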