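"""Fused batch-norm + ReLU layer (numba kernels).

Batch normalisation followed by ReLU appears after every convolution and
dominates the elementwise cost of training on CPU.  The fused layer does
the whole chain in two memory passes per direction instead of ~six numpy
temporaries.  It is numerically the same computation as
``BatchNorm`` followed by ``ReLU`` (float64 accumulators for the batch
statistics); the equivalence is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .layers import Layer


@njit(cache=True)
def _stats(x2):
    n, C = x2.shape
    s1 = np.zeros(C, dtype=np.float64)
    s2 = np.zeros(C, dtype=np.float64)
    for i in range(n):
        for c in range(C):
            v = np.float64(x2[i, c])
            s1[c] += v
            s2[c] += v * v
    return s1, s2


@njit(cache=True)
def _fwd_train(x2, gamma, beta, mu, inv, out, mask):
    n, C = x2.shape
    for i in range(n):
        for c in range(C):
            v = gamma[c] * ((x2[i, c] - mu[c]) * inv[c]) + beta[c]
            if v > 0:
                out[i, c] = v
                mask[i, c] = 1
            else:
                out[i, c] = 0
                mask[i, c] = 0


@njit(cache=True)
def _bwd_reduce(dy2, x2, mu, inv, mask):
    n, C = dy2.shape
    s1 = np.zeros(C, dtype=np.float64)
    s2 = np.zeros(C, dtype=np.float64)
    for i in range(n):
        for c in range(C):
            if mask[i, c]:
                dz = np.float64(dy2[i, c])
                s1[c] += dz
                s2[c] += dz * ((x2[i, c] - mu[c]) * inv[c])
    return s1, s2


@njit(cache=True)
def _bwd_apply(dy2, x2, mu, inv, mask, gamma, m1, m2, dx2):
    # the mean/variance terms couple every position through the batch
    # statistics, so masked (ReLU-blocked) positions still receive gradient
    n, C = dy2.shape
    for i in range(n):
        for c in range(C):
            xhat = (x2[i, c] - mu[c]) * inv[c]
            dz = dy2[i, c] if mask[i, c] else 0.0
            dx2[i, c] = gamma[c] * inv[c] * (dz - m1[c] - xhat * m2[c])


@njit(cache=True)
def _fwd_eval(x2, gamma, beta, mu, inv, out):
    n, C = x2.shape
    for i in range(n):
        for c in range(C):
            v = gamma[c] * ((x2[i, c] - mu[c]) * inv[c]) + beta[c]
            out[i, c] = v if v > 0 else 0


class FusedBNReLU(Layer):
    """Batch normalisation (per channel over batch x length) + ReLU."""

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
        shape = x.shape
        C = shape[-1]
        x2 = np.ascontiguousarray(x).reshape(-1, C)
        n = x2.shape[0]
        out = np.empty_like(x2)
        if train:
            s1, s2 = _stats(x2)
            mu = (s1 / n).astype(x2.dtype)
            var = np.maximum(s2 / n - (s1 / n) ** 2, 0.0).astype(x2.dtype)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(x2.dtype)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(x2.dtype)
            inv = (1.0 / np.sqrt(var + self.eps)).astype(x2.dtype)
            mask = np.empty(x2.shape, dtype=np.uint8)
            _fwd_train(x2, self.params["gamma"], self.params["beta"],
                       mu, inv, out, mask)
            self._cache = (x2, mu, inv, mask, n)
        else:
            mu = self.running_mean
            inv = (1.0 / np.sqrt(self.running_var + self.eps)).astype(x2.dtype)
            _fwd_eval(x2, self.params["gamma"], self.params["beta"], mu, inv, out)
        return out.reshape(shape)

    def backward(self, dy):
        shape = dy.shape
        x2, mu, inv, mask, n = self._cache
        dy2 = np.ascontiguousarray(dy).reshape(n, -1)
        s1, s2 = _bwd_reduce(dy2, x2, mu, inv, mask)
        self.grads["gamma"] = s2.astype(dy2.dtype)
        self.grads["beta"] = s1.astype(dy2.dtype)
        dx2 = np.empty_like(dy2)
        _bwd_apply(dy2, x2, mu, inv, mask, self.params["gamma"],
                   (s1 / n).astype(dy2.dtype), (s2 / n).astype(dy2.dtype), dx2)
        self._cache = None
        return dx2.reshape(shape)
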