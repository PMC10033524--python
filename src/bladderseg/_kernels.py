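"""Fused numba kernels for the elementwise/reduction hot paths.

The convolutions run as BLAS matmuls; everything around them (PReLU, batch
normalization, Adam, sum-pooling) is bandwidth-bound elementwise work where
fusing passes and avoiding numpy temporaries cuts the per-step time
substantially on one CPU. All kernels operate on float32 arrays reshaped to
``(n, channels)`` with float64 accumulators for the reductions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "prelu_forward", "prelu_backward",
    "bn_stats", "bn_apply", "bn_backward",
    "adam_update", "sumpool3d",
]


@njit(fastmath=True)
def prelu_forward(x, alpha, out):
    n, ch = x.shape
    for i in range(n):
        for c in range(ch):
            v = x[i, c]
            out[i, c] = v if v > 0.0 else alpha[c] * v


@njit(fastmath=True)
def prelu_backward(x, alpha, grad, gx, galpha):
    # gx = grad * (1 if x > 0 else alpha); galpha += sum(grad * x | x <= 0)
    n, ch = x.shape
    acc = np.zeros(ch, dtype=np.float64)
    for i in range(n):
        for c in range(ch):
            v = x[i, c]
            g = grad[i, c]
            if v > 0.0:
                gx[i, c] = g
            else:
                gx[i, c] = alpha[c] * g
                acc[c] += g * v
    for c in range(ch):
        galpha[c] += acc[c]


@njit(fastmath=True)
def bn_stats(x, mean, var):
    n, ch = x.shape
    s = np.zeros(ch, dtype=np.float64)
    sq = np.zeros(ch, dtype=np.float64)
    for i in range(n):
        for c in range(ch):
            v = x[i, c]
            s[c] += v
            sq[c] += v * v
    for c in range(ch):
        m = s[c] / n
        mean[c] = m
        v = sq[c] / n - m * m
        var[c] = v if v > 0.0 else 0.0


@njit(fastmath=True)
def bn_apply(x, mean, inv_std, gamma, beta, xhat, out):
    n, ch = x.shape
    for i in range(n):
        for c in range(ch):
            h = (x[i, c] - mean[c]) * inv_std[c]
            xhat[i, c] = h
            out[i, c] = gamma[c] * h + beta[c]


@njit(fastmath=True)
def bn_backward(xhat, grad, gamma, inv_std, gx, dgamma, dbeta):
    n, ch = xhat.shape
    sg = np.zeros(ch, dtype=np.float64)
    sgx = np.zeros(ch, dtype=np.float64)
    for i in range(n):
        for c in range(ch):
            g = grad[i, c]
            sg[c] += g
            sgx[c] += g * xhat[i, c]
    for c in range(ch):
        dbeta[c] += sg[c]
        dgamma[c] += sgx[c]
    for i in range(n):
        for c in range(ch):
            gx[i, c] = (gamma[c] * inv_std[c]) * (
                grad[i, c] - sg[c] / n - xhat[i, c] * (sgx[c] / n)
            )


@njit(fastmath=True)
def adam_update(p, g, m, v, lr, beta1, beta2, eps, bc1, bc2):
    n = p.size
    for i in range(n):
        gi = g[i]
        m[i] += (1.0 - beta1) * (gi - m[i])
        v[i] += (1.0 - beta2) * (gi * gi - v[i])
        p[i] -= lr * (m[i] / bc1) / (np.sqrt(v[i] / bc2) + eps)


@njit(fastmath=True)
def sumpool3d(grad, f1, f2, f3, out):
    # inverse of nearest-neighbour upsampling: sum each f1 x f2 x f3 block
    n, r, c, s, ch = out.shape
    for b in range(n):
        for i in range(r):
            for j in range(c):
                for k in range(s):
                    for q in range(ch):
                        acc = 0.0
                        for a in range(f1):
                            for d in range(f2):
                                for e in range(f3):
                                    acc += grad[b, i * f1 + a, j * f2 + d,
                                                k * f3 + e, q]
                        out[b, i, j, k, q] = acc
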