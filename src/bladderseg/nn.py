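"""Minimal numpy neural-network layers for volumetric segmentation.

Implements exactly the primitives the progressive-dilated 3D U-Net needs:
dilated/strided 3D convolution, batch normalization, PReLU, nearest-neighbour
upsampling, softmax and the Adam optimizer, each with a hand-written backward
pass. Tensors are channels-last: ``(batch, rows, cols, slices, channels)``,
float32.

Convolutions use "same" padding: the output spatial size is
``ceil(input / stride)`` per axis, with asymmetric zero padding (extra voxel
on the high side) when the required total padding is odd.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np

from . import _kernels


def _flat(x: np.ndarray) -> np.ndarray:
    """Contiguous (n, channels) float32 view of a channels-last tensor."""
    x = np.ascontiguousarray(x, dtype=np.float32)
    return x.reshape(-1, x.shape[-1])

__all__ = [
    "Parameter",
    "Layer",
    "Conv3D",
    "BatchNorm",
    "PReLU",
    "Upsample3D",
    "Softmax",
    "Adam",
]


class Parameter:
    """A trainable array with its accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: forward caches whatever backward needs."""

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(c) for c in v)
    if len(t) != 3:
        raise ValueError(f"expected a scalar or length-3 sequence, got {v!r}")
    return t


class Conv3D(Layer):
    """3D convolution with per-axis stride and isotropic dilation.

    The kernel is laid out ``(k0, k1, k2, in_ch, out_ch)`` and the forward
    pass loops over kernel taps, reducing each tap to a single matmul —
    memory-light and fast for the 3x3x3 kernels used here.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: Sequence[int] | int = 3,
        stride: Sequence[int] | int = 1,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "conv",
        needs_input_grad: bool = True,
    ):
        self.needs_input_grad = needs_input_grad
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.dilation = int(dilation)
        self.name = name
        rng = rng or np.random.default_rng()
        fan_in = self.in_channels * int(np.prod(self.kernel))
        scale = math.sqrt(2.0 / fan_in)  # He init for rectifier-family nets
        self.weight = Parameter(
            rng.normal(0.0, scale, size=self.kernel + (in_channels, out_channels)),
            name=f"{name}.weight",
        )
        self.bias = Parameter(np.zeros(out_channels), name=f"{name}.bias")
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def out_spatial(self, in_spatial: Sequence[int]) -> tuple[int, int, int]:
        return tuple(-(-d // s) for d, s in zip(in_spatial, self.stride))

    def _padding(self, in_spatial):
        pads = []
        for d, s, k in zip(in_spatial, self.stride, self.kernel):
            out = -(-d // s)
            eff = (k - 1) * self.dilation + 1
            total = max((out - 1) * s + eff - d, 0)
            pads.append((total // 2, total - total // 2))
        return pads

    def _tap_slices(self, out_spatial):
        d = self.dilation
        s = self.stride
        for taps in itertools.product(*(range(k) for k in self.kernel)):
            sl = tuple(
                slice(t * d, t * d + st * o, st)
                for t, st, o in zip(taps, s, out_spatial)
            )
            yield taps, (slice(None),) + sl + (slice(None),)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if x.ndim != 5 or x.shape[-1] != self.in_channels:
            raise ValueError(
                f"{self.name}: expected (N, r, c, s, {self.in_channels}), got {x.shape}"
            )
        in_spatial = x.shape[1:4]
        out_spatial = self.out_spatial(in_spatial)
        pads = self._padding(in_spatial)
        if any(p != (0, 0) for p in pads):
            xp = np.pad(x.astype(np.float32, copy=False),
                        [(0, 0)] + pads + [(0, 0)])
        else:
            xp = x.astype(np.float32, copy=False)
        n = x.shape[0]
        m = n * int(np.prod(out_spatial))
        yf = np.zeros((m, self.out_channels), dtype=np.float32)
        w = self.weight.value
        for taps, sl in self._tap_slices(out_spatial):
            xs = xp[sl].reshape(m, self.in_channels)
            yf += xs @ w[taps]
        yf += self.bias.value
        self._cache = (xp, pads, x.shape, out_spatial) if training else None
        return yf.reshape((n,) + out_spatial + (self.out_channels,))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, pads, in_shape, out_spatial = self._cache
        n = in_shape[0]
        m = n * int(np.prod(out_spatial))
        gf = np.ascontiguousarray(grad.reshape(m, self.out_channels),
                                  dtype=np.float32)
        self.bias.grad += gf.sum(axis=0)
        w = self.weight.value
        for taps, sl in self._tap_slices(out_spatial):
            xs = xp[sl].reshape(m, self.in_channels)
            self.weight.grad[taps] += xs.T @ gf
        self._cache = None
        if not self.needs_input_grad:
            return None
        if self.stride == (1, 1, 1):
            return self._input_grad_gather(grad, in_shape)
        return self._input_grad_scatter(gf, xp.shape, pads, in_shape,
                                        out_spatial)

    def _input_grad_gather(self, grad, in_shape):
        # stride-1 "same" conv: dx is the dilated correlation of the output
        # gradient with the spatially flipped, channel-transposed kernel —
        # a gather with contiguous accumulation, faster than scatter-adds
        d = self.dilation
        k = self.kernel
        spatial = in_shape[1:4]
        pads_in = self._padding(spatial)
        gpads = [((kk - 1) * d - lo, (kk - 1) * d - hi)
                 for kk, (lo, hi) in zip(k, pads_in)]
        gp = np.pad(grad.astype(np.float32, copy=False),
                    [(0, 0)] + gpads + [(0, 0)])
        m = in_shape[0] * int(np.prod(spatial))
        acc = np.zeros((m, self.in_channels), dtype=np.float32)
        w = self.weight.value
        for taps in itertools.product(*(range(kk) for kk in k)):
            flipped = tuple(kk - 1 - t for kk, t in zip(k, taps))
            sl = (slice(None),) + tuple(
                slice(t * d, t * d + s) for t, s in zip(taps, spatial)
            ) + (slice(None),)
            acc += gp[sl].reshape(m, self.out_channels) @ w[flipped].T
        return acc.reshape(in_shape)

    def _input_grad_scatter(self, gf, xp_shape, pads, in_shape, out_spatial):
        gxp = np.zeros(xp_shape, dtype=np.float32)
        w = self.weight.value
        for taps, sl in self._tap_slices(out_spatial):
            gxp[sl] += (gf @ w[taps].T).reshape(gxp[sl].shape)
        if all(p == (0, 0) for p in pads):
            return gxp
        unpad = (slice(None),) + tuple(
            slice(lo, lo + d) for (lo, _), d in zip(pads, in_shape[1:4])
        ) + (slice(None),)
        return gxp[unpad]


class BatchNorm(Layer):
    """Per-channel normalization over batch and spatial axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.channels = int(channels)
        self.momentum = float(momentum)
        self.eps = float(eps)
        self.name = name
        self.gamma = Parameter(np.ones(channels), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        xf = _flat(x)
        if training:
            mean = np.empty(self.channels, dtype=np.float32)
            var = np.empty(self.channels, dtype=np.float32)
            _kernels.bn_stats(xf, mean, var)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = np.empty_like(xf)
        out = np.empty_like(xf)
        _kernels.bn_apply(xf, mean.astype(np.float32), inv_std,
                          self.gamma.value, self.beta.value, xhat, out)
        self._cache = (xhat, inv_std, x.shape)
        return out.reshape(x.shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        gf = _flat(grad)
        gx = np.empty_like(gf)
        _kernels.bn_backward(xhat, gf, self.gamma.value, inv_std, gx,
                             self.gamma.grad, self.beta.grad)
        return gx.reshape(shape)


class PReLU(Layer):
    """Parametric ReLU with one learnable negative slope per channel."""

    def __init__(self, channels: int, init: float = 0.25, name: str = "prelu"):
        self.channels = int(channels)
        self.name = name
        self.alpha = Parameter(np.full(channels, init), name=f"{name}.alpha")
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.alpha]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        xf = _flat(x)
        out = np.empty_like(xf)
        _kernels.prelu_forward(xf, self.alpha.value, out)
        self._cache = (xf, x.shape)
        return out.reshape(x.shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xf, shape = self._cache
        gf = _flat(grad)
        gx = np.empty_like(gf)
        _kernels.prelu_backward(xf, self.alpha.value, gf, gx, self.alpha.grad)
        return gx.reshape(shape)


class Upsample3D(Layer):
    """Nearest-neighbour upsampling by integer per-axis factors."""

    def __init__(self, factors: Sequence[int] | int = 2, name: str = "up"):
        self.factors = _triple(factors)
        self.name = name
        self._in_shape = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._in_shape = x.shape
        y = x
        for axis, f in enumerate(self.factors, start=1):
            if f > 1:
                y = np.repeat(y, f, axis=axis)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = np.empty(self._in_shape, dtype=np.float32)
        _kernels.sumpool3d(np.ascontiguousarray(grad, dtype=np.float32),
                           *self.factors, out)
        return out


class Softmax(Layer):
    """Softmax over the channel axis."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        self._cache = p
        return p.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        p = self._cache
        inner = (grad * p).sum(axis=-1, keepdims=True)
        return (p * (grad - inner)).astype(np.float32)


class Adam:
    """Adam optimizer over a flat list of Parameters."""

    def __init__(self, params: Iterable[Parameter], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            _kernels.adam_update(p.value.reshape(-1), p.grad.reshape(-1),
                                 m.reshape(-1), v.reshape(-1), self.lr,
                                 self.beta1, self.beta2, self.eps, bc1, bc2)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
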