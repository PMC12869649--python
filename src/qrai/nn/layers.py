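"""Minimal N-dimensional convolutional layers with explicit backpropagation.

Arrays are (batch, channels, *spatial); layers work identically for 2D and 3D
volumes. Each layer caches what its backward pass needs during ``forward`` and
returns input cotangents from ``backward``; parameter gradients accumulate in
``.grads``. Gradient correctness is established by finite differences in the
test suite, which is the contract everything downstream relies on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv", "ReLU", "AvgPool", "Upsample", "he_init"]


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Layer:
    """Base class: stateless unless it has parameters."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


_FWD_EINSUM = {2: "ncxyuv,ocuv->noxy", 3: "ncxyzuvw,ocuvw->noxyz"}
_DW_EINSUM = {2: "ncxyuv,noxy->ocuv", 3: "ncxyzuvw,noxyz->ocuvw"}
_DX_EINSUM = {2: "noxyuv,ocuv->ncxy", 3: "noxyzuvw,ocuvw->ncxyz"}


class Conv(Layer):
    """Same-padded stride-1 convolution with bias, odd kernel size."""

    def __init__(
        self, in_ch: int, out_ch: int, ndim: int, ksize: int = 3,
        rng: np.random.Generator | None = None,
    ) -> None:
        if ksize % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.ndim = ndim
        self.ksize = ksize
        rng = rng or np.random.default_rng()
        fan_in = in_ch * ksize**ndim
        self.w = he_init(rng, (out_ch, in_ch) + (ksize,) * ndim, fan_in)
        self.b = np.zeros(out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x_win = None

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.ksize // 2
        pad = [(0, 0), (0, 0)] + [(p, p)] * self.ndim
        return np.pad(x, pad)

    def _windows(self, x: np.ndarray) -> np.ndarray:
        return sliding_window_view(
            self._pad(x), (self.ksize,) * self.ndim, axis=tuple(range(2, 2 + self.ndim))
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_win = self._windows(x)
        out = np.einsum(_FWD_EINSUM[self.ndim], self._x_win, self.w)
        return out + self.b.reshape((1, -1) + (1,) * self.ndim)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw += np.einsum(_DW_EINSUM[self.ndim], self._x_win, grad)
        self.db += grad.sum(axis=(0,) + tuple(range(2, 2 + self.ndim)))
        flip = (slice(None), slice(None)) + (slice(None, None, -1),) * self.ndim
        g_win = self._windows(grad)
        return np.einsum(_DX_EINSUM[self.ndim], g_win, self.w[flip])

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class AvgPool(Layer):
    """Factor-2 average pooling over all spatial axes."""

    def __init__(self, ndim: int):
        self.ndim = ndim

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        if any(s % 2 for s in spatial):
            raise ValueError(f"spatial shape {spatial} not divisible by 2")
        new = []
        for s in spatial:
            new.extend([s // 2, 2])
        x = x.reshape((n, c) + tuple(new))
        axes = tuple(3 + 2 * i for i in range(self.ndim))
        return x.mean(axis=axes)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for ax in range(2, 2 + self.ndim):
            grad = np.repeat(grad, 2, axis=ax)
        return grad / 2**self.ndim


class Upsample(Layer):
    """Factor-2 nearest-neighbour upsampling (adjoint of sum pooling)."""

    def __init__(self, ndim: int):
        self.ndim = ndim

    def forward(self, x: np.ndarray) -> np.ndarray:
        for ax in range(2, 2 + self.ndim):
            x = np.repeat(x, 2, axis=ax)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c = grad.shape[:2]
        spatial = grad.shape[2:]
        new = []
        for s in spatial:
            new.extend([s // 2, 2])
        grad = grad.reshape((n, c) + tuple(new))
        axes = tuple(3 + 2 * i for i in range(self.ndim))
        return grad.sum(axis=axes)
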