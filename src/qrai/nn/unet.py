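"""A compact N-dimensional U-Net built from the explicit-backprop layers.

Encoder levels apply two 3^n convolutions + ReLU then average-pool; the
decoder upsamples, concatenates the skip connection and applies two more
convolutions. A 1x..x1 head maps back to one channel; an optional ReLU on the
output enforces non-negativity of the predicted pressure.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv, ReLU, AvgPool, Upsample, Layer

__all__ = ["UNet"]


class _Block:
    """conv-relu-conv-relu."""

    def __init__(self, in_ch, out_ch, ndim, rng):
        self.c1 = Conv(in_ch, out_ch, ndim, rng=rng)
        self.r1 = ReLU()
        self.c2 = Conv(out_ch, out_ch, ndim, rng=rng)
        self.r2 = ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, g):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(g))))

    @property
    def layers(self):
        return [self.c1, self.c2]


class UNet:
    """U-Net with ``depth`` resolution levels and ``base_channels`` features.

    Input spatial extents must be divisible by 2^(depth-1). Deterministic
    given the seed of the generator used at construction.
    """

    def __init__(
        self,
        ndim: int = 3,
        depth: int = 3,
        base_channels: int = 8,
        final_activation: str = "nonneg",
        rng: np.random.Generator | None = None,
    ) -> None:
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if final_activation not in ("nonneg", "linear"):
            raise ValueError("final_activation must be 'nonneg' or 'linear'")
        rng = rng or np.random.default_rng()
        self.ndim = ndim
        self.depth = depth
        self.base_channels = base_channels
        self.final_activation = final_activation

        chans = [base_channels * 2**i for i in range(depth)]
        self.enc = []
        in_ch = 1
        for i in range(depth - 1):
            self.enc.append(_Block(in_ch, chans[i], ndim, rng))
            in_ch = chans[i]
        self.pool = AvgPool(ndim)
        self.bottleneck = _Block(in_ch, chans[-1], ndim, rng)
        self.up = Upsample(ndim)
        self.dec = []
        in_ch = chans[-1]
        for i in range(depth - 2, -1, -1):
            self.dec.append(_Block(in_ch + chans[i], chans[i], ndim, rng))
            in_ch = chans[i]
        self.head = Conv(in_ch, 1, ndim, ksize=1, rng=rng)
        self.out_act = ReLU() if final_activation == "nonneg" else None

    # -- plumbing -----------------------------------------------------------
    @property
    def _blocks(self):
        return self.enc + [self.bottleneck] + self.dec

    @property
    def layers(self) -> list[Layer]:
        out = []
        for b in self._blocks:
            out.extend(b.layers)
        out.append(self.head)
        return out

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def check_shape(self, spatial: tuple[int, ...]) -> None:
        f = 2 ** (self.depth - 1)
        if any(s % f for s in spatial):
            raise ValueError(
                f"input spatial shape {spatial} must be divisible by {f} "
                f"for depth {self.depth}"
            )

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (batch, 1, *spatial) -> (batch, 1, *spatial)."""
        self.check_shape(x.shape[2:])
        skips = []
        h = x
        for blk in self.enc:
            h = blk.forward(h)
            skips.append(h)
            h = self.pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_chans = []
        for blk, skip in zip(self.dec, reversed(skips)):
            h = self.up.forward(h)
            self._skip_chans.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h)
        h = self.head.forward(h)
        if self.out_act is not None:
            h = self.out_act.forward(h)
        return h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.out_act is not None:
            grad = self.out_act.backward(grad)
        grad = self.head.backward(grad)
        skip_grads = []
        for blk, sc in zip(reversed(self.dec), reversed(self._skip_chans)):
            grad = blk.backward(grad)
            skip_grads.append(grad[:, :sc])
            grad = self.up.backward(grad[:, sc:])
        grad = self.bottleneck.backward(grad)
        for blk, sg in zip(reversed(self.enc), reversed(skip_grads)):
            grad = self.pool.backward(grad)
            grad = blk.backward(grad + sg)
        return grad

    # -- (de)serialization --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params
        if len(state) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            arr = state[f"p{i}"]
            if arr.shape != p.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p[...] = arr
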