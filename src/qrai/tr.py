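"""Time-reversal reconstruction of the initial pressure.

The measured sinogram is reversed in time and re-emitted into the medium from
the transducer (sub-element) locations; by the time symmetry of the lossless
wave equation the field refocuses onto the source, and the field at the final
reversed-time step is taken as the reconstruction ``p_rec``. With a
limited-view (single planar array) geometry the inverse problem is not
uniquely determined: reconstructions localize the source but distort its
morphology and may contain negative values — the artifacts the enhancement
network is trained to remove. No positivity clamp is applied here for exactly
that reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid, PressureVolume
from .acoustics import AcousticMedium, WaveSolver
from .twin import Sinogram, TransducerArray

__all__ = ["TRConfig", "reverse_sinogram", "tr_reconstruct"]


@dataclass
class TRConfig:
    """Configuration of the time-reversal operator.

    ``injection_mode`` selects how the reversed signals drive the solver:
    ``additive-source`` adds them as time-varying sources at the element
    positions (the practical default); ``dirichlet`` enforces them as
    pressure values. The medium's sound-speed and density maps are used by
    the back-propagation, so prior knowledge of the acoustic properties
    enters the reconstruction here.
    """

    medium: AcousticMedium
    array: TransducerArray
    injection_mode: str = "additive-source"
    use_sub_elements: bool = True
    dt: float | None = None
    cfl: float = 0.3
    pml_width: int = 10

    def __post_init__(self) -> None:
        if self.injection_mode not in ("additive-source", "dirichlet"):
            raise ValueError(f"unknown injection mode {self.injection_mode!r}")

    @property
    def grid(self) -> Grid:
        return self.medium.grid


def reverse_sinogram(s: Sinogram) -> Sinogram:
    """Flip the time axis of every channel.

    Sample ``k`` of the output equals sample ``N-1-k`` of the input; dt and
    the channel map are preserved and t0 is remapped to the reversed origin.
    """
    return Sinogram(
        s.data[:, ::-1].copy(),
        dt=s.dt,
        t0=-(s.t0 + (s.n_samples - 1) * s.dt),
        channel_map=s.channel_map.copy(),
        units_flag=s.units_flag,
        element_centers=None if s.element_centers is None else s.element_centers.copy(),
    )


def tr_reconstruct(s: Sinogram, cfg: TRConfig) -> PressureVolume:
    """Back-propagate the time-reversed sinogram; return the refocused field.

    Each channel's signal is re-emitted from its element location (spread
    over the element's sub-element points when ``use_sub_elements``), stepping
    the same solver used for the forward problem backwards through the
    recorded window. Output role is ``p_rec``; values are on an arbitrary
    linear scale relative to the true p0 (single-point calibration restores
    dose units downstream).
    """
    if s.n_channels != cfg.array.n_elements:
        raise ValueError(
            f"sinogram has {s.n_channels} channels but the array has "
            f"{cfg.array.n_elements} elements"
        )
    grid = cfg.grid
    solver = WaveSolver(cfg.medium, dt=cfg.dt, cfl=cfg.cfl, pml_width=cfg.pml_width)
    # re-emit on the solver time base
    data = s.data
    if abs(s.dt - solver.dt) > 1e-12 * solver.dt:
        n_new = max(2, int(round(s.n_samples * s.dt / solver.dt)))
        t_new = np.arange(n_new) * solver.dt
        t_old = np.arange(s.n_samples) * s.dt
        data = np.vstack([np.interp(t_new, t_old, row) for row in data])
    rev = data[:, ::-1]
    # order channels by element index
    order = np.argsort(s.channel_map)
    rev = rev[order]
    if cfg.use_sub_elements:
        pts = cfg.array.sub_element_points()
        n_sub = cfg.array.n_sub
        signals = np.repeat(rev / n_sub, n_sub, axis=0)
    else:
        pts = cfg.array.element_centers
        signals = rev
    idx = np.asarray([grid.index_of(p) for p in pts], dtype=int)
    field = solver.inject(signals, idx, mode=cfg.injection_mode)
    return PressureVolume(grid, field, role="p_rec")
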