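"""Digital twin of the radiacoustic acquisition chain.

The measured signal differs from the ideal acoustic response in three
system-specific ways, each modeled here as a linear stage:

1. the radiation pulse has finite duration, so the ideal impulse response of
   the medium is convolved with the pulse temporal profile;
2. each transducer element has finite aperture, modeled by subdividing the
   element into sub-elements and summing their point signals;
3. the piezo element rings like a damped harmonic oscillator, so the aperture
   signal is convolved with the element impulse response.

Composed with acoustic propagation these stages define the unified forward
operator F mapping an initial pressure volume to the measured sinogram.
Because every stage is linear, F has an exact adjoint, exposed through
:class:`TwinOperator` for use inside gradient-based training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grid import PressureVolume
from .acoustics import AcousticMedium, TimeSeries, WaveSolver
from .beams import PulseProfile

__all__ = [
    "TransducerArray",
    "ImpulseResponse",
    "Sinogram",
    "TwinConfig",
    "apply_pulse",
    "finite_element_signal",
    "apply_impulse_response",
    "forward_operator",
    "TwinOperator",
]


@dataclass(frozen=True)
class TransducerArray:
    """A planar matrix array of square elements.

    ``element_centers`` are the element centre coordinates (m). Each element of
    aperture ``element_size`` is subdivided on a ``sub_pitch`` grid; the
    sub-element displacement vectors span the aperture symmetrically about the
    centre (3x3 sub-elements for a 3 mm element at 1 mm pitch). ``normal`` is
    the facing direction; sub-elements are laid out in the plane orthogonal to
    it.
    """

    element_centers: np.ndarray
    element_size: tuple[float, float] = (3e-3, 3e-3)
    sub_pitch: float = 1e-3
    normal: tuple[float, ...] = (1.0, 0.0, 0.0)
    layout: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.element_centers, dtype=float))
        object.__setattr__(self, "element_centers", centers)
        if any(s <= 0 for s in self.element_size):
            raise ValueError("element_size must be positive")
        if self.sub_pitch <= 0:
            raise ValueError("sub_pitch must be positive")
        for s in self.element_size:
            ratio = s / self.sub_pitch
            if abs(ratio - round(ratio)) > 1e-6:
                raise ValueError("sub_pitch must divide element_size evenly")
        n = np.asarray(self.normal, dtype=float)
        object.__setattr__(self, "normal", tuple(n / np.linalg.norm(n)))

    @property
    def n_elements(self) -> int:
        return len(self.element_centers)

    @property
    def ndim(self) -> int:
        return self.element_centers.shape[1]

    def sub_offsets(self) -> np.ndarray:
        """Sub-element displacement vectors from the element centre (m)."""
        n = np.asarray(self.normal, dtype=float)
        nd = self.ndim
        # orthonormal tangent frame of the element plane
        tangents = []
        for axis in range(nd):
            e = np.zeros(nd)
            e[axis] = 1.0
            t = e - np.dot(e, n) * n
            norm = np.linalg.norm(t)
            if norm > 1e-9:
                tangents.append(t / norm)
            if len(tangents) == nd - 1:
                break
        offs_1d = []
        for s in self.element_size[: nd - 1]:
            m = int(round(s / self.sub_pitch))
            offs_1d.append((np.arange(m) - (m - 1) / 2.0) * self.sub_pitch)
        mesh = np.meshgrid(*offs_1d, indexing="ij")
        flat = [m.ravel() for m in mesh]
        offsets = np.zeros((len(flat[0]), nd))
        for t, comp in zip(tangents, flat):
            offsets += np.outer(comp, t)
        return offsets

    @property
    def n_sub(self) -> int:
        return len(self.sub_offsets())

    def sub_element_points(self) -> np.ndarray:
        """(n_elements * n_sub, ndim) sensor coordinates, element-major order."""
        offs = self.sub_offsets()
        pts = (self.element_centers[:, None, :] + offs[None, :, :]).reshape(
            -1, self.ndim
        )
        return pts

    @classmethod
    def matrix(
        cls,
        rows: int = 16,
        cols: int = 16,
        pitch: float = 3e-3,
        center: Sequence[float] = (0.0, 0.0, 0.0),
        normal: Sequence[float] = (1.0, 0.0, 0.0),
        element_size: tuple[float, float] = (3e-3, 3e-3),
        sub_pitch: float = 1e-3,
    ) -> "TransducerArray":
        """A rows x cols planar matrix array centred at ``center``."""
        center = np.asarray(center, dtype=float)
        nd = len(center)
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        tangents = []
        for axis in range(nd):
            e = np.zeros(nd)
            e[axis] = 1.0
            t = e - np.dot(e, n) * n
            norm = np.linalg.norm(t)
            if norm > 1e-9:
                tangents.append(t / norm)
            if len(tangents) == nd - 1:
                break
        r_off = (np.arange(rows) - (rows - 1) / 2.0) * pitch
        if nd == 2 or cols == 1:
            centers = center[None, :] + np.outer(r_off, tangents[0])
        else:
            c_off = (np.arange(cols) - (cols - 1) / 2.0) * pitch
            rr, cc = np.meshgrid(r_off, c_off, indexing="ij")
            centers = (
                center[None, :]
                + np.outer(rr.ravel(), tangents[0])
                + np.outer(cc.ravel(), tangents[1])
            )
        return cls(
            centers,
            element_size=element_size,
            sub_pitch=sub_pitch,
            normal=tuple(n),
            layout=(rows, cols),
        )


@dataclass
class ImpulseResponse:
    """Transducer element impulse response.

    The default parametric model is a damped harmonic oscillator,
    ``IR(t) = exp(-pi f0 t / q) * sin(2 pi f0 t)``, energy-normalized so
    convolution preserves overall signal scale. ``kind='delta'`` is the
    identity; ``kind='samples'`` accepts a measured response.
    """

    kind: str = "damped-sinusoid"
    f0: float = 1e6
    q: float = 2.0
    dt: float | None = None
    samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("delta", "damped-sinusoid", "samples"):
            raise ValueError(f"unknown impulse response kind {self.kind!r}")
        if self.kind == "damped-sinusoid" and (self.f0 <= 0 or self.q <= 0):
            raise ValueError("f0 and q must be positive")
        if self.kind == "samples":
            if self.samples is None or self.dt is None:
                raise ValueError("kind='samples' requires samples and dt")
            self.samples = np.asarray(self.samples, dtype=float)

    def kernel(self, dt: float) -> np.ndarray:
        """Energy-normalized discrete kernel at sampling interval dt."""
        if self.kind == "delta":
            return np.array([1.0])
        if self.kind == "samples":
            s = self.samples
            if self.dt is not None and not math.isclose(self.dt, dt, rel_tol=1e-9):
                n = max(2, int(round(s.size * self.dt / dt)))
                t_new = np.arange(n) * dt
                s = np.interp(t_new, np.arange(s.size) * self.dt, s, right=0.0)
        else:
            # ring-down to exp(-2 pi q) after q periods; truncate at 4 decay times
            decay = self.q / (np.pi * self.f0)
            n = max(2, int(round(4.0 * decay / dt)))
            t = np.arange(n) * dt
            s = np.exp(-np.pi * self.f0 * t / self.q) * np.sin(2.0 * np.pi * self.f0 * t)
        energy = np.sqrt(np.sum(s**2))
        if energy == 0:
            raise ValueError("impulse response has zero energy")
        return s / energy


@dataclass
class Sinogram:
    """Channels x time pressure recordings from a transducer array."""

    data: np.ndarray
    dt: float
    t0: float = 0.0
    channel_map: np.ndarray | None = None
    units_flag: str = "relative"
    element_centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")
        if self.channel_map is None:
            self.channel_map = np.arange(self.data.shape[0])
        else:
            self.channel_map = np.asarray(self.channel_map, dtype=int)
        if len(self.channel_map) != self.data.shape[0]:
            raise ValueError("channel_map length must equal channel count")
        if self.units_flag not in ("absolute", "relative"):
            raise ValueError("units_flag must be 'absolute' or 'relative'")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TwinConfig:
    """Bundle defining the unified forward operator: pulse + array + IR + medium."""

    pulse: PulseProfile
    array: TransducerArray
    ir: ImpulseResponse
    medium: AcousticMedium
    duration: float
    dt: float | None = None
    cfl: float = 0.3
    pml_width: int = 10

    def solver(self) -> WaveSolver:
        return WaveSolver(
            self.medium, dt=self.dt, cfl=self.cfl, pml_width=self.pml_width
        )


# ---------------------------------------------------------------------------
# signal-chain stages


def _convolve_ts(ts: TimeSeries, kernel: np.ndarray) -> TimeSeries:
    out = np.convolve(ts.samples, kernel)[: ts.samples.size]
    return TimeSeries(out, dt=ts.dt, t0=ts.t0)


def apply_pulse(signal: TimeSeries, pulse: PulseProfile) -> TimeSeries:
    """Convolve a point signal with the radiation pulse temporal profile.

    The pulse is resampled to the signal's dt if needed; a unit-area pulse
    preserves the signal integral, and a delta pulse is the identity. The
    convolution is linear (not circular), truncated to the recording window.
    """
    if pulse.samples.size == 0:
        raise ValueError("empty pulse profile")
    if pulse.kind == "delta":
        kernel = np.array([1.0])
    else:
        p = pulse.resample(signal.dt)
        kernel = p.samples * signal.dt  # discrete kernel with unit sum
    return _convolve_ts(signal, kernel)


def finite_element_signal(
    sub_signals: Sequence[TimeSeries], weights: Sequence[float] | None = None
) -> TimeSeries:
    """Sum sub-element point signals into one finite-aperture element signal."""
    if len(sub_signals) == 0:
        raise ValueError("no sub-element signals")
    ref = sub_signals[0]
    if weights is None:
        weights = np.ones(len(sub_signals))
    out = np.zeros_like(ref.samples)
    for w, ts in zip(weights, sub_signals):
        if (
            ts.samples.size != ref.samples.size
            or not math.isclose(ts.dt, ref.dt, rel_tol=1e-12)
            or not math.isclose(ts.t0, ref.t0, rel_tol=1e-9, abs_tol=1e-15)
        ):
            raise ValueError("sub-element signals must share dt, t0 and length")
        out += w * ts.samples
    return TimeSeries(out, dt=ref.dt, t0=ref.t0)


def apply_impulse_response(signal: TimeSeries, ir: ImpulseResponse) -> TimeSeries:
    """Convolve with the element impulse response (energy-normalized kernel)."""
    return _convolve_ts(signal, ir.kernel(signal.dt))


# ---------------------------------------------------------------------------
# the unified operator


class TwinOperator:
    """The unified forward operator F as an explicit linear map with adjoint.

    ``apply`` maps an initial-pressure array to the sinogram data array by
    composing propagation to all sub-element sensor points, pulse convolution,
    sub-element summation and impulse-response convolution. ``adjoint`` applies
    the exact transpose, which is what back-propagates sinogram-domain
    gradients to the image domain during physics-informed training.
    """

    def __init__(self, cfg: TwinConfig):
        self.cfg = cfg
        self.solver = cfg.solver()
        self.dt = self.solver.dt
        self.n_steps = max(1, int(round(cfg.duration / self.dt)))
        grid = cfg.medium.grid
        pts = cfg.array.sub_element_points()
        self.sensor_idx = np.asarray([grid.index_of(p) for p in pts], dtype=int)
        self.n_elements = cfg.array.n_elements
        self.n_sub = cfg.array.n_sub
        # combined pulse+IR kernel: both stages are time convolutions and the
        # chain is commutative, so they collapse into one kernel
        if cfg.pulse.kind == "delta":
            pk = np.array([1.0])
        else:
            pk = cfg.pulse.resample(self.dt).samples * self.dt
        ik = cfg.ir.kernel(self.dt)
        self.kernel = np.convolve(pk, ik)

    def apply(self, p0_values: np.ndarray) -> np.ndarray:
        """p0 array -> (n_elements, n_steps) sinogram data."""
        rec = self.solver.record(p0_values, self.sensor_idx, self.n_steps)
        elem = rec.reshape(self.n_elements, self.n_sub, self.n_steps).sum(axis=1)
        out = np.empty_like(elem)
        for i in range(self.n_elements):
            out[i] = np.convolve(elem[i], self.kernel)[: self.n_steps]
        return out

    def adjoint(self, sino_bar: np.ndarray) -> np.ndarray:
        """Transpose of :meth:`apply`: sinogram cotangent -> p0 cotangent."""
        sino_bar = np.asarray(sino_bar, dtype=float)
        elem_bar = np.empty_like(sino_bar)
        for i in range(sino_bar.shape[0]):
            # transpose of truncated linear convolution = truncated correlation
            full = np.correlate(sino_bar[i], self.kernel, mode="full")
            elem_bar[i] = full[self.kernel.size - 1 :][: self.n_steps]
        sub_bar = np.repeat(elem_bar[:, None, :], self.n_sub, axis=1).reshape(
            -1, self.n_steps
        )
        return self.solver.record_adjoint(sub_bar, self.sensor_idx)

    def to_sinogram(self, data: np.ndarray) -> Sinogram:
        return Sinogram(
            data,
            dt=self.dt,
            t0=0.0,
            channel_map=np.arange(self.n_elements),
            units_flag="relative",
            element_centers=self.cfg.array.element_centers,
        )


def forward_operator(p0: PressureVolume, twin: TwinConfig) -> Sinogram:
    """Apply the unified digital-twin operator F to an initial pressure map."""
    if p0.grid != twin.medium.grid:
        raise ValueError("p0 must live on the twin medium grid")
    op = TwinOperator(twin)
    return op.to_sinogram(op.apply(p0.values))
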