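"""Synthetic radiation beams, pulse profiles, and experiment catalogs.

Parametric surrogates for the dose engines used in practice (Monte Carlo or a
treatment planning system): an analytic proton pencil beam with a Bragg peak
at the range given by the power law ``R = alpha * E^p``, and a collimated
electron field with build-up, plateau and a sigmoid distal falloff through the
50%-dose depth. Only the geometric and dosimetric semantics matter here —
peak position, lateral width, entrance-to-peak ratio — not nuclear physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erf, erfc

from .grid import Grid, DoseVolume

__all__ = [
    "ProtonBeamSpec",
    "ElectronBeamSpec",
    "PulseProfile",
    "DatasetCatalog",
    "proton_pencil_beam",
    "electron_flash_beam",
    "instantaneous_dose_rate",
    "imaging_frame_rate",
    "make_pulse",
    "watertank_catalog",
]

#: default range-energy power law for protons in water, R[cm] = alpha * E[MeV]^p
RANGE_ALPHA = 0.0022
RANGE_P = 1.77


@dataclass(frozen=True)
class ProtonBeamSpec:
    """A proton pencil beam.

    ``energy`` in MeV; ``entry`` (m) is where the beam enters the grid and
    ``direction`` the unit beam axis. ``sigma_lateral`` is the lateral Gaussian
    spot size (m). The range-energy power law R = alpha * E^p uses cm and MeV.
    ``fluence_scale`` sets the Bragg-peak dose in Gy.
    """

    energy: float
    entry: tuple[float, ...]
    direction: tuple[float, ...]
    sigma_lateral: float = 3e-3
    range_alpha: float = RANGE_ALPHA
    range_p: float = RANGE_P
    fluence_scale: float = 1.0
    distal_sigma: float = 3e-3  # m; sharpness of the distal falloff

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError("beam energy must be positive")
        if self.sigma_lateral <= 0:
            raise ValueError("sigma_lateral must be positive")
        if self.fluence_scale < 0:
            raise ValueError("fluence_scale must be non-negative")
        d = np.asarray(self.direction, dtype=float)
        if not math.isclose(float(np.linalg.norm(d)), 1.0, rel_tol=1e-6):
            raise ValueError("direction must be a unit vector")

    @property
    def range_m(self) -> float:
        """CSDA-style range in metres from the power law (alpha, p in cm/MeV)."""
        return self.range_alpha * self.energy**self.range_p * 1e-2


@dataclass(frozen=True)
class ElectronBeamSpec:
    """A collimated electron field for ultra-high-dose-rate (FLASH) delivery."""

    field_size: tuple[float, float] = (2e-2, 2e-2)
    r50: float = 3e-2
    surface_dose_fraction: float = 0.85
    dose_per_pulse: float = 1.0
    pulse_duration: float = 1e-6
    penumbra_sigma: float = 2e-3

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.field_size):
            raise ValueError("field_size must be positive")
        if not (0.0 < self.surface_dose_fraction <= 1.0):
            raise ValueError("surface_dose_fraction must lie in (0, 1]")
        if self.dose_per_pulse <= 0:
            raise ValueError("dose_per_pulse must be positive")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.r50 <= 0:
            raise ValueError("r50 must be positive")


@dataclass
class PulseProfile:
    """Normalized temporal profile of the radiation pulse.

    Unit area (sum * dt == 1) for all kinds except ``delta``, which is a
    single unit sample so that convolution with it is the identity.
    """

    samples: np.ndarray
    dt: float
    kind: str = "box"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.samples.size == 0:
            raise ValueError("pulse has no samples")

    @property
    def area(self) -> float:
        return float(np.sum(self.samples) * self.dt)

    def resample(self, dt: float) -> "PulseProfile":
        if self.kind == "delta" or math.isclose(dt, self.dt, rel_tol=1e-12):
            return self
        duration = self.samples.size * self.dt
        n = max(1, int(round(duration / dt)))
        t_new = (np.arange(n) + 0.5) * dt
        t_old = (np.arange(self.samples.size) + 0.5) * self.dt
        samples = np.interp(t_new, t_old, self.samples, left=0.0, right=0.0)
        total = samples.sum() * dt
        if total > 0:
            samples = samples / total
        return PulseProfile(samples, dt, kind=self.kind)


def make_pulse(kind: str, duration: float, dt: float) -> PulseProfile:
    """Build a unit-area pulse profile of the requested shape.

    Kinds: ``delta`` (ideal impulse), ``box`` (flat pulse), ``gaussian``
    (truncated at +-3 sigma with sigma = duration/6), ``double-gaussian``
    (two equal Gaussian sub-pulses, emulating a beam with sub-structure).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if kind == "delta":
        return PulseProfile(np.array([1.0]), dt, kind="delta")
    n = max(1, int(round(duration / dt)))
    t = (np.arange(n) + 0.5) * dt
    if kind == "box":
        samples = np.ones(n)
    elif kind == "gaussian":
        sigma = duration / 6.0 if duration > 0 else dt
        samples = np.exp(-((t - duration / 2.0) ** 2) / (2.0 * sigma**2))
    elif kind == "double-gaussian":
        sigma = duration / 12.0 if duration > 0 else dt
        samples = np.exp(
            -((t - duration / 4.0) ** 2) / (2.0 * sigma**2)
        ) + np.exp(-((t - 3.0 * duration / 4.0) ** 2) / (2.0 * sigma**2))
    else:
        raise ValueError(f"unknown pulse kind {kind!r}")
    samples = samples / (samples.sum() * dt)
    return PulseProfile(samples, dt, kind=kind)


def instantaneous_dose_rate(dose_per_pulse: float, pulse_duration: float) -> float:
    """Instantaneous dose rate in Gy/s during a single pulse."""
    if pulse_duration <= 0:
        raise ValueError("pulse_duration must be positive")
    return dose_per_pulse / pulse_duration


def imaging_frame_rate(pulse_rep_rate: float, n_average: int) -> float:
    """Frames per second achievable when each frame averages ``n_average`` pulses."""
    if pulse_rep_rate <= 0:
        raise ValueError("pulse repetition rate must be positive")
    if n_average < 1:
        raise ValueError("n_average must be >= 1")
    return pulse_rep_rate / n_average


def _beam_frame(grid: Grid, entry, direction) -> tuple[np.ndarray, list[np.ndarray]]:
    """Depth along the beam axis and lateral offsets, per voxel."""
    entry = np.asarray(entry, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    coords = grid.coords()
    rel = [coords[a] - entry[a] for a in range(grid.ndim)]
    depth = sum(rel[a] * d[a] for a in range(grid.ndim))
    lateral = []
    for a in range(grid.ndim):
        lateral.append(rel[a] - depth * d[a])
    return depth, lateral


def proton_pencil_beam(spec: ProtonBeamSpec, grid: Grid) -> DoseVolume:
    """Analytic pencil-beam dose with a Bragg peak at depth R = alpha * E^p.

    The depth-dose curve is a rising entrance plateau plus a Gaussian peak
    whose width follows range straggling (~1.2% of range), cut off distally by
    an erfc edge of width ``distal_sigma``; the lateral profile is Gaussian.
    The volume maximum equals ``fluence_scale``.
    """
    R = spec.range_m
    depth, lateral = _beam_frame(grid, spec.entry, spec.direction)
    # require the peak to sit inside the grid
    peak_point = np.asarray(spec.entry, dtype=float) + R * np.asarray(
        spec.direction, dtype=float
    )
    if not grid.contains(peak_point):
        raise ValueError(
            f"Bragg peak at depth {R * 100:.2f} cm falls outside the grid; "
            f"grid extent is {tuple(f'{e * 100:.2f} cm' for e in grid.extent)} "
            f"from origin {grid.origin}"
        )
    straggle = max(0.012 * R, 1.5 * min(grid.spacing))
    plateau = 0.35 * (1.0 + 0.45 * np.clip(depth / R, 0.0, 1.0))
    peak = np.exp(-((depth - R) ** 2) / (2.0 * straggle**2))
    distal = 0.5 * erfc((depth - R) / (np.sqrt(2.0) * spec.distal_sigma))
    ddc = (plateau * distal + peak) * (depth >= 0)
    lat2 = sum(l**2 for l in lateral)
    lat = np.exp(-lat2 / (2.0 * spec.sigma_lateral**2))
    values = ddc * lat
    peak_val = values.max()
    if peak_val > 0:
        values = values * (spec.fluence_scale / peak_val)
    else:
        values = values * 0.0
    meta = {
        "modality": "proton",
        "energy_MeV": spec.energy,
        "entry": tuple(spec.entry),
        "direction": tuple(spec.direction),
        "range_m": R,
    }
    return DoseVolume(grid, values, meta=meta)


def electron_flash_beam(spec: ElectronBeamSpec, grid: Grid) -> DoseVolume:
    """Collimated electron field: penumbra-smoothed top-hat times depth dose.

    Depth dose builds up from ``surface_dose_fraction`` at the surface to a
    plateau, then falls off through 50% of the maximum at depth ``r50`` with a
    sigmoid edge. Beam axis is the first grid axis. Maximum equals
    ``dose_per_pulse`` (Gy per pulse).
    """
    if spec.r50 >= grid.extent[0]:
        raise ValueError(
            f"r50 = {spec.r50 * 100:.1f} cm is deeper than the grid extent "
            f"{grid.extent[0] * 100:.1f} cm along the beam axis"
        )
    coords = grid.coords()
    depth = coords[0] - grid.origin[0]
    z_max = 0.4 * spec.r50
    w = 0.08 * spec.r50
    rise = np.clip(depth / z_max, 0.0, 1.0)
    buildup = spec.surface_dose_fraction + (1.0 - spec.surface_dose_fraction) * (
        3.0 * rise**2 - 2.0 * rise**3
    )
    falloff = 1.0 / (1.0 + np.exp((depth - spec.r50) / w))
    ddc = buildup * falloff

    lat = np.ones(grid.shape)
    centre = [
        grid.origin[a] + 0.5 * (grid.shape[a] - 1) * grid.spacing[a]
        for a in range(grid.ndim)
    ]
    for a in range(1, grid.ndim):
        half = 0.5 * spec.field_size[min(a - 1, len(spec.field_size) - 1)]
        x = coords[a] - centre[a]
        s = np.sqrt(2.0) * spec.penumbra_sigma
        lat = lat * 0.5 * (erf((x + half) / s) - erf((x - half) / s))
    values = ddc * lat
    peak = values.max()
    if peak > 0:
        values = values * (spec.dose_per_pulse / peak)
    meta = {
        "modality": "electron",
        "r50_m": spec.r50,
        "dose_per_pulse_Gy": spec.dose_per_pulse,
        "pulse_duration_s": spec.pulse_duration,
        "field_size_m": tuple(spec.field_size),
    }
    return DoseVolume(grid, values, meta=meta)


# --------------------------------------------------------------------------
# experiment catalog


@dataclass
class DatasetCatalog:
    """Factorial beam-energy x array-position acquisition catalog.

    Wraps a DataFrame with one row per acquisition (columns: id, modality,
    energy_MeV, shift_x_mm, shift_y_mm, excluded, split).
    """

    entries: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        df = self.entries
        usable = df[~df["excluded"]]
        out = {"total": len(df), "excluded": int(df["excluded"].sum()),
               "usable": len(usable)}
        for tag, cnt in usable["split"].value_counts().items():
            out[str(tag)] = int(cnt)
        return out

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetCatalog":
        return cls(pd.read_csv(path))


def watertank_catalog(
    n_energies: int = 7,
    n_positions: int = 5,
    n_excluded: int = 2,
    split: Sequence[int] = (20, 5, 8),
    seed: int = 0,
    energies_mev: Sequence[float] | None = None,
    shift_m: float = 1e-2,
) -> DatasetCatalog:
    """Enumerate the water-tank protocol: energies x array positions.

    Positions are the array centre plus ``shift_m`` displacements left, right,
    up and down when ``n_positions`` is 5 (additional positions extend the
    shift ring). ``n_excluded`` entries are dropped (seeded draw, emulating
    interference-corrupted acquisitions) and the remaining entries are
    partitioned into train/val/test splits of the given sizes.
    """
    total = n_energies * n_positions
    if total < n_excluded + sum(split):
        raise ValueError(
            f"{n_energies}x{n_positions}={total} entries cannot cover "
            f"{n_excluded} exclusions plus splits {tuple(split)}"
        )
    if energies_mev is None:
        energies_mev = np.linspace(70.0, 130.0, n_energies)
    elif len(energies_mev) != n_energies:
        raise ValueError("energies_mev length must equal n_energies")
    shifts = [(0.0, 0.0), (-shift_m, 0.0), (shift_m, 0.0), (0.0, shift_m), (0.0, -shift_m)]
    while len(shifts) < n_positions:
        k = len(shifts)
        ang = 2.0 * np.pi * k / 8.0
        shifts.append((shift_m * np.cos(ang), shift_m * np.sin(ang)))
    shifts = shifts[:n_positions]

    rows = []
    i = 0
    for e in energies_mev:
        for sx, sy in shifts:
            rows.append(
                {
                    "id": f"wt{i:03d}",
                    "modality": "proton",
                    "energy_MeV": float(e),
                    "shift_x_mm": sx * 1e3,
                    "shift_y_mm": sy * 1e3,
                    "excluded": False,
                    "split": "",
                }
            )
            i += 1
    df = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    excl = rng.choice(total, size=n_excluded, replace=False)
    df.loc[excl, "excluded"] = True
    usable_idx = df.index[~df["excluded"]].to_numpy()
    perm = rng.permutation(usable_idx)
    tags = ("train", "val", "test")
    start = 0
    for tag, size in zip(tags, split):
        df.loc[perm[start : start + size], "split"] = tag
        start += size
    return DatasetCatalog(df)
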