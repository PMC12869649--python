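"""Regular grids and scalar volumes.

All physical quantities are SI internally (metres, seconds, Pascals); dose is
stored in Gray. Grids use the voxel-centre convention: the physical coordinate
of voxel ``(i, j, k)`` is ``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Grid", "DoseVolume", "PressureVolume"]


@dataclass(frozen=True)
class Grid:
    """A regular rectilinear grid in 2 or 3 dimensions.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts per axis.
    spacing : tuple of float
        Voxel edge length per axis, in metres.
    origin : tuple of float
        Physical coordinate of the centre of voxel ``(0, ..., 0)``, in metres.
    """

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        ndim = len(shape)
        spacing = self.spacing
        if np.isscalar(spacing):
            spacing = (float(spacing),) * ndim
        spacing = tuple(float(s) for s in spacing)
        origin = self.origin
        if origin is None:
            origin = (0.0,) * ndim
        origin = tuple(float(o) for o in origin)
        if len(spacing) != ndim or len(origin) != ndim:
            raise ValueError("shape, spacing and origin must have equal length")
        if any(n < 1 for n in shape):
            raise ValueError("grid shape entries must be >= 1")
        if any(s <= 0 for s in spacing):
            raise ValueError("grid spacings must be positive")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def extent(self) -> tuple[float, ...]:
        """Physical length covered along each axis (edge to edge), metres."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def coords(self) -> list[np.ndarray]:
        """Meshgrid (ij-indexed) of voxel-centre coordinates, one array per axis."""
        axes = [self.axis_coords(a) for a in range(self.ndim)]
        return list(np.meshgrid(*axes, indexing="ij"))

    def index_of(self, point) -> tuple[int, ...]:
        """Nearest-voxel index of a physical point; raises if outside the grid."""
        point = np.asarray(point, dtype=float)
        if point.shape != (self.ndim,):
            raise ValueError(f"point must have {self.ndim} coordinates")
        idx = np.rint((point - np.array(self.origin)) / np.array(self.spacing))
        if np.any(idx < 0) or np.any(idx > np.array(self.shape) - 1):
            raise ValueError(
                f"point {tuple(point)} lies outside grid "
                f"(extent {self.extent}, origin {self.origin})"
            )
        return tuple(int(i) for i in idx)

    def contains(self, point) -> bool:
        try:
            self.index_of(point)
            return True
        except ValueError:
            return False


def _check_values(grid: Grid, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(
            f"{name} shape {values.shape} does not match grid shape {grid.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite values")
    return values


@dataclass
class DoseVolume:
    """Absorbed dose on a regular grid, in Gray."""

    grid: Grid
    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = _check_values(self.grid, self.values, "dose")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    def peak(self) -> tuple[tuple[int, ...], float]:
        """Index and value of the dose maximum."""
        flat = int(np.argmax(self.values))
        idx = np.unravel_index(flat, self.values.shape)
        return tuple(int(i) for i in idx), float(self.values[idx])


@dataclass
class PressureVolume:
    """Acoustic pressure on a regular grid, in Pascals.

    ``role`` distinguishes the physical initial pressure (``p0``, non-negative),
    a time-reversal reconstruction (``p_rec``, may go negative under limited
    view), and a network prediction (``p_pred``).
    """

    grid: Grid
    values: np.ndarray
    role: str = "p0"

    _ROLES = ("p0", "p_rec", "p_pred")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")
        self.values = _check_values(self.grid, self.values, "pressure")
        if self.role == "p0" and np.any(self.values < 0):
            raise ValueError("initial pressure (role='p0') must be non-negative")
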