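"""Single-point pressure-to-dose calibration.

Reconstructed pressure is on an arbitrary linear scale (acquisition gains are
unknown), so absolute dose is recovered with one reference point: at a
location where the delivered dose D_c is known from machine log files, the
reconstructed pressure p_c fixes the scalar factor K = D_c / p_c, and
K * p_pred converts the whole map to dose. Because both D_c's pressure and
the map scale linearly with any global sinogram gain, K is invariant to that
gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DoseVolume, PressureVolume

__all__ = ["CalibrationFactor", "calibration_factor", "apply_calibration", "pick_calibration_point"]


@dataclass(frozen=True)
class CalibrationFactor:
    """K = D_c / p_c, in cGy per relative pressure unit, with provenance."""

    k: float
    reference_dose: float
    reference_pressure: float
    reference_location: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.reference_pressure <= 0:
            raise ValueError(
                "calibration point has no signal (reference pressure <= 0)"
            )
        expected = self.reference_dose / self.reference_pressure
        if not np.isclose(self.k, expected, rtol=1e-12):
            raise ValueError("k must equal reference_dose / reference_pressure")


def calibration_factor(
    d_c: float, p_c: float, location: tuple[int, ...] | None = None
) -> CalibrationFactor:
    """Build the calibration factor from a known dose and measured pressure."""
    if d_c < 0:
        raise ValueError("reference dose must be non-negative")
    if p_c <= 0:
        raise ValueError("calibration point has no signal (p_c <= 0)")
    return CalibrationFactor(
        k=d_c / p_c,
        reference_dose=d_c,
        reference_pressure=p_c,
        reference_location=location,
    )


def pick_calibration_point(
    p_pred: PressureVolume,
    point: tuple[int, ...] | str = "auto-peak",
    neighborhood: int = 1,
) -> tuple[tuple[int, ...], float]:
    """Select the calibration voxel and its pressure value.

    ``auto-peak`` takes the argmax of the prediction (the Bragg peak for a
    pencil beam); an explicit voxel index may be given instead. With
    ``neighborhood = 3`` the pressure is averaged over a 3^ndim box, damping
    single-voxel noise.
    """
    vals = p_pred.values
    if point == "auto-peak":
        idx = np.unravel_index(int(np.argmax(vals)), vals.shape)
    else:
        idx = tuple(int(i) for i in point)
    if neighborhood > 1:
        h = neighborhood // 2
        sl = tuple(
            slice(max(0, i - h), min(n, i + h + 1)) for i, n in zip(idx, vals.shape)
        )
        p_c = float(vals[sl].mean())
    else:
        p_c = float(vals[idx])
    return tuple(int(i) for i in idx), p_c


def apply_calibration(p_pred: PressureVolume, k: CalibrationFactor) -> DoseVolume:
    """Convert a relative pressure map to dose (cGy) via K * p_pred."""
    dose = np.maximum(k.k * p_pred.values, 0.0)
    return DoseVolume(
        p_pred.grid,
        dose,
        meta={
            "units": "cGy",
            "calibration_k": k.k,
            "reference_dose_cGy": k.reference_dose,
        },
    )
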