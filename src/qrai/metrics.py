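"""Dosimetric and image-quality evaluation.

The gamma index is the standard radiotherapy acceptance metric combining a
dose-difference criterion (as a fraction of the global reference maximum) and
a distance-to-agreement criterion: a reference voxel passes when some nearby
evaluated voxel agrees in dose within the combined tolerance,

    gamma(r) = min_{r'} sqrt( |r - r'|^2 / dd^2 + (D_gt(r) - D_pred(r'))^2 / dD^2 ).

SSIM is computed globally, from the whole-volume means, variances and
covariance; PSNR uses the root-mean-square error against the reference
maximum. Both follow the printed single-window formulas rather than the
sliding-window variants (a windowed SSIM is available behind a flag).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DoseVolume

__all__ = [
    "GammaCriteria",
    "MetricReport",
    "gamma_map",
    "ssim",
    "psnr",
    "evaluate_methods",
]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma comparison criteria: DTA in metres, dose in fraction of max(ref).

    The defaults are the clinical 3 mm / 3% with a 10% low-dose threshold and
    global (max of reference) normalization.
    """

    delta_d: float = 3e-3
    delta_dose: float = 0.03
    low_dose_threshold: float = 0.10
    search_factor: float = 3.0
    refine: int = 1  # grid refinement factor for the evaluated volume

    def __post_init__(self) -> None:
        if self.delta_d <= 0:
            raise ValueError("delta_d must be positive")
        if not (0.0 < self.delta_dose < 1.0):
            raise ValueError("delta_dose must lie in (0, 1)")
        if not (0.0 <= self.low_dose_threshold < 1.0):
            raise ValueError("low_dose_threshold must lie in [0, 1)")
        if self.refine < 1:
            raise ValueError("refine must be >= 1")


def _values(v) -> np.ndarray:
    return v.values if hasattr(v, "values") and not isinstance(v, np.ndarray) else np.asarray(v, dtype=float)


def gamma_map(
    d_gt: DoseVolume, d_pred: DoseVolume, crit: GammaCriteria = GammaCriteria()
) -> tuple[np.ndarray, float]:
    """Gamma field and pass rate of ``d_pred`` against reference ``d_gt``.

    Reference voxels below the low-dose threshold are excluded (NaN in the
    returned field). The evaluated-position search is exhaustive over voxel
    offsets within ``search_factor * delta_d``; with ``refine > 1`` the
    evaluated volume is first interpolated onto a finer grid. The result is
    asymmetric in (reference, evaluated), as the definition prescribes.
    """
    gt = _values(d_gt)
    pr = _values(d_pred)
    if hasattr(d_gt, "grid"):
        spacing = np.asarray(d_gt.grid.spacing)
    else:
        spacing = np.ones(gt.ndim)
    if gt.shape != pr.shape:
        raise ValueError("reference and evaluated volumes must share a grid")
    ref_max = gt.max()
    if ref_max <= 0:
        raise ValueError("reference dose is identically zero")
    dd_abs = crit.delta_dose * ref_max

    if crit.refine > 1:
        from scipy.ndimage import map_coordinates

        # fine index f maps to coarse coordinate f / refine, so coarse voxel i
        # sits exactly at fine index i * refine
        fine_axes = [
            np.arange((n - 1) * crit.refine + 1) / crit.refine for n in pr.shape
        ]
        mesh = np.meshgrid(*fine_axes, indexing="ij")
        pr_f = map_coordinates(pr, np.stack(mesh), order=1)
        spacing_f = spacing / crit.refine
    else:
        pr_f = pr
        spacing_f = spacing

    radius = crit.search_factor * crit.delta_d
    ranges = [int(np.floor(radius / s)) for s in spacing_f]
    nd = gt.ndim
    scale = crit.refine

    best = np.full(gt.shape, np.inf)
    for off in itertools.product(*[range(-r, r + 1) for r in ranges]):
        dist2 = sum((o * s) ** 2 for o, s in zip(off, spacing_f))
        if dist2 > radius**2:
            continue
        base = dist2 / crit.delta_d**2
        # reference voxel i maps to fine voxel i*scale; evaluated at i*scale+off
        src = []
        dst = []
        valid = True
        for ax in range(nd):
            n_ref = gt.shape[ax]
            lo = off[ax]
            hi = lo + (n_ref - 1) * scale
            i0 = max(0, int(np.ceil(-lo / scale)))
            i1 = n_ref - 1 - max(0, int(np.ceil((hi - (pr_f.shape[ax] - 1)) / scale)))
            if i1 < i0:
                valid = False
                break
            src.append(slice(i0, i1 + 1))
            dst.append(slice(i0 * scale + lo, i1 * scale + lo + 1, scale))
        if not valid:
            continue
        diff = gt[tuple(src)] - pr_f[tuple(dst)]
        cand = base + diff**2 / dd_abs**2
        np.minimum(best[tuple(src)], cand, out=best[tuple(src)])

    gamma = np.sqrt(best)
    mask = gt >= crit.low_dose_threshold * ref_max
    # a voxel exactly at the combined tolerance passes; the tiny relative
    # slack keeps the boundary case from failing to float roundoff
    pass_rate = (
        float(np.mean(gamma[mask] <= 1.0 + 1e-9)) if mask.any() else float("nan")
    )
    gamma = np.where(mask, gamma, np.nan)
    return gamma, pass_rate


def ssim(
    ref,
    test,
    k1: float = 0.01,
    k2: float = 0.03,
    dynamic_range: float | None = None,
    windowed: bool = False,
    win_size: int = 7,
) -> float:
    """Structural similarity from global image statistics.

    c1 = (k1 L)^2 and c2 = (k2 L)^2 stabilize the ratio; the dynamic range L
    defaults to the reference maximum. ``windowed=True`` averages a local
    (uniform-window) SSIM map instead of using global statistics.
    """
    r = _values(ref)
    t = _values(test)
    if r.shape != t.shape:
        raise ValueError("ref and test must share a shape")
    if dynamic_range is None:
        dynamic_range = float(r.max())
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    if windowed:
        from scipy.ndimage import uniform_filter

        mu_r = uniform_filter(r, win_size)
        mu_t = uniform_filter(t, win_size)
        var_r = uniform_filter(r * r, win_size) - mu_r**2
        var_t = uniform_filter(t * t, win_size) - mu_t**2
        cov = uniform_filter(r * t, win_size) - mu_r * mu_t
        s = ((2 * mu_r * mu_t + c1) * (2 * cov + c2)) / (
            (mu_r**2 + mu_t**2 + c1) * (var_r + var_t + c2)
        )
        return float(s.mean())
    mu_r, mu_t = r.mean(), t.mean()
    var_r, var_t = r.var(), t.var()
    cov = np.mean((r - mu_r) * (t - mu_t))
    return float(
        (2 * mu_r * mu_t + c1)
        * (2 * cov + c2)
        / ((mu_r**2 + mu_t**2 + c1) * (var_r + var_t + c2))
    )


def psnr(ref, test, mode: str = "rmse") -> float:
    """Peak signal-to-noise ratio in dB.

    ``mode='rmse'`` (default): 20 log10( sqrt(n_voxels) * max|ref| / ||test - ref||_2 ),
    the standard peak-over-RMSE reading. ``mode='literal'`` uses the raw voxel
    count as the prefactor instead of its square root. Identical inputs return
    +inf.
    """
    r = _values(ref)
    t = _values(test)
    if r.shape != t.shape:
        raise ValueError("ref and test must share a shape")
    peak = np.abs(r).max()
    if peak <= 0:
        raise ValueError("reference has no nonzero values")
    l2 = float(np.linalg.norm(t - r))
    if l2 == 0:
        return float("inf")
    if mode == "rmse":
        pref = np.sqrt(r.size)
    elif mode == "literal":
        pref = r.size
    else:
        raise ValueError("mode must be 'rmse' or 'literal'")
    return float(20.0 * np.log10(pref * peak / l2))


@dataclass
class MetricReport:
    """Per-method metric table with mean +- sd aggregation across samples."""

    per_sample: pd.DataFrame  # columns: method, sample, ssim, psnr, gamma_pass

    @property
    def summary(self) -> pd.DataFrame:
        return self.per_sample.groupby("method")[["ssim", "psnr", "gamma_pass"]].agg(
            ["mean", "std"]
        )

    def mean(self, method: str, metric: str) -> float:
        df = self.per_sample
        return float(df.loc[df["method"] == method, metric].mean())

    def to_csv(self, path) -> None:
        self.per_sample.to_csv(path, index=False)


def evaluate_methods(
    samples: list[dict],
    crit: GammaCriteria = GammaCriteria(),
    reference_key: str = "p0",
) -> MetricReport:
    """Score every method volume in each sample dict against the reference.

    Each sample maps names to volumes; the entry under ``reference_key`` is
    ground truth and every other entry is treated as a method to score.
    """
    if not samples:
        raise ValueError("no samples to evaluate")
    rows = []
    for i, sample in enumerate(samples):
        ref = sample[reference_key]
        for name, vol in sample.items():
            if name == reference_key:
                continue
            _, rate = gamma_map(ref, vol, crit)
            rows.append(
                {
                    "method": name,
                    "sample": i,
                    "ssim": ssim(ref, vol),
                    "psnr": psnr(ref, vol),
                    "gamma_pass": rate,
                }
            )
    return MetricReport(pd.DataFrame(rows))
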