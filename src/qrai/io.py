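"""HDF5 containers for volumes, media and sinograms, plus YAML configs.

Every gridded dataset carries ``spacing``, ``origin`` and ``units`` attributes
so a file is self-describing; round trips are lossless. Values with NaN or
infinities are refused at write time, mirroring the in-memory invariants.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .grid import Grid, DoseVolume, PressureVolume
from .acoustics import AcousticMedium
from .twin import Sinogram

__all__ = [
    "write_volume",
    "read_volume",
    "write_medium",
    "read_medium",
    "write_sinogram",
    "read_sinogram",
    "load_config",
    "config_hash",
]

_UNITS = {"dose": "Gy", "pressure": "Pa"}


def _check_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError(f"refusing to write non-finite {what} values")


def _write_grid_attrs(ds, grid: Grid) -> None:
    ds.attrs["spacing"] = np.asarray(grid.spacing)
    ds.attrs["origin"] = np.asarray(grid.origin)


def _read_grid(ds) -> Grid:
    for attr in ("spacing", "origin"):
        if attr not in ds.attrs:
            raise KeyError(f"container is missing required attribute {attr!r}")
    return Grid(
        shape=ds.shape,
        spacing=tuple(ds.attrs["spacing"]),
        origin=tuple(ds.attrs["origin"]),
    )


def write_volume(path, volume) -> None:
    """Write a DoseVolume (`dose` dataset) or PressureVolume (`pressure`)."""
    path = Path(path)
    if isinstance(volume, DoseVolume):
        name, units, extra = "dose", "Gy", dict(volume.meta)
    elif isinstance(volume, PressureVolume):
        name, units, extra = "pressure", "Pa", {"role": volume.role}
    else:
        raise TypeError(f"cannot write object of type {type(volume).__name__}")
    _check_finite(volume.values, name)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(name, data=volume.values)
        _write_grid_attrs(ds, volume.grid)
        ds.attrs["units"] = units
        if extra:
            ds.attrs["meta"] = json.dumps(extra, default=str)


def read_volume(path):
    """Read a volume container back into its original type."""
    with h5py.File(Path(path), "r") as f:
        if "dose" in f:
            ds = f["dose"]
            grid = _read_grid(ds)
            if ds.attrs.get("units") != "Gy":
                raise ValueError(
                    f"expected dose units 'Gy', found {ds.attrs.get('units')!r}"
                )
            meta = json.loads(ds.attrs.get("meta", "{}"))
            return DoseVolume(grid, ds[...], meta=meta)
        if "pressure" in f:
            ds = f["pressure"]
            grid = _read_grid(ds)
            meta = json.loads(ds.attrs.get("meta", "{}"))
            return PressureVolume(grid, ds[...], role=meta.get("role", "p0"))
    raise KeyError("container holds neither a 'dose' nor a 'pressure' dataset")


def write_medium(path, medium: AcousticMedium) -> None:
    with h5py.File(Path(path), "w") as f:
        for name in ("c", "rho", "grueneisen"):
            arr = getattr(medium, name)
            _check_finite(arr, name)
            ds = f.create_dataset(name, data=arr)
            _write_grid_attrs(ds, medium.grid)
        f.attrs["eta_th"] = medium.eta_th
        if medium.alpha_att is not None:
            f.create_dataset("alpha_att", data=medium.alpha_att)
            f.attrs["att_power"] = medium.att_power
            f.attrs["att_ref_freq"] = medium.att_ref_freq


def read_medium(path) -> AcousticMedium:
    with h5py.File(Path(path), "r") as f:
        for name in ("c", "rho", "grueneisen"):
            if name not in f:
                raise KeyError(f"medium container is missing dataset {name!r}")
        grid = _read_grid(f["c"])
        kwargs = {}
        if "alpha_att" in f:
            kwargs = {
                "alpha_att": f["alpha_att"][...],
                "att_power": float(f.attrs["att_power"]),
                "att_ref_freq": float(f.attrs["att_ref_freq"]),
            }
        return AcousticMedium(
            grid,
            c=f["c"][...],
            rho=f["rho"][...],
            grueneisen=f["grueneisen"][...],
            eta_th=float(f.attrs.get("eta_th", 1.0)),
            **kwargs,
        )


def write_sinogram(path, s: Sinogram) -> None:
    _check_finite(s.data, "sinogram")
    with h5py.File(Path(path), "w") as f:
        ds = f.create_dataset("data", data=s.data)
        ds.attrs["dt"] = s.dt
        ds.attrs["t0"] = s.t0
        ds.attrs["units_flag"] = s.units_flag
        f.create_dataset("channel_map", data=s.channel_map)
        if s.element_centers is not None:
            f.create_dataset("element_centers", data=s.element_centers)


def read_sinogram(path) -> Sinogram:
    with h5py.File(Path(path), "r") as f:
        if "data" not in f:
            raise KeyError("sinogram container is missing the 'data' dataset")
        ds = f["data"]
        for attr in ("dt", "t0"):
            if attr not in ds.attrs:
                raise KeyError(f"sinogram is missing required attribute {attr!r}")
        return Sinogram(
            ds[...],
            dt=float(ds.attrs["dt"]),
            t0=float(ds.attrs["t0"]),
            units_flag=str(ds.attrs.get("units_flag", "relative")),
            channel_map=f["channel_map"][...] if "channel_map" in f else None,
            element_centers=f["element_centers"][...]
            if "element_centers" in f
            else None,
        )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, for provenance stamps."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
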