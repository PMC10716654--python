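"""Space-time environmental state consumed by the population simulator.

`LandscapeSeries` holds per-generation, per-cell habitat suitability (the
niche-model projection in [0, 1]), land-use-adjusted forage biomass, the ice
mask, and the dispersal-friction multiplier. `HumanField` holds the relative
human abundance surface (mean and cell-wise standard deviation). Both
round-trip through NetCDF with dims (time, row, col) and a time coordinate in
years BP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import xarray as xr

from .grid import GridSpec


def _check_shape(name: str, arr: np.ndarray, grid: GridSpec) -> np.ndarray:
    arr = np.asarray(arr, dtype=float) if arr.dtype != bool else np.asarray(arr)
    if arr.shape != grid.shape:
        raise ValueError(f"{name} has shape {arr.shape}, expected {grid.shape}")
    return arr


@dataclass
class LandscapeSeries:
    """Per-cell, per-generation environmental state.

    suitability already includes the land-use reduction; the companion fields
    ``suitability_nolanduse``/``biomass_raw``/``friction_nolanduse`` carry the
    counterfactual (land use never happens) variants used by scenario runs.
    """

    grid: GridSpec
    suitability: np.ndarray          # (T, R, C) in [0, 1]
    biomass_adjusted: np.ndarray     # (T, R, C) >= 0
    ice: np.ndarray                  # (T, R, C) bool
    friction: np.ndarray             # (T, R, C) in [0, 1]
    suitability_nolanduse: np.ndarray | None = None
    biomass_raw: np.ndarray | None = None
    friction_nolanduse: np.ndarray | None = None
    temperature: np.ndarray | None = None  # mean annual temperature, deg C

    def __post_init__(self) -> None:
        self.suitability = _check_shape("suitability", np.asarray(self.suitability, float), self.grid)
        self.biomass_adjusted = _check_shape("biomass_adjusted", np.asarray(self.biomass_adjusted, float), self.grid)
        self.ice = _check_shape("ice", np.asarray(self.ice, bool), self.grid)
        self.friction = _check_shape("friction", np.asarray(self.friction, float), self.grid)
        if np.any(self.suitability < -1e-12) or np.any(self.suitability > 1 + 1e-12):
            raise ValueError("suitability must lie in [0, 1]")
        if np.any(self.friction < -1e-12) or np.any(self.friction > 1 + 1e-12):
            raise ValueError("friction must lie in [0, 1]")
        if np.any(self.suitability[self.ice] != 0):
            raise ValueError("ice cells must have suitability 0")
        if np.any(self.friction[self.ice] != 0):
            raise ValueError("ice cells must have friction 0")

    def copy(self) -> "LandscapeSeries":
        kw = {}
        for name in (
            "suitability", "biomass_adjusted", "ice", "friction",
            "suitability_nolanduse", "biomass_raw", "friction_nolanduse",
            "temperature",
        ):
            v = getattr(self, name)
            kw[name] = None if v is None else v.copy()
        return LandscapeSeries(grid=self.grid, **kw)

    def to_dataset(self) -> xr.Dataset:
        g = self.grid
        coords = {
            "time": ("time", g.times_bp, {"units": "years BP"}),
            "row": np.arange(g.n_rows),
            "col": np.arange(g.n_cols),
        }
        data = {
            "suitability": (("time", "row", "col"), self.suitability),
            "biomass_adjusted": (("time", "row", "col"), self.biomass_adjusted),
            "ice": (("time", "row", "col"), self.ice.astype(np.int8)),
            "friction": (("time", "row", "col"), self.friction),
        }
        for name in ("suitability_nolanduse", "biomass_raw", "friction_nolanduse", "temperature"):
            v = getattr(self, name)
            if v is not None:
                data[name] = (("time", "row", "col"), v)
        ds = xr.Dataset(data, coords=coords)
        ds.attrs.update(
            cell_width_km=g.cell_width_km,
            cell_height_km=g.cell_height_km,
            step_years=g.step_years,
        )
        return ds

    def to_netcdf(self, path: str | Path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "LandscapeSeries":
        times = np.asarray(ds["time"].values, float)
        grid = GridSpec(
            n_rows=ds.sizes["row"],
            n_cols=ds.sizes["col"],
            cell_width_km=float(ds.attrs["cell_width_km"]),
            cell_height_km=float(ds.attrs["cell_height_km"]),
            t_start_bp=float(times[0]),
            t_end_bp=float(times[-1]),
            step_years=float(ds.attrs["step_years"]),
        )
        kw = {}
        for name in ("suitability_nolanduse", "biomass_raw", "friction_nolanduse", "temperature"):
            if name in ds:
                kw[name] = np.asarray(ds[name].values, float)
        return cls(
            grid=grid,
            suitability=np.asarray(ds["suitability"].values, float),
            biomass_adjusted=np.asarray(ds["biomass_adjusted"].values, float),
            ice=np.asarray(ds["ice"].values).astype(bool),
            friction=np.asarray(ds["friction"].values, float),
            **kw,
        )

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "LandscapeSeries":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


@dataclass
class HumanField:
    """Relative human abundance surface: per-cell mean and s.d. per step.

    After `scale_ne` the mean lies in [0, 1]; `native_step_years` is the
    temporal resolution of the underlying demographic-model output (25 years
    in the source data, interpolated to the generational 10-year step).
    """

    mean: np.ndarray                # (T, R, C)
    sd: np.ndarray                  # (T, R, C) >= 0
    times_bp: np.ndarray            # (T,) descending
    native_step_years: float = 25.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.sd = np.asarray(self.sd, float)
        self.times_bp = np.asarray(self.times_bp, float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd shapes differ")
        if self.mean.shape[0] != self.times_bp.shape[0]:
            raise ValueError("time axis length mismatch")
        if np.any(self.sd < 0):
            raise ValueError("sd must be nonnegative")
        if np.any(~np.isfinite(self.mean)) or np.any(~np.isfinite(self.sd)):
            raise ValueError("human field contains non-finite values")

    @property
    def n_steps(self) -> int:
        return self.mean.shape[0]

    def copy(self) -> "HumanField":
        return HumanField(
            mean=self.mean.copy(),
            sd=self.sd.copy(),
            times_bp=self.times_bp.copy(),
            native_step_years=self.native_step_years,
        )

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "mean_ne": (("time", "row", "col"), self.mean),
                "sd_ne": (("time", "row", "col"), self.sd),
            },
            coords={
                "time": ("time", self.times_bp, {"units": "years BP"}),
                "row": np.arange(self.mean.shape[1]),
                "col": np.arange(self.mean.shape[2]),
            },
        )
        ds.attrs["native_step_years"] = self.native_step_years
        return ds

    def to_netcdf(self, path: str | Path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "HumanField":
        return cls(
            mean=np.asarray(ds["mean_ne"].values, float),
            sd=np.asarray(ds["sd_ne"].values, float),
            times_bp=np.asarray(ds["time"].values, float),
            native_step_years=float(ds.attrs.get("native_step_years", 25.0)),
        )

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "HumanField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())
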