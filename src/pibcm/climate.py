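"""Gridded SST climatologies, coarsening, depth masking and delta-method
statistical downscaling.

The working container is :class:`ClimGrid`: a regular lat/lon grid of 12
monthly climatological mean SST layers with an explicit validity mask
(masked cells hold NaN, never a silent zero).  Downscaling follows the
delta method: the (future - historical) climate-model climatology is
interpolated to the baseline grid with an exact thin-plate spline and
added to the observed baseline climatology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RBFInterpolator

from .errors import DegenerateDesignError, DomainError, GeometryError

EARTH_RADIUS_KM = 6371.0


@dataclass
class ClimGrid:
    """Monthly climatology on a regular lat/lon grid of cell centers.

    ``monthly_mean`` has shape (12, nlat, nlon) in degC; invalid cells are
    NaN in every month.  ``valid_mask`` is derived from month 0 and is
    required to be identical across months.
    """

    lat: np.ndarray
    lon: np.ndarray
    monthly_mean: np.ndarray

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.monthly_mean = np.asarray(self.monthly_mean, dtype=float)
        if self.monthly_mean.shape != (12, self.lat.size, self.lon.size):
            raise GeometryError(
                f"monthly_mean shape {self.monthly_mean.shape} does not match "
                f"(12, {self.lat.size}, {self.lon.size})"
            )
        if np.any(np.diff(self.lat) <= 0) or np.any(np.diff(self.lon) <= 0):
            raise GeometryError("lat/lon centers must be strictly ascending")
        month_valid = ~np.isnan(self.monthly_mean)
        if not (month_valid == month_valid[0]).all():
            raise GeometryError("validity mask must be identical across months")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.monthly_mean[0])

    def same_geometry(self, other: "ClimGrid") -> bool:
        return (
            self.lat.shape == other.lat.shape
            and self.lon.shape == other.lon.shape
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
        )

    def annual_mean(self) -> np.ndarray:
        """Mean of the 12 monthly layers (NaN where masked)."""
        return self.monthly_mean.mean(axis=0)

    # -- I/O ---------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "sst": (
                    ("month", "lat", "lon"),
                    self.monthly_mean,
                    {"units": "degC", "long_name": "climatological monthly mean SST"},
                )
            },
            coords={
                "month": np.arange(1, 13),
                "lat": ("lat", self.lat, {"units": "degrees_north"}),
                "lon": ("lon", self.lon, {"units": "degrees_east"}),
            },
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ClimGrid":
        return cls(ds["lat"].values, ds["lon"].values, ds["sst"].values)

    @classmethod
    def from_netcdf(cls, path) -> "ClimGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


@dataclass(frozen=True)
class CellExtremes:
    """Per-cell climatological extremes and their range."""

    t_min_C: float
    t_max_C: float

    @property
    def sst_range_C(self) -> float:
        return self.t_max_C - self.t_min_C


def monthly_climatology(
    daily: xr.DataArray, years: tuple[int, int] | None = None
) -> ClimGrid:
    """Average a daily (time, lat, lon) SST series into 12 monthly layers.

    Month membership is by calendar month of the timestamp; all days of a
    month across all (selected) years are pooled into one arithmetic
    mean.  Cells with no finite data are masked.
    """
    if daily.sizes.get("time", 0) == 0:
        raise DomainError("daily series is empty")
    if years is not None:
        daily = daily.sel(time=slice(f"{years[0]}-01-01", f"{years[1]}-12-31"))
        if daily.sizes["time"] == 0:
            raise DomainError(f"no data within years {years}")
    clim = daily.groupby("time.month").mean("time", skipna=True)
    clim = clim.reindex(month=np.arange(1, 13))
    data = clim.transpose("month", "lat", "lon").values
    # enforce a month-invariant mask: a cell is valid only if all 12 months are
    nan_any = np.isnan(data).any(axis=0)
    data[:, nan_any] = np.nan
    return ClimGrid(daily["lat"].values, daily["lon"].values, data)


def extremes_and_range(clim: ClimGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(t_min, t_max, range) over the 12 monthly layers, NaN where masked."""
    t_min = np.where(clim.valid_mask, clim.monthly_mean.min(axis=0), np.nan)
    t_max = np.where(clim.valid_mask, clim.monthly_mean.max(axis=0), np.nan)
    return t_min, t_max, t_max - t_min


def extremes_frame(clim: ClimGrid) -> pd.DataFrame:
    """Per-cell extremes as a tidy table (valid cells only)."""
    t_min, t_max, rng = extremes_and_range(clim)
    ii, jj = np.nonzero(clim.valid_mask)
    return pd.DataFrame(
        {
            "lat": clim.lat[ii],
            "lon": clim.lon[jj],
            "t_min_C": t_min[ii, jj],
            "t_max_C": t_max[ii, jj],
            "sst_range_C": rng[ii, jj],
        }
    )


def coarsen(fine: ClimGrid, factor: int) -> ClimGrid:
    """Block-average a fine grid to a coarser resolution.

    Each coarse cell is the cos(latitude)-weighted mean of its
    factor x factor block of fine cells, ignoring masked members; a
    coarse cell is masked only when every child is masked.
    """
    nlat, nlon = fine.lat.size, fine.lon.size
    if nlat % factor or nlon % factor:
        raise GeometryError(
            f"grid dims ({nlat}, {nlon}) not divisible by coarsening factor {factor}"
        )
    w = np.cos(np.deg2rad(fine.lat))[None, :, None] * np.ones((1, 1, nlon))
    data = fine.monthly_mean
    valid = ~np.isnan(data)
    wv = np.where(valid, w, 0.0)
    num = np.where(valid, data * w, 0.0)
    shape = (12, nlat // factor, factor, nlon // factor, factor)
    num_b = num.reshape(shape).sum(axis=(2, 4))
    den_b = wv.reshape(shape).sum(axis=(2, 4))
    with np.errstate(invalid="ignore"):
        coarse = np.where(den_b > 0, num_b / np.where(den_b > 0, den_b, 1.0), np.nan)
    lat_c = fine.lat.reshape(nlat // factor, factor).mean(axis=1)
    lon_c = fine.lon.reshape(nlon // factor, factor).mean(axis=1)
    nan_any = np.isnan(coarse).any(axis=0)
    coarse[:, nan_any] = np.nan
    return ClimGrid(lat_c, lon_c, coarse)


def depth_mask(
    bathymetry: xr.DataArray, d_min: float = 0.0, d_max: float = 10.0
) -> np.ndarray:
    """Boolean habitat mask from a positive-down bathymetry grid.

    True where depth lies in the closed interval [d_min, d_max]; land
    (depth <= 0 or non-finite) is always False.
    """
    depth = np.asarray(bathymetry.values, dtype=float)
    ocean = np.isfinite(depth) & (depth > 0)
    return ocean & (depth >= d_min) & (depth <= d_max)


def tps_interpolate(
    nodes: np.ndarray,
    values: np.ndarray,
    targets: np.ndarray,
    smoothing: float = 0.0,
) -> np.ndarray:
    """Exact thin-plate-spline interpolation of scattered (lat, lon, value)
    nodes onto target points.

    Uses the r^2 log r radial kernel plus an affine polynomial part with
    zero smoothing by default, so node values and any affine function of
    (lat, lon) are reproduced exactly.
    """
    nodes = np.asarray(nodes, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if nodes.ndim != 2 or nodes.shape[1] != 2:
        raise DomainError("nodes must be an (n, 2) array of (lat, lon)")
    if nodes.shape[0] < 3:
        raise DegenerateDesignError("thin-plate spline needs >= 3 nodes")
    design = np.column_stack([np.ones(nodes.shape[0]), nodes])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateDesignError("thin-plate spline nodes are collinear")
    rbf = RBFInterpolator(
        nodes, values, kernel="thin_plate_spline", degree=1, smoothing=smoothing
    )
    return rbf(targets)


def delta_downscale(
    model_hist: ClimGrid,
    model_future: ClimGrid,
    baseline: ClimGrid,
    smoothing: float = 0.0,
) -> ClimGrid:
    """Additive delta-method downscaling.

    Per month: delta = future - historical on the coarse model grid;
    the delta is regridded to the baseline cell centers by thin-plate
    spline and added to the baseline climatology.  The baseline mask is
    preserved (no cell is ever unmasked).
    """
    if not model_hist.same_geometry(model_future):
        raise GeometryError("model historical and future grids differ in geometry")
    if model_hist.monthly_mean.shape[0] != baseline.monthly_mean.shape[0]:
        raise GeometryError("month-count mismatch between model and baseline")

    lat2d, lon2d = np.meshgrid(model_hist.lat, model_hist.lon, indexing="ij")
    blat2d, blon2d = np.meshgrid(baseline.lat, baseline.lon, indexing="ij")
    bmask = baseline.valid_mask
    targets = np.column_stack([blat2d[bmask], blon2d[bmask]])

    out = np.full_like(baseline.monthly_mean, np.nan)
    for m in range(12):
        delta = model_future.monthly_mean[m] - model_hist.monthly_mean[m]
        node_mask = ~np.isnan(delta)
        nodes = np.column_stack([lat2d[node_mask], lon2d[node_mask]])
        interp = tps_interpolate(nodes, delta[node_mask], targets, smoothing)
        layer = np.full(bmask.shape, np.nan)
        layer[bmask] = baseline.monthly_mean[m][bmask] + interp
        out[m] = layer
    return ClimGrid(baseline.lat, baseline.lon, out)


def ensemble_mean(members: Sequence[ClimGrid]) -> ClimGrid:
    """Unweighted per-cell, per-month mean across ensemble members."""
    if not members:
        raise DomainError("ensemble is empty")
    first = members[0]
    for m in members[1:]:
        if not first.same_geometry(m):
            raise GeometryError("ensemble members differ in geometry")
        if not (first.valid_mask == m.valid_mask).all():
            raise GeometryError("ensemble members differ in mask")
    stack = np.stack([m.monthly_mean for m in members])
    return ClimGrid(first.lat, first.lon, stack.mean(axis=0))


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance between points on a spherical Earth (km)."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlmb = np.deg2rad(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
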