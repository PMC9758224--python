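"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline's external data needs so that every
stage can be exercised end-to-end without downloads:

* Arrhenius rate data — exponential in inverse temperature with a known
  activation energy and multiplicative lognormal noise (additive on the
  log scale the regression uses, so noise-free recovery is exact and
  noisy recovery unbiased on the fitted scale);
* coastal daily SST with a latitudinal mean gradient, a seasonal cycle
  whose amplitude grows with latitude (mid-latitude estuaries see the
  widest ranges), an optional linear warming trend and interannual
  noise, together with a west-coast shelf bathymetry and a smooth
  habitat-probability field on the half-degree grid;
* a coarse climate-model historical/future pair whose (future - hist)
  delta is a known constant, affine or smooth-bump field, returned
  alongside for oracle checks.

All generators are pure functions of (spec, seed): reruns are
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import xarray as xr

from .climate import ClimGrid, depth_mask
from .errors import DomainError, GeometryError
from .habitat import HabitatMap
from .mte import BOLTZMANN_EV_PER_K, CELSIUS_OFFSET, RateMeasurement, Subpopulation


def gen_arrhenius_measurements(
    E_true: float,
    ln_A0: float,
    temps_C: list[float],
    noise_sd: float,
    n_reps: int,
    seed: int,
    species: str = "synthetic",
    subpopulation: Subpopulation = Subpopulation.UNSPECIFIED,
    mass_g: float = 10.0,
) -> list[RateMeasurement]:
    """Rates drawn from the Arrhenius model with lognormal noise.

    rate = exp(ln_A0 - E_true/(K*T_K) + eps), eps ~ N(0, noise_sd^2).
    """
    if not temps_C:
        raise DomainError("temps_C must be non-empty")
    if noise_sd < 0:
        raise DomainError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        for t in temps_C:
            log_rate = ln_A0 - E_true / (BOLTZMANN_EV_PER_K * (t + CELSIUS_OFFSET))
            if noise_sd > 0:
                log_rate += rng.normal(0.0, noise_sd)
            out.append(
                RateMeasurement(
                    species=species,
                    subpopulation=subpopulation,
                    mass_g=mass_g,
                    temp_C=t,
                    rate=math.exp(log_rate),
                )
            )
    return out


@dataclass(frozen=True)
class DeltaSpec:
    """Description of the known (future - historical) warming field.

    constant: delta = a.
    affine:   delta = a + b*lat + c*lon.
    bump:     delta = a * exp(-((lat-lat0)^2+(lon-lon0)^2)/(2*width^2)).
    """

    kind: Literal["constant", "affine", "bump"] = "constant"
    a: float = 2.0
    b: float = 0.0
    c: float = 0.0
    lat0: float = 0.0
    lon0: float = 0.0
    width: float = 2.0

    def __call__(self, lat, lon, month: int | None = None):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if self.kind == "constant":
            return np.broadcast_to(self.a, np.broadcast_shapes(lat.shape, lon.shape)).copy()
        if self.kind == "affine":
            return self.a + self.b * lat + self.c * lon
        if self.kind == "bump":
            r2 = (lat - self.lat0) ** 2 + (lon - self.lon0) ** 2
            return self.a * np.exp(-r2 / (2 * self.width**2))
        raise DomainError(f"unknown delta kind {self.kind!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """Study-domain description for the coastal SST generator.

    Defaults describe a mid-Atlantic coastal strip: a western coastline
    with a shallow shelf, mean SST falling ~0.74 degC per degree of
    latitude (the observed coastal gradient), a seasonal amplitude
    growing from ~6 degC at the southern edge by 0.5 degC per degree of
    latitude, and mild interannual noise.  Resolutions must nest evenly.
    """

    lat_bounds: tuple[float, float] = (34.0, 36.5)
    lon_bounds: tuple[float, float] = (-77.5, -75.0)
    fine_res_deg: float = 0.05
    coarsen_factor: int = 10
    years: tuple[int, int] = (2001, 2002)
    base_sst_C: float = 22.0  # mean SST at the southern boundary
    lat_gradient_C_per_deg: float = -0.74
    seasonal_amp_C: float = 6.0
    seasonal_amp_slope_C_per_deg: float = 0.5
    peak_doy: int = 228  # seasonal maximum in mid-August
    warming_trend_C_per_year: float = 0.0
    interannual_sd_C: float = 0.3
    shelf_width_deg: float = 3.0
    shelf_max_depth_m: float = 30.0
    habitat_wavelength_deg: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        nlat = (self.lat_bounds[1] - self.lat_bounds[0]) / self.fine_res_deg
        nlon = (self.lon_bounds[1] - self.lon_bounds[0]) / self.fine_res_deg
        for n in (nlat, nlon):
            if abs(n - round(n)) > 1e-9:
                raise GeometryError("domain bounds must be multiples of the fine resolution")
        if round(nlat) % self.coarsen_factor or round(nlon) % self.coarsen_factor:
            raise GeometryError("fine grid dims must be divisible by the coarsen factor")

    @property
    def fine_lat(self) -> np.ndarray:
        lo, hi = self.lat_bounds
        n = round((hi - lo) / self.fine_res_deg)
        return lo + self.fine_res_deg * (np.arange(n) + 0.5)

    @property
    def fine_lon(self) -> np.ndarray:
        lo, hi = self.lon_bounds
        n = round((hi - lo) / self.fine_res_deg)
        return lo + self.fine_res_deg * (np.arange(n) + 0.5)

    def mean_sst(self, lat) -> np.ndarray:
        """Long-term mean SST as a function of latitude."""
        return self.base_sst_C + self.lat_gradient_C_per_deg * (
            np.asarray(lat, dtype=float) - self.lat_bounds[0]
        )

    def seasonal_amplitude(self, lat) -> np.ndarray:
        return self.seasonal_amp_C + self.seasonal_amp_slope_C_per_deg * (
            np.asarray(lat, dtype=float) - self.lat_bounds[0]
        )


@dataclass
class SyntheticScenario:
    """Bundle of generated inputs plus the constructed truth."""

    spec: ScenarioSpec
    daily_sst: xr.DataArray  # (time, lat, lon), fine grid, degC
    bathymetry: xr.DataArray  # (lat, lon), fine grid, m positive-down
    coarse_bathymetry: xr.DataArray  # (lat, lon), half-degree grid
    habitat_map: HabitatMap  # half-degree cells within the depth band

    def habitat_mask(self, d_min: float = 0.0, d_max: float = 10.0) -> np.ndarray:
        return depth_mask(self.coarse_bathymetry, d_min, d_max)


def _shelf_depth(spec: ScenarioSpec, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Positive-down depth: land (negative) west of the coast, then a
    linear shelf dropping to ``shelf_max_depth_m`` over ``shelf_width_deg``."""
    coast_lon = spec.lon_bounds[0] + 0.5  # leave a land strip on the west
    dist = lon[None, :] - coast_lon + 0.0 * lat[:, None]
    depth = spec.shelf_max_depth_m * dist / spec.shelf_width_deg
    depth[dist <= 0] = -10.0  # land
    return depth


def gen_coastal_sst(spec: ScenarioSpec) -> SyntheticScenario:
    """Daily fine-grid SST + bathymetry + half-degree habitat probabilities."""
    rng = np.random.default_rng(spec.seed)
    lat, lon = spec.fine_lat, spec.fine_lon
    times = pd.date_range(
        f"{spec.years[0]}-01-01", f"{spec.years[1]}-12-31", freq="D"
    )
    doy = times.dayofyear.values
    year_idx = times.year.values - spec.years[0]
    n_years = spec.years[1] - spec.years[0] + 1

    base = spec.mean_sst(lat)[:, None] * np.ones((1, lon.size))
    amp = spec.seasonal_amplitude(lat)[:, None] * np.ones((1, lon.size))
    season = np.cos(2 * np.pi * (doy - spec.peak_doy) / 365.0)
    # interannual offsets: one smooth (spatially constant) draw per year
    yearly = rng.normal(0.0, spec.interannual_sd_C, size=n_years)

    sst = (
        base[None, :, :]
        + amp[None, :, :] * season[:, None, None]
        + (spec.warming_trend_C_per_year * year_idx + yearly[year_idx])[:, None, None]
    )
    daily = xr.DataArray(
        sst,
        dims=("time", "lat", "lon"),
        coords={"time": times, "lat": lat, "lon": lon},
        name="sst",
        attrs={"units": "degC"},
    )

    depth = _shelf_depth(spec, lat, lon)
    bathy = xr.DataArray(
        depth, dims=("lat", "lon"), coords={"lat": lat, "lon": lon},
        name="depth", attrs={"units": "m", "positive": "down"},
    )
    # land masking of the SST field
    daily = daily.where(xr.DataArray(depth > 0, dims=("lat", "lon")))

    f = spec.coarsen_factor
    lat_c = lat.reshape(-1, f).mean(axis=1)
    lon_c = lon.reshape(-1, f).mean(axis=1)
    blocks = np.where(depth > 0, depth, np.nan).reshape(lat_c.size, f, lon_c.size, f)
    counts = np.sum(~np.isnan(blocks), axis=(1, 3))
    sums = np.nansum(blocks, axis=(1, 3))
    depth_c = np.where(counts > 0, sums / np.maximum(counts, 1), -10.0)
    cbathy = xr.DataArray(
        depth_c, dims=("lat", "lon"), coords={"lat": lat_c, "lon": lon_c},
        name="depth", attrs={"units": "m", "positive": "down"},
    )

    mask = depth_mask(cbathy)
    ii, jj = np.nonzero(mask)
    p = 0.2 + 0.6 * 0.5 * (
        1.0 + np.sin(2 * np.pi * (lat_c[ii] - spec.lat_bounds[0]) / spec.habitat_wavelength_deg)
    )
    habitat = HabitatMap(lat_c[ii], lon_c[jj], np.clip(p, 0.0, 1.0))

    return SyntheticScenario(
        spec=spec, daily_sst=daily, bathymetry=bathy,
        coarse_bathymetry=cbathy, habitat_map=habitat,
    )


def _analytic_monthly(spec: ScenarioSpec, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Noise-free monthly climatology implied by the seasonal model."""
    mid_doy = np.array([15.5, 45.5, 75.5, 106, 136.5, 167, 197.5, 228.5, 259, 289.5, 320, 350.5])
    base = spec.mean_sst(lat)[:, None] * np.ones((1, lon.size))
    amp = spec.seasonal_amplitude(lat)[:, None] * np.ones((1, lon.size))
    season = np.cos(2 * np.pi * (mid_doy - spec.peak_doy) / 365.0)
    return base[None, :, :] + amp[None, :, :] * season[:, None, None]


def gen_model_pair(
    spec: ScenarioSpec,
    delta_spec: DeltaSpec,
    coarse_res_deg: float = 1.0,
) -> tuple[ClimGrid, ClimGrid, DeltaSpec]:
    """Coarse climate-model historical/future climatologies.

    The historical field follows the scenario's analytic seasonal model on
    a coarse regular grid; the future field adds the known delta.  The
    delta spec is returned so oracle checks can evaluate the truth at any
    location.
    """
    lo_lat, hi_lat = spec.lat_bounds
    lo_lon, hi_lon = spec.lon_bounds
    nlat = max(2, round((hi_lat - lo_lat) / coarse_res_deg))
    nlon = max(2, round((hi_lon - lo_lon) / coarse_res_deg))
    lat = lo_lat + (hi_lat - lo_lat) * (np.arange(nlat) + 0.5) / nlat
    lon = lo_lon + (hi_lon - lo_lon) * (np.arange(nlon) + 0.5) / nlon

    hist = _analytic_monthly(spec, lat, lon)
    lat2d, lon2d = np.meshgrid(lat, lon, indexing="ij")
    delta = delta_spec(lat2d, lon2d)
    fut = hist + delta[None, :, :]
    return ClimGrid(lat, lon, hist), ClimGrid(lat, lon, fut), delta_spec
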