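"""End-to-end pipeline stages gluing the library modules together.

Each stage reads/writes the package's standard on-disk formats (NetCDF
for grids, CSV for tables and maps) and records the seed and config hash
alongside its outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .climate import ClimGrid, coarsen, depth_mask, extremes_and_range, extremes_frame, delta_downscale, monthly_climatology
from .config import RunConfig
from .envelopes import ThermalEnvelope, assign_subpopulation, build_envelope_E_table, snap_to_envelope
from .errors import DomainError, GeometryError
from .habitat import CellState, HabitatMap, PIBCMConfig, probability_delta, project_habitat
from .mte import RateMeasurement, Subpopulation, fit_arrhenius, fit_summary_frame, read_rate_table, write_rate_table
from .res import RESEnvelope, project_res_map
from .synthetic import DeltaSpec, ScenarioSpec, gen_arrhenius_measurements, gen_coastal_sst, gen_model_pair

log = logging.getLogger("pibcm")

COMMANDS = ("fit-e", "climatology", "downscale", "project", "res", "simulate")


def _provenance(config: RunConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.config_hash(),
            "rcp_label": config.rcp_label}


def _write_provenance(out: Path, config: RunConfig, stage: str, extra: dict | None = None) -> None:
    rec = {"stage": stage, **_provenance(config)}
    if extra:
        rec.update(extra)
    (out / f"{stage}_run.json").write_text(json.dumps(rec, indent=2, default=str))


def _pibcm_config(config: RunConfig) -> PIBCMConfig:
    return PIBCMConfig(
        t_break_C=config.t_break_C, cline_lat=config.cline_lat,
        mass_g=config.mass_g, b0=config.b0,
        refuge_reference=config.refuge_reference,  # type: ignore[arg-type]
    )


def _measurements_for(data: Sequence[RateMeasurement], sub: Subpopulation) -> list[RateMeasurement]:
    """Measurements labelled for the subpopulation, falling back to
    unlabelled data when a dataset carries no north/south annotation."""
    labelled = [m for m in data if m.subpopulation == sub]
    if labelled:
        return labelled
    return [m for m in data if m.subpopulation == Subpopulation.UNSPECIFIED]


def build_cell_states(
    contemp: ClimGrid,
    future: ClimGrid,
    habitat: HabitatMap,
    acclimation_data: Sequence[RateMeasurement],
    cfg: PIBCMConfig,
    include_warm_assay: bool = True,
) -> list[CellState]:
    """Physiological state per habitat cell from the two climatologies.

    For each occupied cell: climatological extremes now and future are
    snapped to thermal envelopes, the envelope- and subpopulation-
    specific activation energy is fitted from the acclimation data, and
    the metabolic rate ranges are evaluated at the configured body mass.
    """
    from .mte import MTEParameters, metabolic_rate_range

    if not contemp.same_geometry(future):
        raise GeometryError("contemporary and future climatologies differ in geometry")
    tmin_n, tmax_n, _ = extremes_and_range(contemp)
    tmin_f, tmax_f, _ = extremes_and_range(future)

    lat_idx = {round(v, 6): i for i, v in enumerate(contemp.lat)}
    lon_idx = {round(v, 6): j for j, v in enumerate(contemp.lon)}

    # collect the envelopes each subpopulation needs, then fit each once
    cell_info = []
    needed: dict[Subpopulation, set[ThermalEnvelope]] = {}
    for lat, lon in zip(habitat.lat, habitat.lon):
        i, j = lat_idx.get(round(lat, 6)), lon_idx.get(round(lon, 6))
        if i is None or j is None or np.isnan(tmax_n[i, j]) or np.isnan(tmax_f[i, j]):
            raise GeometryError(f"habitat cell ({lat}, {lon}) is outside the valid climatology")
        sub = assign_subpopulation(lat, cfg.cline_lat)
        env_now = snap_to_envelope(tmin_n[i, j], tmax_n[i, j])
        env_fut = snap_to_envelope(tmin_f[i, j], tmax_f[i, j])
        needed.setdefault(sub, set()).update((env_now, env_fut))
        cell_info.append((lat, lon, i, j, sub, env_now, env_fut))

    tables = {
        sub: build_envelope_E_table(
            _measurements_for(acclimation_data, sub), sorted(envs), include_warm_assay
        )
        for sub, envs in needed.items()
    }
    params = MTEParameters(b0=cfg.b0)

    states = []
    for lat, lon, i, j, sub, env_now, env_fut in cell_info:
        table = tables[sub]
        key_sub = next(s for (e, s) in table.fits if e == env_now)
        E_now = table.get(env_now, key_sub).E_eV
        E_fut = table.get(env_fut, key_sub).E_eV
        states.append(
            CellState(
                lat=lat, lon=lon,
                t_max_now=float(tmax_n[i, j]), t_max_fut=float(tmax_f[i, j]),
                mrr_now=metabolic_rate_range(cfg.mass_g, float(tmin_n[i, j]), float(tmax_n[i, j]), E_now, params),
                mrr_fut=metabolic_rate_range(cfg.mass_g, float(tmin_f[i, j]), float(tmax_f[i, j]), E_fut, params),
            )
        )
    return states


# ---------------------------------------------------------------------------
# pipeline stages

def stage_simulate(config: RunConfig, out: Path) -> dict:
    """Generate a complete synthetic input bundle."""
    spec = ScenarioSpec(seed=config.seed)
    scen = gen_coastal_sst(spec)
    scen.daily_sst.to_netcdf(out / "daily_sst.nc", engine="scipy")
    scen.bathymetry.to_netcdf(out / "bathymetry.nc", engine="scipy")
    scen.coarse_bathymetry.to_netcdf(out / "bathymetry_halfdeg.nc", engine="scipy")
    scen.habitat_map.to_csv(out / "habitat.csv")

    # acclimation experiment: seven assay temperatures, both subpopulations;
    # the southern population runs slightly warmer activation energies
    temps = [5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 33.0]
    rates = gen_arrhenius_measurements(
        0.55, 20.0, temps, 0.05, 4, config.seed + 1,
        species="killifish", subpopulation=Subpopulation.NORTH, mass_g=5.0,
    ) + gen_arrhenius_measurements(
        0.65, 20.0, temps, 0.05, 4, config.seed + 2,
        species="killifish", subpopulation=Subpopulation.SOUTH, mass_g=5.0,
    )
    write_rate_table(rates, out / "rates.csv")

    hist, fut, _ = gen_model_pair(spec, DeltaSpec(kind="constant", a=2.0))
    hist.to_netcdf(out / "model_hist.nc")
    fut.to_netcdf(out / "model_future.nc")
    return {"files": sorted(p.name for p in out.iterdir())}


def stage_fit_e(config: RunConfig, out: Path) -> dict:
    """Arrhenius fits per (species, subpopulation) from a rates CSV."""
    config.require_paths("rates_csv")
    data = read_rate_table(config.rates_csv)
    groups: dict[str, list[RateMeasurement]] = {}
    for m in data:
        groups.setdefault(f"{m.species}/{m.subpopulation.value}", []).append(m)
    fits = {label: fit_arrhenius(ms) for label, ms in sorted(groups.items())}
    frame = fit_summary_frame(fits)
    frame.to_csv(out / "e_fits.csv", index=False)
    return {"n_fits": len(fits), "rows": len(frame)}


def _load_climatology(config: RunConfig) -> ClimGrid:
    """Fine daily SST + bathymetry -> depth-banded half-degree climatology."""
    config.require_paths("daily_sst_nc", "bathymetry_nc")
    with xr.open_dataarray(config.daily_sst_nc, engine="scipy") as da:
        daily = da.load()
    with xr.open_dataarray(config.bathymetry_nc, engine="scipy") as da:
        bathy = da.load()
    mask = depth_mask(bathy, config.depth_min_m, config.depth_max_m)
    daily = daily.where(xr.DataArray(mask, dims=("lat", "lon")))
    clim_fine = monthly_climatology(daily, config.baseline_years)
    return coarsen(clim_fine, config.coarsen_factor)


def stage_climatology(config: RunConfig, out: Path) -> dict:
    clim = _load_climatology(config)
    clim.to_netcdf(out / "climatology.nc")
    frame = extremes_frame(clim)
    frame.to_csv(out / "extremes.csv", index=False)
    return {"n_valid_cells": int(clim.valid_mask.sum())}


def stage_downscale(config: RunConfig, out: Path) -> dict:
    config.require_paths("baseline_clim_nc", "model_hist_nc", "model_future_nc")
    baseline = ClimGrid.from_netcdf(config.baseline_clim_nc)
    hist = ClimGrid.from_netcdf(config.model_hist_nc)
    fut = ClimGrid.from_netcdf(config.model_future_nc)
    down = delta_downscale(hist, fut, baseline)
    down.to_netcdf(out / "downscaled.nc")
    return {"n_valid_cells": int(down.valid_mask.sum())}


def stage_project(config: RunConfig, out: Path) -> dict:
    config.require_paths("baseline_clim_nc", "habitat_csv", "rates_csv")
    baseline = ClimGrid.from_netcdf(config.baseline_clim_nc)
    if config.model_hist_nc and config.model_future_nc:
        config.require_paths("model_hist_nc", "model_future_nc")
        hist = ClimGrid.from_netcdf(config.model_hist_nc)
        fut = ClimGrid.from_netcdf(config.model_future_nc)
        future = delta_downscale(hist, fut, baseline)
    else:  # null scenario: future == contemporary
        future = baseline
    habitat = HabitatMap.from_csv(config.habitat_csv)
    data = read_rate_table(config.rates_csv)
    cfg = _pibcm_config(config)
    states = build_cell_states(baseline, future, habitat, data, cfg)
    future_map, diag = project_habitat(habitat, states, cfg)

    future_map.to_csv(out / "habitat_future.csv")
    delta = probability_delta(future_map, habitat)
    pd.DataFrame(
        {"lat": habitat.lat, "lon": habitat.lon, "delta_probability": delta}
    ).to_csv(out / "habitat_delta.csv", index=False)
    pd.DataFrame(
        {
            "lat": [s.lat for s in states],
            "lon": [s.lon for s in states],
            "t_max_now": [s.t_max_now for s in states],
            "t_max_fut": [s.t_max_fut for s in states],
            "mrr_now": [s.mrr_now for s in states],
            "mrr_fut": [s.mrr_fut for s in states],
            "condition": [s.condition.value if s.condition else "" for s in states],
        }
    ).to_csv(out / "conditions.csv", index=False)
    diag.moves.to_csv(out / "moves.csv", index=False)
    (out / "diagnostics.txt").write_text(diag.summary() + "\n")
    return {
        "condition_counts": diag.condition_counts,
        "n_stranded": diag.n_stranded,
        "total_post_cap": diag.total_post_cap,
    }


def stage_res(config: RunConfig, out: Path) -> dict:
    config.require_paths("baseline_clim_nc")
    clim = ClimGrid.from_netcdf(config.baseline_clim_nc)
    env = RESEnvelope(config.res_t_min, config.res_t_pref_min,
                      config.res_t_pref_max, config.res_t_max)
    res_map = project_res_map(clim, env)
    res_map.to_csv(out / "res_map.csv")
    return {"n_cells": int(res_map.p.size)}


_STAGES = {
    "simulate": stage_simulate,
    "fit-e": stage_fit_e,
    "climatology": stage_climatology,
    "downscale": stage_downscale,
    "project": stage_project,
    "res": stage_res,
}


def run_pipeline(config: RunConfig, command: str) -> dict:
    """Execute one named stage, writing artifacts under config.out_dir."""
    if command not in _STAGES:
        raise DomainError(f"unknown command {command!r}; expected one of {COMMANDS}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    log.info("stage %s starting (seed=%d, config=%s)", command, config.seed, config.config_hash())
    result = _STAGES[command](config, out)
    elapsed = time.perf_counter() - t0
    log.info("stage %s finished in %.2f s: %s", command, elapsed, result)
    _write_provenance(out, config, command.replace("-", "_"), {"elapsed_s": round(elapsed, 3), **result})
    return result
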