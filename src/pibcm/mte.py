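"""Metabolic theory of ecology (MTE) primitives.

The central model is the Arrhenius–Boltzmann form of whole-organism
metabolic rate,

    B = b0 * M^(3/4) * exp(-E / (K * T)),

where ``M`` is body mass (g), ``T`` absolute temperature (K), ``E`` the
averaged enzyme activation energy (eV) and ``K`` Boltzmann's constant in
eV/K.  ``E`` is treated as species-, population- and thermal-history-
specific: it is estimated by ordinary least squares of ln(rate) on 1/T,
whose slope equals -E/K.

The metabolic rate range (MRR) — the difference between routine rates at
a habitat's climatological maximum and minimum temperatures — is the
physiological quantity the habitat projection model is driven by, serving
as a proxy for aerobic scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .errors import DegenerateDesignError, DomainError, InsufficientDataError, OrderingError

#: Boltzmann constant in electron-volts per kelvin.
BOLTZMANN_EV_PER_K: float = 8.617e-5

#: Additive offset between degrees Celsius and kelvin.
CELSIUS_OFFSET: float = 273.15


def celsius_to_kelvin(temp_C: float) -> float:
    """Convert Celsius to kelvin (T_K = T_C + 273.15)."""
    return temp_C + CELSIUS_OFFSET


class Subpopulation(str, Enum):
    """Geographic subpopulation label for a rate measurement."""

    NORTH = "north"
    SOUTH = "south"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class RateMeasurement:
    """One whole-animal metabolic-rate observation.

    Parameters
    ----------
    species : str
        Species name.
    subpopulation : Subpopulation
        Geographic subpopulation, or UNSPECIFIED.
    mass_g : float
        Body mass in grams, > 0.
    temp_C : float
        Assay temperature in degrees Celsius, within [-5, 45].
    rate : float
        Routine/standard metabolic rate, > 0 (units are opaque but must be
        consistent within a dataset; the log-transform must be defined).
    """

    species: str
    subpopulation: Subpopulation
    mass_g: float
    temp_C: float
    rate: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mass_g) and self.mass_g > 0):
            raise DomainError(f"mass_g must be positive and finite, got {self.mass_g}")
        if not np.isfinite(self.temp_C) or not (-5.0 <= self.temp_C <= 45.0):
            raise DomainError(
                f"temp_C must lie in the physically plausible range [-5, 45], got {self.temp_C}"
            )
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise DomainError(f"rate must be positive and finite, got {self.rate}")


@dataclass(frozen=True)
class MTEParameters:
    """Parameters of the MTE rate equation.

    ``b0`` is the multiplicative normalization constant (default 14.47,
    the taxon-level value used throughout the sensitivity analysis);
    ``mass_exponent`` defaults to the canonical 3/4.
    """

    b0: float = 14.47
    mass_exponent: float = 0.75
    boltzmann_eV_per_K: float = field(default=BOLTZMANN_EV_PER_K)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.b0) and self.b0 > 0):
            raise DomainError(f"b0 must be positive, got {self.b0}")


@dataclass(frozen=True)
class ArrheniusFit:
    """Result of the ln(rate) ~ 1/T_K ordinary least-squares regression.

    ``E_eV = -slope * K``; the fit is reported regardless of significance.
    """

    E_eV: float
    ln_A0: float
    r_squared: float
    p_value: float
    n: int
    E_stderr: float


def metabolic_rate(
    mass_g: float,
    temp_C: float,
    E_eV: float,
    params: MTEParameters | None = None,
) -> float:
    """Whole-organism metabolic rate b0 * M^a * exp(-E/(K*T_K)).

    Strictly increasing in temperature for E > 0 and in mass for a > 0.
    Units are whatever b0's units imply ("rate units").
    """
    params = params or MTEParameters()
    if not np.isfinite(mass_g) or mass_g <= 0:
        raise DomainError(f"mass_g must be positive and finite, got {mass_g}")
    if not (np.isfinite(temp_C) and np.isfinite(E_eV)):
        raise DomainError("temp_C and E_eV must be finite")
    t_K = celsius_to_kelvin(temp_C)
    return (
        params.b0
        * mass_g**params.mass_exponent
        * math.exp(-E_eV / (params.boltzmann_eV_per_K * t_K))
    )


def fold_change(delta_E_eV: float, temp_C: float) -> float:
    """Multiplicative change in rate caused by lowering E by ``delta_E_eV``.

    This is the ratio of two MTE rates identical except that their
    activation energies differ by ``delta_E_eV``:
    exp(delta_E / (K * T_K)).  A 0.1 eV shift is a ~70-fold change at
    0 degC, decaying to ~40-fold at 40 degC.
    """
    if not (np.isfinite(delta_E_eV) and np.isfinite(temp_C)):
        raise DomainError("delta_E_eV and temp_C must be finite")
    return math.exp(delta_E_eV / (BOLTZMANN_EV_PER_K * celsius_to_kelvin(temp_C)))


def fit_arrhenius(measurements: Sequence[RateMeasurement]) -> ArrheniusFit:
    """Estimate activation energy by OLS of ln(rate) on inverse temperature.

    Requires at least 3 measurements at >= 2 distinct temperatures.  The
    slope of ln(rate) vs 1/T_K equals -E/K, so E = -slope * K.  R², the
    two-sided p-value for the slope (t distribution, n-2 df), n and the
    standard error of E are reported; fits are never rejected on
    significance.
    """
    ms = list(measurements)
    if len(ms) < 3:
        raise InsufficientDataError(
            f"Arrhenius fit needs at least 3 measurements, got {len(ms)}"
        )
    temps = np.array([m.temp_C for m in ms])
    if np.unique(temps).size < 2:
        raise DegenerateDesignError(
            "Arrhenius fit needs at least 2 distinct assay temperatures"
        )
    x = 1.0 / (temps + CELSIUS_OFFSET)
    y = np.log(np.array([m.rate for m in ms]))
    n = len(ms)

    # Closed-form normal equations for the two-parameter line.
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    r_squared = min(max(r_squared, 0.0), 1.0)

    if n > 2:
        sigma2 = ss_res / (n - 2)
        slope_stderr = math.sqrt(sigma2 / sxx)
    else:  # pragma: no cover - guarded by the n >= 3 precondition
        slope_stderr = float("nan")
    if slope_stderr > 0:
        t_stat = slope / slope_stderr
        p_value = 2.0 * stats.t.sf(abs(t_stat), df=n - 2)
    else:
        p_value = 0.0 if slope != 0 else 1.0

    k = BOLTZMANN_EV_PER_K
    return ArrheniusFit(
        E_eV=-slope * k,
        ln_A0=intercept,
        r_squared=r_squared,
        p_value=float(p_value),
        n=n,
        E_stderr=slope_stderr * k,
    )


def metabolic_rate_range(
    mass_g: float,
    t_min_C: float,
    t_max_C: float,
    E_eV: float,
    params: MTEParameters | None = None,
) -> float:
    """Metabolic rate range: rate at t_max minus rate at t_min.

    Nonnegative for E >= 0; zero iff the endpoints coincide or E = 0.
    """
    if t_min_C > t_max_C:
        raise OrderingError(f"t_min_C ({t_min_C}) exceeds t_max_C ({t_max_C})")
    return metabolic_rate(mass_g, t_max_C, E_eV, params) - metabolic_rate(
        mass_g, t_min_C, E_eV, params
    )


def sensitivity_surface(
    mass_grid: Iterable[float],
    temp_grid: Iterable[float],
    E_grid: Iterable[float],
    params: MTEParameters | None = None,
) -> xr.Dataset:
    """Hypothetical log10 rates over a (mass, temp, E) lattice.

    Returns a Dataset with ``log10_rate`` indexed by (mass_g, temp_C, E_eV)
    and, when the temperature grid is uniformly spaced, ``window_mrr``:
    the rate difference over each consecutive temperature window (e.g.
    0-2, 2-4 degC), indexed by the window's lower edge.
    """
    params = params or MTEParameters()
    mass = np.atleast_1d(np.asarray(list(mass_grid), dtype=float))
    temp = np.atleast_1d(np.asarray(list(temp_grid), dtype=float))
    E = np.atleast_1d(np.asarray(list(E_grid), dtype=float))
    if mass.size == 0 or temp.size == 0 or E.size == 0:
        raise DomainError("sensitivity grids must be non-empty")
    if np.any(mass <= 0):
        raise DomainError("mass grid must be strictly positive")

    t_K = temp + CELSIUS_OFFSET
    # rate[m, t, e] = b0 * M^a * exp(-E/(K*T))
    rate = (
        params.b0
        * (mass**params.mass_exponent)[:, None, None]
        * np.exp(-E[None, None, :] / (params.boltzmann_eV_per_K * t_K[None, :, None]))
    )
    ds = xr.Dataset(
        {"log10_rate": (("mass_g", "temp_C", "E_eV"), np.log10(rate))},
        coords={"mass_g": mass, "temp_C": temp, "E_eV": E},
    )

    if temp.size >= 2:
        steps = np.diff(temp)
        if np.allclose(steps, steps[0]):
            mrr = rate[:, 1:, :] - rate[:, :-1, :]
            ds["window_mrr"] = xr.DataArray(
                mrr,
                dims=("mass_g", "window_start_C", "E_eV"),
                coords={
                    "mass_g": mass,
                    "window_start_C": temp[:-1],
                    "E_eV": E,
                },
            )
    return ds


# ---------------------------------------------------------------------------
# Tabular I/O

RATE_TABLE_COLUMNS = ["species", "subpopulation", "mass_g", "temp_C", "rate"]


def read_rate_table(path) -> list[RateMeasurement]:
    """Read rate measurements from a CSV with columns
    species, subpopulation, mass_g, temp_C, rate."""
    df = pd.read_csv(path)
    missing = set(RATE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"rate table {path} missing columns: {sorted(missing)}")
    return [
        RateMeasurement(
            species=str(row.species),
            subpopulation=Subpopulation(str(row.subpopulation)),
            mass_g=float(row.mass_g),
            temp_C=float(row.temp_C),
            rate=float(row.rate),
        )
        for row in df.itertuples()
    ]


def write_rate_table(measurements: Sequence[RateMeasurement], path) -> None:
    """Write measurements to CSV in the canonical column order."""
    pd.DataFrame(
        [
            {
                "species": m.species,
                "subpopulation": m.subpopulation.value,
                "mass_g": m.mass_g,
                "temp_C": m.temp_C,
                "rate": m.rate,
            }
            for m in measurements
        ],
        columns=RATE_TABLE_COLUMNS,
    ).to_csv(path, index=False)


def fit_summary_frame(fits: dict[str, ArrheniusFit]) -> pd.DataFrame:
    """Arrange fits as a summary table (one row per label) mirroring the
    conventional survey-table columns: E value (eV), R2, P, n."""
    return pd.DataFrame(
        [
            {
                "label": label,
                "E_eV": f.E_eV,
                "r_squared": f.r_squared,
                "p_value": f.p_value,
                "n": f.n,
                "E_stderr": f.E_stderr,
                "ln_A0": f.ln_A0,
            }
            for label, f in fits.items()
        ]
    )
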