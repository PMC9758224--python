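"""Thermal acclimation envelopes and envelope-specific activation energies.

A habitat cell's climatological (min, max) SST pair is snapped to the
5 degC acclimation lattice {5, 10, ..., 30} to select which acclimation
measurements enter the Arrhenius fit for that cell.  Subpopulations are
assigned by a hard latitudinal cline (default 40 N, configurable to probe
the hybrid zone at 39-41 N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, OrderingError
from .mte import ArrheniusFit, RateMeasurement, Subpopulation, fit_arrhenius

#: Acclimation lattice endpoints (degC).
ENVELOPE_MIN_C = 5.0
ENVELOPE_MAX_C = 30.0
ENVELOPE_STEP_C = 5.0

#: Warmest assay temperature in the acclimation experiment; measurements at
#: this temperature may be folded into envelopes capped at 30 degC.
WARM_ASSAY_C = 33.0

#: Default latitudinal cline separating northern and southern subpopulations.
DEFAULT_CLINE_LAT = 40.0


@dataclass(frozen=True, order=True)
class ThermalEnvelope:
    """A (t_min, t_max) acclimation envelope on the 5 degC lattice."""

    t_min_C: float
    t_max_C: float

    def __post_init__(self) -> None:
        for t in (self.t_min_C, self.t_max_C):
            if t % ENVELOPE_STEP_C != 0 or not (ENVELOPE_MIN_C <= t <= ENVELOPE_MAX_C):
                raise OrderingError(
                    f"envelope endpoints must be multiples of 5 in [5, 30], got {t}"
                )
        if self.t_min_C >= self.t_max_C:
            raise OrderingError(
                f"envelope must have t_min < t_max, got ({self.t_min_C}, {self.t_max_C})"
            )

    def __str__(self) -> str:  # e.g. "5-30"
        return f"{self.t_min_C:g}-{self.t_max_C:g}"


def snap_to_envelope(t_min_C: float, t_max_C: float) -> ThermalEnvelope:
    """Snap habitat temperature extremes to the nearest 5 degC lattice.

    Each endpoint is rounded to the nearest multiple of 5 with ties
    upward, then clamped to [5, 30].  If both endpoints land on the same
    value, t_min is lowered one step (floor 5) so the envelope stays
    non-degenerate even for cells with tiny seasonal range.
    """
    if t_min_C > t_max_C:
        raise OrderingError(f"t_min_C ({t_min_C}) exceeds t_max_C ({t_max_C})")

    def snap(t: float) -> float:
        # nearest multiple of 5, ties upward
        snapped = ENVELOPE_STEP_C * np.floor(t / ENVELOPE_STEP_C + 0.5)
        return float(np.clip(snapped, ENVELOPE_MIN_C, ENVELOPE_MAX_C))

    lo, hi = snap(t_min_C), snap(t_max_C)
    if lo == hi:
        if lo > ENVELOPE_MIN_C:
            lo -= ENVELOPE_STEP_C
        else:
            hi += ENVELOPE_STEP_C
    return ThermalEnvelope(lo, hi)


def assign_subpopulation(lat_deg: float, cline_lat: float = DEFAULT_CLINE_LAT) -> Subpopulation:
    """North iff the cell center lies at or above the cline latitude."""
    return Subpopulation.NORTH if lat_deg >= cline_lat else Subpopulation.SOUTH


@dataclass
class EnvelopeETable:
    """Mapping (envelope, subpopulation) -> ArrheniusFit."""

    fits: dict[tuple[ThermalEnvelope, Subpopulation], ArrheniusFit]

    def get(self, envelope: ThermalEnvelope, subpop: Subpopulation) -> ArrheniusFit:
        return self.fits[(envelope, subpop)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "t_min_C": env.t_min_C,
                    "t_max_C": env.t_max_C,
                    "subpopulation": sub.value,
                    "E_eV": f.E_eV,
                    "r_squared": f.r_squared,
                    "p_value": f.p_value,
                    "n": f.n,
                }
                for (env, sub), f in sorted(
                    self.fits.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
                )
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def envelope_measurements(
    data: Iterable[RateMeasurement],
    envelope: ThermalEnvelope,
    include_warm_assay: bool = True,
) -> list[RateMeasurement]:
    """Measurements whose assay temperature falls inside the envelope
    (endpoints inclusive).  When ``include_warm_assay`` is set, 33 degC
    assays are folded into envelopes whose upper bound is 30 degC, so all
    warm-acclimation data is used."""
    upper = envelope.t_max_C
    if include_warm_assay and envelope.t_max_C == ENVELOPE_MAX_C:
        upper = WARM_ASSAY_C
    return [m for m in data if envelope.t_min_C <= m.temp_C <= upper]


def build_envelope_E_table(
    acclimation_data: Sequence[RateMeasurement],
    envelopes: Iterable[ThermalEnvelope],
    include_warm_assay: bool = True,
) -> EnvelopeETable:
    """Fit an activation energy per (envelope, subpopulation).

    For each envelope and each subpopulation present in the data, the
    Arrhenius regression is run on the measurements whose assay
    temperature lies within the (inclusive) envelope bounds.
    """
    subpops = sorted({m.subpopulation for m in acclimation_data}, key=lambda s: s.value)
    fits: dict[tuple[ThermalEnvelope, Subpopulation], ArrheniusFit] = {}
    for env in envelopes:
        for sub in subpops:
            subset = [
                m
                for m in envelope_measurements(acclimation_data, env, include_warm_assay)
                if m.subpopulation == sub
            ]
            n_temps = len({m.temp_C for m in subset})
            if n_temps < 2:
                raise InsufficientDataError(
                    f"envelope {env} ({sub.value}): needs >= 2 assay temperatures "
                    f"inside [{env.t_min_C}, {env.t_max_C}], found {n_temps}"
                )
            fits[(env, sub)] = fit_arrhenius(subset)
    return EnvelopeETable(fits)


def annual_E_variance(
    yearly_extremes: Sequence[tuple[float, float]],
    subpop: Subpopulation,
    acclimation_data: Sequence[RateMeasurement],
    include_warm_assay: bool = True,
    display_scale: float = 1e3,
) -> float:
    """Sample variance of the yearly envelope-specific E series.

    Each year's (t_min, t_max) SST extremes are snapped to an envelope
    and looked up in an E table built from the acclimation data; the
    sample variance (ddof=1) of the resulting E series is returned,
    multiplied by ``display_scale`` (default 10^3, the conventional
    display scaling for these small variances).
    """
    if len(yearly_extremes) < 2:
        raise InsufficientDataError("annual E variance needs >= 2 years")
    envs = [snap_to_envelope(lo, hi) for lo, hi in yearly_extremes]
    table = build_envelope_E_table(
        [m for m in acclimation_data if m.subpopulation == subpop],
        sorted(set(envs)),
        include_warm_assay,
    )
    series = np.array([table.get(env, subpop).E_eV for env in envs])
    if np.all(series == series[0]):  # constant series: exactly zero
        return 0.0
    return float(np.var(series, ddof=1)) * display_scale
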