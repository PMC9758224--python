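"""Trapezoidal Relative Environmental Suitability (RES) envelope model.

The comparison baseline: a single-variable (SST) AquaMaps-style envelope
defined by four temperatures (absolute minimum, preferred minimum,
preferred maximum, absolute maximum).  Suitability is 0 outside the
absolute envelope, 1 inside the preferred envelope, and ramps linearly
in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate import ClimGrid
from .errors import DomainError
from .habitat import HabitatMap


@dataclass(frozen=True)
class RESEnvelope:
    """Four-point trapezoidal SST envelope (degC)."""

    t_min: float
    t_pref_min: float
    t_pref_max: float
    t_max: float

    def __post_init__(self) -> None:
        if not (self.t_min <= self.t_pref_min <= self.t_pref_max <= self.t_max):
            raise DomainError(
                "envelope must satisfy t_min <= t_pref_min <= t_pref_max <= t_max, "
                f"got {self}"
            )


#: Published SST envelope for the Atlantic killifish:
#: minimum, preferred minimum, preferred maximum, maximum.
KILLIFISH_ENVELOPE = RESEnvelope(5.63, 7.74, 21.97, 27.05)


def res_suitability(sst_C, env: RESEnvelope = KILLIFISH_ENVELOPE):
    """Trapezoidal suitability in [0, 1] for scalar or array SST.

    0 at/below t_min and at/above t_max; 1 on [t_pref_min, t_pref_max];
    linear ramps between.  Degenerate (zero-width) ramps take the
    preferred value 1 at the shared point.
    """
    scalar_in = np.ndim(sst_C) == 0
    sst = np.atleast_1d(np.asarray(sst_C, dtype=float))
    out = np.zeros_like(sst)
    lo_ramp = env.t_pref_min - env.t_min
    hi_ramp = env.t_max - env.t_pref_max
    inside_pref = (sst >= env.t_pref_min) & (sst <= env.t_pref_max)
    out[inside_pref] = 1.0
    if lo_ramp > 0:
        on = (sst > env.t_min) & (sst < env.t_pref_min)
        out[on] = (sst[on] - env.t_min) / lo_ramp
    if hi_ramp > 0:
        on = (sst > env.t_pref_max) & (sst < env.t_max)
        out[on] = (env.t_max - sst[on]) / hi_ramp
    out[np.isnan(sst)] = np.nan
    if scalar_in:
        return float(out[0])
    return out


def project_res_map(clim: ClimGrid, env: RESEnvelope = KILLIFISH_ENVELOPE) -> HabitatMap:
    """Suitability map from a climatology's annual-mean SST layer.

    The annual mean is the mean of the 12 monthly layers; masked cells
    are dropped from the output cell list.
    """
    mean_sst = clim.annual_mean()
    ii, jj = np.nonzero(clim.valid_mask)
    suit = res_suitability(mean_sst[ii, jj], env)
    return HabitatMap(clim.lat[ii], clim.lon[jj], suit)
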