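"""Habitat projection under the three-condition stay/relocate algorithm.

Every occupied half-degree cell carries a contemporary and a future
maximum SST (T_max) and metabolic rate range (MRR).  A population

* stays (condition 1) when the future T_max is at or below the 32 degC
  physiological break, the habitat is warming, but the future MRR does
  not exceed the contemporary MRR (the population can compensate by
  adjusting its activation energy);
* stays (condition 2) when T_max stays below the break and either the
  habitat is not warming or the MRR is not growing;
* relocates (condition 3) when the future T_max exceeds the break, or
  the habitat both warms and its MRR grows — the population moves to the
  nearest cell (great-circle distance) whose future MRR is no larger
  than the MRR it is adapted to, and whose future T_max is below the
  break.

Probability mass moves with the population; receiving cells are capped
at probability 1 and the excess recorded as overflow.  Populations with
no qualifying refuge are stranded (zeroed and reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .climate import haversine_km
from .errors import DomainError, GeometryError, PibcmError


class Condition(str, Enum):
    STAY_C1 = "stay_c1"
    STAY_C2 = "stay_c2"
    MOVE_C3 = "move_c3"
    OUTSIDE = "outside"


@dataclass(frozen=True)
class PIBCMConfig:
    """Tunable parameters of the projection algorithm.

    ``t_break_C``: physiological break temperature (32 degC for the
    killifish parameterization).  ``refuge_reference`` selects whether a
    refuge's future MRR is compared against the mover's contemporary or
    future MRR; the default (contemporary) reads relocation as seeking a
    habitat no more metabolically demanding than the one the population
    is currently adapted to.
    """

    t_break_C: float = 32.0
    cline_lat: float = 40.0
    mass_g: float = 10.0
    b0: float = 14.47
    refuge_reference: Literal["contemporary", "future"] = "contemporary"

    def __post_init__(self) -> None:
        if not np.isfinite(self.t_break_C):
            raise DomainError("t_break_C must be finite")
        if self.mass_g <= 0:
            raise DomainError("mass_g must be positive")


@dataclass
class CellState:
    """Physiological state of one habitat cell under both climates."""

    lat: float
    lon: float
    t_max_now: float
    t_max_fut: float
    mrr_now: float
    mrr_fut: float
    condition: Condition | None = None


@dataclass
class HabitatMap:
    """Per-cell occupancy probability on the half-degree grid.

    Cells are a flat list of centers with probabilities in [0, 1];
    ``overflow`` records mass discarded by the cap at 1 (zero before any
    projection).
    """

    lat: np.ndarray
    lon: np.ndarray
    p: np.ndarray
    overflow: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if not (self.lat.shape == self.lon.shape == self.p.shape):
            raise GeometryError("lat, lon and p must have identical shapes")
        if np.any((self.p < 0) | (self.p > 1) | ~np.isfinite(self.p)):
            raise DomainError("probabilities must lie in [0, 1]")
        if self.overflow is None:
            self.overflow = np.zeros_like(self.p)
        else:
            self.overflow = np.asarray(self.overflow, dtype=float)

    def same_geometry(self, other: "HabitatMap") -> bool:
        return (
            self.lat.shape == other.lat.shape
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
        )

    def total(self) -> float:
        return float(self.p.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lat": self.lat, "lon": self.lon, "probability": self.p})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HabitatMap":
        df = pd.read_csv(path)
        missing = {"lat", "lon", "probability"} - set(df.columns)
        if missing:
            raise DomainError(f"habitat map {path} missing columns: {sorted(missing)}")
        return cls(df["lat"].values, df["lon"].values, df["probability"].values)


def classify_cell(state: CellState, cfg: PIBCMConfig) -> Condition:
    """Assign one of the three model conditions to a cell.

    Evaluated in order; boundary equalities resolve in favor of staying.
    The three conditions are jointly exhaustive.
    """
    for v in (state.t_max_now, state.t_max_fut, state.mrr_now, state.mrr_fut):
        if not np.isfinite(v):
            raise DomainError(f"non-finite cell state at ({state.lat}, {state.lon})")
    tb = cfg.t_break_C
    tn, tf = state.t_max_now, state.t_max_fut
    mn, mf = state.mrr_now, state.mrr_fut
    if tf <= tb and tf >= tn and mf <= mn:
        return Condition.STAY_C1
    if tf <= tb and (tf <= tn or mf <= mn):
        return Condition.STAY_C2
    if tf > tb or (tf >= tn and mf >= mn):
        return Condition.MOVE_C3
    raise PibcmError(  # pragma: no cover - conditions are exhaustive
        f"cell ({state.lat}, {state.lon}) matched no model condition"
    )


def nearest_refuge(
    source: CellState, candidates: Sequence[CellState], cfg: PIBCMConfig
) -> CellState | None:
    """Nearest qualifying relocation target for a moving population.

    A candidate qualifies when its future MRR does not exceed the
    source's reference MRR (contemporary by default) and its future
    T_max is at or below the break temperature.  Distance is haversine
    between cell centers; ties break toward lower latitude, then lower
    longitude.  Returns None when no candidate qualifies.
    """
    ref_mrr = source.mrr_now if cfg.refuge_reference == "contemporary" else source.mrr_fut
    best: tuple[float, float, float] | None = None
    best_cand: CellState | None = None
    for cand in candidates:
        if cand is source or (cand.lat == source.lat and cand.lon == source.lon):
            continue
        if cand.mrr_fut > ref_mrr or cand.t_max_fut > cfg.t_break_C:
            continue
        d = float(haversine_km(source.lat, source.lon, cand.lat, cand.lon))
        key = (d, cand.lat, cand.lon)
        if best is None or key < best:
            best, best_cand = key, cand
    return best_cand


@dataclass
class ProjectionDiagnostics:
    """Bookkeeping from one habitat projection run."""

    n_cells: int
    condition_counts: dict[str, int]
    condition_fractions: dict[str, float]
    n_stranded: int
    stranded_mass: float
    total_input: float
    total_pre_cap: float
    total_post_cap: float
    total_overflow: float
    moves: pd.DataFrame  # source lat/lon, dest lat/lon (NaN if stranded), mass

    def summary(self) -> str:
        lines = [
            f"cells: {self.n_cells}",
            "condition counts: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.condition_counts.items())),
            "condition fractions: "
            + ", ".join(
                f"{k}={v:.3f}" for k, v in sorted(self.condition_fractions.items())
            ),
            f"stranded cells: {self.n_stranded} (mass {self.stranded_mass:.6f})",
            f"probability total: input={self.total_input:.6f} "
            f"pre-cap={self.total_pre_cap:.6f} post-cap={self.total_post_cap:.6f} "
            f"overflow={self.total_overflow:.6f}",
        ]
        return "\n".join(lines)


def project_habitat(
    contemp_map: HabitatMap,
    states: Sequence[CellState],
    cfg: PIBCMConfig | None = None,
) -> tuple[HabitatMap, ProjectionDiagnostics]:
    """Project a contemporary habitat map into the future climate.

    Staying cells keep their probability in place; each moving cell's
    probability is transferred to its nearest refuge (or dropped, and the
    cell reported stranded, when none qualifies).  Moving cells are
    processed in (lat, lon) ascending order; the cap at 1 is applied once
    after all transfers and overflow recorded, never cascaded.
    """
    cfg = cfg or PIBCMConfig()
    state_index: dict[tuple[float, float], CellState] = {
        (s.lat, s.lon): s for s in states
    }
    cell_keys = list(zip(contemp_map.lat, contemp_map.lon))
    for key, p in zip(cell_keys, contemp_map.p):
        if p > 0 and key not in state_index:
            raise GeometryError(f"occupied cell {key} has no physiological state")

    out_p = np.zeros_like(contemp_map.p)
    pos = {key: i for i, key in enumerate(cell_keys)}
    conditions: dict[tuple[float, float], Condition] = {}

    movers: list[tuple[tuple[float, float], CellState, float]] = []
    for key, p in zip(cell_keys, contemp_map.p):
        st = state_index.get(key)
        if st is None or p == 0:
            if st is not None:
                st.condition = classify_cell(st, cfg)
                conditions[key] = st.condition
            continue
        st.condition = classify_cell(st, cfg)
        conditions[key] = st.condition
        if st.condition is Condition.MOVE_C3:
            movers.append((key, st, p))
        else:
            out_p[pos[key]] += p

    movers.sort(key=lambda item: (item[0][0], item[0][1]))
    occupied_states = [
        state_index[key] for key, p in zip(cell_keys, contemp_map.p) if key in state_index
    ]
    move_rows = []
    stranded_mass = 0.0
    n_stranded = 0
    for key, st, p in movers:
        refuge = nearest_refuge(st, occupied_states, cfg)
        if refuge is None:
            n_stranded += 1
            stranded_mass += p
            move_rows.append(
                {"src_lat": key[0], "src_lon": key[1], "dst_lat": np.nan,
                 "dst_lon": np.nan, "mass": p, "stranded": True}
            )
            continue
        out_p[pos[(refuge.lat, refuge.lon)]] += p
        move_rows.append(
            {"src_lat": key[0], "src_lon": key[1], "dst_lat": refuge.lat,
             "dst_lon": refuge.lon, "mass": p, "stranded": False}
        )

    total_pre_cap = float(out_p.sum())
    overflow = np.maximum(out_p - 1.0, 0.0)
    capped = np.minimum(out_p, 1.0)
    future_map = HabitatMap(contemp_map.lat, contemp_map.lon, capped, overflow)

    occupied = contemp_map.p > 0
    occ_conditions = [conditions[k] for k, o in zip(cell_keys, occupied) if o]
    counts = {c.value: 0 for c in (Condition.STAY_C1, Condition.STAY_C2, Condition.MOVE_C3)}
    for c in occ_conditions:
        counts[c.value] += 1
    n_occ = len(occ_conditions)
    diagnostics = ProjectionDiagnostics(
        n_cells=n_occ,
        condition_counts=counts,
        condition_fractions={
            k: (v / n_occ if n_occ else 0.0) for k, v in counts.items()
        },
        n_stranded=n_stranded,
        stranded_mass=stranded_mass,
        total_input=contemp_map.total(),
        total_pre_cap=total_pre_cap,
        total_post_cap=future_map.total(),
        total_overflow=float(overflow.sum()),
        moves=pd.DataFrame(
            move_rows,
            columns=["src_lat", "src_lon", "dst_lat", "dst_lon", "mass", "stranded"],
        ),
    )
    return future_map, diagnostics


def probability_delta(future_map: HabitatMap, contemp_map: HabitatMap) -> np.ndarray:
    """Per-cell future minus contemporary probability, in [-1, 1]."""
    if not future_map.same_geometry(contemp_map):
        raise GeometryError("habitat maps differ in geometry")
    return future_map.p - contemp_map.p
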