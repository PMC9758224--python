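"""Run configuration: strict YAML schema, validation and hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import DomainError


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Unknown keys in the YAML file are rejected outright; paths are only
    required (and checked for existence) by the stages that read them.
    """

    # input paths
    rates_csv: str | None = None
    daily_sst_nc: str | None = None
    bathymetry_nc: str | None = None
    habitat_csv: str | None = None
    baseline_clim_nc: str | None = None
    model_hist_nc: str | None = None
    model_future_nc: str | None = None
    # output
    out_dir: str = "pibcm_out"
    # physiology / projection parameters
    t_break_C: float = 32.0
    cline_lat: float = 40.0
    mass_g: float = 10.0
    b0: float = 14.47
    refuge_reference: str = "contemporary"
    # RES envelope (degC)
    res_t_min: float = 5.63
    res_t_pref_min: float = 7.74
    res_t_pref_max: float = 21.97
    res_t_max: float = 27.05
    # grid / period settings
    coarsen_factor: int = 10
    depth_min_m: float = 0.0
    depth_max_m: float = 10.0
    baseline_years: tuple[int, int] | None = None
    # randomness
    seed: int = 0
    # free-text scenario label carried into outputs (metadata only)
    rcp_label: str = ""

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise DomainError(f"config {path} must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DomainError(f"config {path} has unknown keys: {sorted(unknown)}")
        if "baseline_years" in raw and raw["baseline_years"] is not None:
            raw["baseline_years"] = tuple(raw["baseline_years"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the full configuration for provenance records."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def require_paths(self, *names: str) -> None:
        """Ensure the named path fields are set and exist on disk."""
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise DomainError(f"config field {name!r} is required for this stage")
            if not Path(value).exists():
                raise DomainError(f"config field {name!r}: path does not exist: {value}")
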