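"""Run configuration: one YAML file mirrored by CLI flags (flags win).

A seed is mandatory for any stochastic command; a config without one is
refused rather than silently defaulted, so every run is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int | None = None
    # paths
    clusters_path: str | None = None
    raster_dir: str | None = None
    regions_path: str | None = None
    out_dir: str = "."
    # model
    covariates: list[str] = field(default_factory=list)
    engine: str = "laplace"
    nu: float = 1.0
    n_draws: int = 5000
    include_spatial_field: bool = True
    # prediction
    cell_km: float = 10.0
    n_pred_draws: int = 1000
    # simulation (optional block passed to synthetic.SimulationConfig)
    simulation: dict[str, Any] = field(default_factory=dict)

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigError("a seed is required for stochastic commands; none was given")
        return int(self.seed)


def load_config(path, **overrides) -> RunConfig:
    """Load YAML config; keyword overrides (CLI flags) win over file values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)
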