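"""Config handling, tabular readers/writers and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .parameters import ParameterSet, default_parameters


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


class FormatError(ValueError):
    """Malformed tabular input."""


_RUNCONFIG_KEYS = {
    "variant", "parameter_file", "overrides", "rtol", "atol",
    "t_end", "grid_step", "seed", "log_level", "output",
}


@dataclass
class RunConfig:
    """Validated run configuration shared by all CLI stages."""

    variant: str = "NH3"
    parameter_file: str | None = None
    overrides: dict = field(default_factory=dict)
    rtol: float = 1e-6
    atol: float = 1e-12
    t_end: float = 79.0
    grid_step: float = 0.1
    seed: int = 0
    log_level: str = "INFO"
    output: str | None = None

    def __post_init__(self):
        if self.variant not in ("ctrl", "NH3", "NH3_HCl"):
            raise ConfigError(f"variant: unknown value {self.variant!r}")
        for key in ("rtol", "atol", "t_end", "grid_step"):
            if not getattr(self, key) > 0:
                raise ConfigError(f"{key}: must be positive")
        if self.parameter_file is not None and not Path(self.parameter_file).exists():
            raise ConfigError(f"parameter_file: {self.parameter_file!r} does not exist")
        # overrides are parameter-name keyed; validate against ParameterSet
        self.parameters()

    def parameters(self) -> ParameterSet:
        params = (ParameterSet.from_yaml(self.parameter_file)
                  if self.parameter_file else default_parameters())
        if self.overrides:
            try:
                params = params.replace(**self.overrides)
            except TypeError as e:
                raise ConfigError(f"overrides: {e}") from None
            except ValueError as e:
                raise ConfigError(f"overrides: {e}") from None
        return params

    def to_dict(self) -> dict:
        return {
            "variant": self.variant, "parameter_file": self.parameter_file,
            "overrides": dict(self.overrides), "rtol": self.rtol, "atol": self.atol,
            "t_end": self.t_end, "grid_step": self.grid_step, "seed": self.seed,
            "log_level": self.log_level, "output": self.output,
        }


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected by name; missing keys take defaults.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    unknown = set(data) - _RUNCONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except TypeError as e:
        raise ConfigError(str(e)) from None


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(config: RunConfig, path: str | Path, extra: dict | None = None) -> dict:
    """Machine-readable record sufficient to reproduce a run."""
    from . import __version__

    manifest = {
        "package": "admtaxa",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# --- tidy time-series CSV ------------------------------------------------

_SERIES_COLUMNS = ("time", "variable", "value")


def write_timeseries(df: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format (time, variable, value[, basis]) series."""
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    df.to_csv(path, index=False, float_format="%.17g")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a long-format series; rows are sorted by time per variable.

    Duplicate (time, variable) pairs are a format error (reported with
    row numbers); the time axis must be numeric.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if not np.issubdtype(df["time"].dtype, np.number):
        raise FormatError(f"{path}: non-numeric time column")
    dup = df.duplicated(subset=["time", "variable"], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup]]  # 1-based incl. header
        raise FormatError(f"{path}: duplicate (time, variable) pairs at rows {rows}")
    return df.sort_values(["variable", "time"], kind="mergesort").reset_index(drop=True)
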