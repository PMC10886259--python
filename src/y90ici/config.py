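"""Run configuration, validation and result writing.

A run configuration is a nested YAML/JSON document whose blocks mirror
the library's building blocks (model parameters, cohort spec, treatment
settings, trial settings).  Every key has a default equal to the
published value where one exists; unknown keys are rejected by name, and
out-of-range values raise errors naming the offending key and bound.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .cohort import CohortSpec
from .parameters import ModelParameters


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Y90Config:
    total_dose_gy: float = 400.0
    n_fractions: int = 26
    kappa_blood: float = 0.05

    def __post_init__(self):
        if self.total_dose_gy < 0:
            raise ConfigError("y90.total_dose_gy must be >= 0")
        if self.n_fractions < 1:
            raise ConfigError("y90.n_fractions must be >= 1")
        if not 0.0 <= self.kappa_blood <= 1.0:
            raise ConfigError("y90.kappa_blood must lie in [0, 1]")


@dataclass(frozen=True)
class ICIConfig:
    delta_durva: float = 0.12
    interval_days: float = 14.0
    duration_days: float = 730.0

    def __post_init__(self):
        if not 0.0 <= self.delta_durva <= 1.0:
            raise ConfigError("ici.delta_durva must lie in [0, 1]")
        if self.interval_days <= 0:
            raise ConfigError("ici.interval_days must be > 0")
        if self.duration_days < 0:
            raise ConfigError("ici.duration_days must be >= 0")


@dataclass(frozen=True)
class TrialConfig:
    horizon_months: float = 120.0
    arm: str = "A"
    interval_days: float = 60.0
    doses: tuple[float, ...] = (300.0, 400.0, 500.0)
    deltas: tuple[float, ...] = (0.08, 0.12, 0.16)
    intervals: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0, 270.0, 300.0)
    dm_threshold_cc: float = 0.1
    cr_threshold_cells: float = 1.0e8

    def __post_init__(self):
        if self.horizon_months < 60.0:
            raise ConfigError("trial.horizon_months must be >= 60")
        if not 0.0 <= self.interval_days <= 300.0:
            raise ConfigError("trial.interval_days must lie in [0, 300]")


@dataclass(frozen=True)
class CalibrationConfig:
    target_cr: float = 0.79
    target_pr: float = 0.20
    target_sd: float = 0.0
    target_pd: float = 0.0
    dose_gy: float = 400.0
    n: int = 10_000
    assess_month: float = 6.0

    def __post_init__(self):
        # 0.02 slack: published profiles are rounded to whole percents
        total = self.target_cr + self.target_pr + self.target_sd + self.target_pd
        if abs(total - 1.0) > 0.02:
            raise ConfigError("calibration targets must sum to 1")
        if self.n < 1:
            raise ConfigError("calibration.n must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    model: ModelParameters = field(default_factory=ModelParameters)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    y90: Y90Config = field(default_factory=Y90Config)
    ici: ICIConfig = field(default_factory=ICIConfig)
    trial: TrialConfig = field(default_factory=TrialConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    dt: float = 0.25
    seed: int = 0
    outdir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_BLOCKS = {
    "model": ModelParameters,
    "cohort": CohortSpec,
    "y90": Y90Config,
    "ici": ICIConfig,
    "trial": TrialConfig,
    "calibration": CalibrationConfig,
}


def _build(cls, block: dict, prefix: str):
    known = {f.name for f in fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {prefix or 'top level'}: {sorted(unknown)}"
        )
    coerced = {}
    for f in fields(cls):
        if f.name not in block:
            continue
        value = block[f.name]
        if isinstance(value, list):
            value = tuple(value)
        coerced[f.name] = value
    try:
        return cls(**coerced)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid {prefix} block: {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML configuration; missing keys default to
    the published model values.  An empty (or absent) file yields the
    full default configuration."""
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("configuration root must be a mapping")
        raw = loaded

    top_known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    kwargs: dict[str, Any] = {}
    for name, cls in _BLOCKS.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ConfigError(f"block {name!r} must be a mapping")
            kwargs[name] = _build(cls, raw[name], name)
    for name in ("dt", "seed", "outdir", "log_level"):
        if name in raw:
            kwargs[name] = raw[name]
    try:
        return RunConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def write_results(artifacts: dict[str, Any], outdir: str | Path, config: RunConfig | None = None) -> dict:
    """Write result artifacts plus a manifest.

    ``artifacts`` maps file names to objects: DataFrames go to CSV,
    dicts/lists to JSON, strings verbatim.  Returns the manifest.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in artifacts.items():
        path = outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False)
        elif isinstance(obj, (dict, list)):
            path.write_text(json.dumps(obj, indent=2, default=float))
        else:
            path.write_text(str(obj))
        written.append(name)
    manifest = {
        "files": sorted(written),
        "package_version": __version__,
        "seed": config.seed if config is not None else None,
        "config_hash": config.config_hash() if config is not None else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
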