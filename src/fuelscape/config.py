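"""Run configuration: flat key-value documents, presets, validation.

A RunConfig houses every constant an experiment needs (grid size, area
distribution, implementation uncertainty, simulation horizon/burn-in,
optimizer settings, master seed).  Configs round-trip losslessly through
YAML; unknown keys are rejected by name.

Presets:
  * ``full`` — full scale: 180x180 grid, pool 2000, population 800,
    400 generations, 24 replicate evaluations.
  * ``desk``  — small scale for tests and demos: 30x30 grid, pool 50,
    population 40, 30 generations, 4 replicates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "PRESETS", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    preset: str = "desk"
    # landscape
    grid_rows: int = 30
    grid_cols: int = 30
    area_mean: float = 20.0
    area_variance: float = 100.0
    initial_age_max: int = 70
    pool_size: int = 50
    # dynamics
    uncertainty_shape: float = 100.0
    horizon: int = 100
    burn_in: int = 20
    biomass_max: float = 20_000.0
    biomass_rate: float = 0.06
    interval_min: float = 3.0
    interval_max: float = 100.0
    # optimizer
    n_groups: int = 3
    population: int = 40
    generations: int = 30
    replicates: int = 4
    crossover_prob: float = 0.7
    mutation_prob: float = 0.2
    crossover_eta: float = 5.0
    mutation_eta: float = 10.0
    hv_samples: int = 20_000
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigError("grid_rows and grid_cols must be >= 1")
        if self.area_mean <= 0 or self.area_variance <= 0:
            raise ConfigError("area_mean and area_variance must be positive")
        if self.interval_min < 3.0:
            raise ConfigError(f"interval_min below 3 is not allowed (got {self.interval_min})")
        if self.interval_max > 100.0 or self.interval_max <= self.interval_min:
            raise ConfigError("interval_max must lie in (interval_min, 100]")
        if not 0 <= self.burn_in < self.horizon:
            raise ConfigError("burn_in must satisfy 0 <= burn_in < horizon")
        if not 1 <= self.n_groups <= 5:
            raise ConfigError("n_groups must be in 1..5")
        if self.population % 2 or self.population < 2:
            raise ConfigError("population must be even and >= 2")
        if self.replicates < 1 or self.replicates > self.pool_size:
            raise ConfigError("replicates must be in 1..pool_size")
        for name in ("crossover_prob", "mutation_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.uncertainty_shape <= 0:
            raise ConfigError("uncertainty_shape must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


PRESETS: dict[str, dict] = {
    "desk": {},  # the dataclass defaults
    "full": dict(
        grid_rows=180,
        grid_cols=180,
        pool_size=2000,
        population=800,
        generations=400,
        replicates=24,
        hv_samples=100_000,
    ),
}


def make_config(preset: str = "desk", **overrides) -> RunConfig:
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    values = {"preset": preset, **PRESETS[preset], **overrides}
    return RunConfig(**values)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a flat YAML key-value config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    preset = raw.pop("preset", "desk")
    return make_config(preset, **raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
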