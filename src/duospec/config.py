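"""Run configuration for the command-line front end.

One YAML file drives every subcommand so that the method's magic numbers
(differencing window, scaling factor, divisor concentration, working
wavelengths, noise level, seeds, replication design) live in a single
auditable place.  CLI flags override individual keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import (
    DEFAULT_GRID_START,
    DEFAULT_GRID_STOP,
    DEFAULT_GRID_STEP,
    DEFAULT_NOISE_SD,
)
from .transforms import DEFAULT_MIN_DIVISOR_ABS
from .workflows import (
    DEFAULT_CALIBRATION_CONCENTRATIONS,
    DEFAULT_STUDY_LEVELS,
    DEFAULT_STUDY_SEEDS,
)


@dataclass
class RunConfig:
    grid_start: float = DEFAULT_GRID_START
    grid_stop: float = DEFAULT_GRID_STOP
    grid_step: float = DEFAULT_GRID_STEP
    delta_lambda: float = 4.0
    scaling_factor: float = 10.0
    divisor_concentration: float = 5.0
    min_divisor_abs: float = DEFAULT_MIN_DIVISOR_ABS
    smooth_window: float = 4.0
    noise_sd: float = DEFAULT_NOISE_SD
    seeds: dict = field(default_factory=lambda: dict(DEFAULT_STUDY_SEEDS))
    calibration_concentrations: dict = field(
        default_factory=lambda: {
            k: list(v) for k, v in DEFAULT_CALIBRATION_CONCENTRATIONS.items()
        }
    )
    study_levels: dict = field(
        default_factory=lambda: {
            k: list(v) for k, v in DEFAULT_STUDY_LEVELS.items()
        }
    )
    n_replicates: int = 3
    n_days: int = 3

    def __post_init__(self) -> None:
        if self.grid_start >= self.grid_stop:
            raise ValueError("grid start must be below grid stop")
        if self.grid_step <= 0:
            raise ValueError("grid step must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            f: getattr(self, f) for f in self.__dataclass_fields__
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
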