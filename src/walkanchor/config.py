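"""Pipeline configuration.

All analysis thresholds live here so a deployment can reproduce a study's
exact processing decisions from one human-readable YAML file.  Defaults
follow the free-living dual-device protocol this package implements:
1-s activity epochs reaveraged to 15 s, walking bouts with at most 5 s of
internal rest, LONG walks of at least 60 s with median cadence above
80 steps/min, ALL walks of at least 5 steps, valid days with at least 10 h
of waking wear, and a 20-minute clinically important sedentary
misclassification threshold.

Intensity cut points are AVM (average vector magnitude, milli-g) thresholds.
The shipped defaults (45 / 100 mg) are generic ENMO-style wrist thresholds;
deployments applying published population-specific cut points (e.g. the
older-adult wrist values this protocol was designed around) should
transcribe them into the config — the pipeline never silently supplies
study-specific numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class IntensityCutPoints:
    """AVM thresholds separating sedentary/light and light/MVPA.

    An epoch is at least light when its AVM is at or above
    ``light_threshold_mg`` and MVPA when at or above
    ``moderate_threshold_mg`` (lower-inclusive upper class).
    """

    light_threshold_mg: float = 45.0
    moderate_threshold_mg: float = 100.0
    provenance: str = (
        "generic ENMO-style wrist defaults; transcribe published "
        "population-specific cut points here for deployment"
    )

    def __post_init__(self) -> None:
        if not (0 < self.light_threshold_mg < self.moderate_threshold_mg):
            raise ConfigError(
                "cut points require 0 < light_threshold_mg < moderate_threshold_mg, "
                f"got {self.light_threshold_mg} / {self.moderate_threshold_mg}"
            )


@dataclass(frozen=True)
class PipelineConfig:
    epoch_short_s: int = 1
    epoch_long_s: int = 15
    bout_max_rest_s: float = 5.0
    long_walk_min_s: float = 60.0
    long_walk_min_cadence_spm: float = 80.0
    all_walk_min_steps: int = 5
    valid_day_min_wear_h: float = 10.0
    clinical_threshold_min: float = 20.0
    cut_points: IntensityCutPoints = field(default_factory=IntensityCutPoints)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "epoch_short_s",
            "epoch_long_s",
            "bout_max_rest_s",
            "long_walk_min_s",
            "long_walk_min_cadence_spm",
            "all_walk_min_steps",
            "valid_day_min_wear_h",
            "clinical_threshold_min",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.epoch_long_s % self.epoch_short_s != 0:
            raise ConfigError(
                "epoch_long_s must be an integer multiple of epoch_short_s, "
                f"got {self.epoch_long_s} / {self.epoch_short_s}"
            )

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cut_points"] = asdict(self.cut_points)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cuts = d.pop("cut_points", None)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if cuts is not None:
            d["cut_points"] = IntensityCutPoints(**cuts)
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config file; absent keys take package defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return PipelineConfig.from_dict(raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
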