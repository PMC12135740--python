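"""Strict pipeline configuration: every analysis constant lives here.

Loaded from YAML with unknown keys rejected, so a typo in a config file is
an error rather than a silently ignored setting.  Defaults encode the
study constants: 5% deviation corridor, 11-interval reference window, 5%
pause tolerance, 5-beat peak heart rate, 95% readability inclusion cutoff.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .simulate import SimulationConfig

__all__ = [
    "DetectionConfig",
    "PauseConfig",
    "PafConfig",
    "DecelerationConfig",
    "ReadabilityConfig",
    "HrConfig",
    "ModelsConfig",
    "PipelineConfig",
    "load_config",
    "dump_config",
    "ConfigError",
]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DetectionConfig(_Strict):
    threshold: float = Field(0.05, gt=0.0, lt=1.0)
    window: int = Field(11, ge=3)
    threshold_mode: Literal["relative", "absolute_at_peak"] = "relative"
    reference_statistic: Literal["median", "mean"] = "median"


class PauseConfig(_Strict):
    tolerance: float = Field(0.05, ge=0.0, lt=1.0)


class PafConfig(_Strict):
    min_beats: int = Field(12, ge=4)
    cv_threshold: float = Field(0.10, gt=0.0, lt=1.0)


class DecelerationConfig(_Strict):
    drop_bpm: float = Field(30.0, gt=0.0)
    window_s: float = Field(60.0, gt=0.0)
    smooth_s: float = Field(10.0, gt=0.0)
    min_peak_bpm: float = Field(120.0, gt=0.0)


class ReadabilityConfig(_Strict):
    weighting: Literal["duration", "beats"] = "duration"
    inclusion_cutoff: float = Field(0.95, ge=0.0, le=1.0)


class HrConfig(_Strict):
    peak_beats: int = Field(5, ge=1)
    mean_exclude_artifact: bool = True


class ModelsConfig(_Strict):
    logistic_outcomes: list[str] = Field(
        default_factory=lambda: ["arrhythmia", "arrhythmia_deceleration"]
    )
    poisson_outcome: str = "n_pc"
    fixed_terms: list[str] = Field(
        default_factory=lambda: [
            "cardiac", "type", "age", "level", "season", "duration_min", "hr_peak",
        ]
    )
    association_pairs: list[tuple[str, str]] = Field(
        default_factory=lambda: [
            ("n_pc", "age"), ("n_pc", "level"), ("n_pc", "cardiac"),
            ("n_pc", "hr_peak"), ("n_pc", "duration_min"),
            ("arrhythmia", "age"), ("arrhythmia", "hr_peak"),
            ("arrhythmia", "duration_min"),
        ]
    )


class PipelineConfig(_Strict):
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    pause: PauseConfig = Field(default_factory=PauseConfig)
    paf: PafConfig = Field(default_factory=PafConfig)
    deceleration: DecelerationConfig = Field(default_factory=DecelerationConfig)
    readability: ReadabilityConfig = Field(default_factory=ReadabilityConfig)
    hr: HrConfig = Field(default_factory=HrConfig)
    models: ModelsConfig = Field(default_factory=ModelsConfig)
    simulation: SimulationConfig | None = None
    output_dir: str = "out"
    seed: int = 0


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        locations = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration ({locations})") from exc


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    )
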