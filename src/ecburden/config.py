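"""Schema-validated run configuration.

The YAML run config is validated strictly (unknown keys rejected,
field-path error messages) and every default is echoed back so the run
manifest records the effective parameters of each stage.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .burden import FIXED, GLOBAL_MIN, PER_CELL_MIN, PER_CELL_POPULATION, REGION_MEAN_EXPOSURE


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthSection(_Section):
    grid_nx: int = Field(20, ge=4)
    grid_ny: int = Field(20, ge=4)
    cell_size_km: float = Field(10.0, gt=0)
    n_regions: int = Field(5, ge=2)
    years: list[int] = [2012, 2013]
    n_sites: int = Field(30, ge=3)
    obs_missing_rate: float = Field(0.2, ge=0, lt=1)
    noise_sd: float = Field(0.3, ge=0)
    obs_noise_sd: float = Field(0.2, ge=0)
    spatial_range_km: float = Field(30.0, gt=0)
    seasonal_amplitude: float = 0.6
    intercept: float = 2.2
    true_coefficients: Optional[dict[str, float]] = None
    emission_trend_per_year: float = -0.08
    trend_regions: list[int] = [0, 1]
    swath_gap: Optional[list[float]] = None
    swath_gap_period: int = Field(2, ge=1)


class ModelSection(_Section):
    n_trees: int = Field(500, ge=10)
    max_features: float = Field(1.0 / 3.0, gt=0, le=1)
    max_depth: Optional[int] = None
    idw_power: float = Field(2.0, gt=0)
    idw_k_neighbors: int = Field(8, ge=1)


class AggregationSection(_Section):
    min_valid_days: int = Field(60, ge=1)
    min_monthly_obs: int = Field(8, ge=1)
    weighted: bool = True


class ExposureResponseSection(_Section):
    beta: float = 0.06
    beta_low: float = 0.05
    beta_high: float = 0.07
    per_ugm3: float = Field(1.0, gt=0)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.beta_low <= self.beta <= self.beta_high:
            raise ValueError("require beta_low <= beta <= beta_high")
        return self


class CounterfactualSection(_Section):
    mode: str = GLOBAL_MIN
    value: Optional[float] = None

    @model_validator(mode="after")
    def _valid(self):
        if self.mode not in (GLOBAL_MIN, PER_CELL_MIN, FIXED):
            raise ValueError(f"mode must be one of {GLOBAL_MIN!r}, {PER_CELL_MIN!r}, {FIXED!r}")
        if self.mode == FIXED and self.value is None:
            raise ValueError("fixed counterfactual needs a value")
        return self


class BurdenSection(_Section):
    allocation: str = PER_CELL_POPULATION

    @model_validator(mode="after")
    def _valid(self):
        if self.allocation not in (PER_CELL_POPULATION, REGION_MEAN_EXPOSURE):
            raise ValueError(
                f"allocation must be {PER_CELL_POPULATION!r} or {REGION_MEAN_EXPOSURE!r}")
        return self


class PathsSection(_Section):
    out_dir: str = "run_output"
    demographics_csv: Optional[str] = None  # external override; synthetic by default


class RunConfig(_Section):
    seed: int = 0
    log_level: str = "INFO"
    paths: PathsSection = PathsSection()
    synth: SynthSection = SynthSection()
    model: ModelSection = ModelSection()
    aggregation: AggregationSection = AggregationSection()
    exposure_response: ExposureResponseSection = ExposureResponseSection()
    counterfactual: CounterfactualSection = CounterfactualSection()
    burden: BurdenSection = BurdenSection()


def validate_config(path: str | Path) -> RunConfig:
    """Parse and schema-check a YAML run config, defaults filled in."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    return validate_config_dict(raw)


def validate_config_dict(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError("invalid run config:\n  " + "\n  ".join(lines)) from exc
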