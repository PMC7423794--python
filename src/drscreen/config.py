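"""Run configuration: a single YAML schema validated up front.

Unknown keys are rejected (typo safety) and all violations are reported
together, not just the first.  Referenced input paths must resolve at
validation time.
"""

from __future__ import annotations

import hashlib
import pathlib

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "ConfigError", "validate_config"]

_STRICT = ConfigDict(extra="forbid")


class ConfigError(ValueError):
    """Invalid run configuration; ``violations`` lists every problem."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid config: " + "; ".join(violations))


class CohortSection(BaseModel):
    model_config = _STRICT
    n_t1dm: int = Field(default=1232, ge=0)
    n_t2dm: int = Field(default=26812, ge=0)
    followup_years: float = Field(default=10.0, gt=0)
    screening_interval_years: float = Field(default=1.0, gt=0)
    jitter_years: float = Field(default=0.15, ge=0)


class SurvivalSection(BaseModel):
    model_config = _STRICT
    candidates: list[str] = ["hba1c", "duration", "sbp", "tchol", "bmi", "smoker"]
    alpha: float = Field(default=0.05, gt=0, lt=1)
    use_longitudinal: bool = True
    longitudinal_max_subjects: int = Field(default=1500, ge=10)
    compare_families: bool = False


class AnalysisSection(BaseModel):
    model_config = _STRICT
    discount_rate: float = Field(default=0.035, ge=0)
    discount_rate_sensitivity: float = Field(default=0.015, ge=0)
    threshold: float = Field(default=20000.0, gt=0)
    horizon_age: float = Field(default=100.0, gt=12)
    eligibility_rule: bool = False


class ScenarioSection(BaseModel):
    model_config = _STRICT
    hba1c_percent: list[float] = [6.5, 8.0, 9.5]
    t1dm_duration_years: list[float] = [3.0, 9.0, 15.0]
    t2dm_duration_years: list[float] = [1.5, 4.5, 8.0]


class PSASection(BaseModel):
    model_config = _STRICT
    n_draws: int = Field(default=1000, ge=1)
    cost_cv: float = Field(default=0.2, ge=0)
    utility_cv: float = Field(default=0.2, ge=0)
    sample_survival: bool = True
    sample_hes: bool = True


class PathsSection(BaseModel):
    model_config = _STRICT
    output_dir: str = "out"
    life_table: str | None = None
    transitions: str | None = None
    costs: str | None = None
    utilities: str | None = None


class RunConfig(BaseModel):
    model_config = _STRICT
    seed: int = 0
    verbosity: str = "info"
    cohort: CohortSection = CohortSection()
    survival: SurvivalSection = SurvivalSection()
    analysis: AnalysisSection = AnalysisSection()
    scenarios: ScenarioSection = ScenarioSection()
    psa: PSASection = PSASection()
    paths: PathsSection = PathsSection()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML config file, reporting all violations."""
    path = pathlib.Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        violations = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError(violations) from exc
    missing = []
    for name in ("life_table", "transitions", "costs", "utilities"):
        p = getattr(cfg.paths, name)
        if p is not None and not pathlib.Path(p).exists():
            missing.append(f"paths.{name}: file not found: {p}")
    if missing:
        raise ConfigError(missing)
    return cfg
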