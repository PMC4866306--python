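"""Validated run configuration (YAML) for the command-line interface."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["SimulationConfig", "ModelConfig", "EvaluationConfig", "RunConfig",
           "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationConfig(_Strict):
    n_a: int = Field(20, ge=1, description="MatA panel size")
    n_alpha: int = Field(20, ge=1, description="MatAlpha panel size")
    n_chrom: int = Field(16, ge=1)
    sites_per_chrom: int = Field(50, ge=1)
    chrom_length_cM: float = Field(100.0, gt=0)
    n_meioses: int = Field(12, ge=1, description="recombination rounds (F12)")
    n_rep: int = Field(4, ge=1, description="replicate measurements per trait")
    n_traits: int = Field(9, ge=1)
    excluded_a: list[str] = Field(default_factory=list)
    excluded_alpha: list[str] = Field(default_factory=list)


class ModelConfig(_Strict):
    models: list[str] = Field(default_factory=lambda: ["BLUP"])
    max_terms: int = Field(50, ge=1, description="forward-selection cap")
    inner_folds: int = Field(4, ge=2)
    interactions_max: int = Field(20, ge=0)

    @field_validator("models")
    @classmethod
    def _known(cls, v):
        from .evaluation import MODELS

        unknown = [m for m in v if m not in MODELS]
        if unknown:
            raise ValueError(f"unknown models {unknown}; choose from {MODELS}")
        return v


class EvaluationConfig(_Strict):
    scenarios: list[str] = Field(default_factory=lambda: ["random"])
    traits: list[str] | None = None
    fraction: float = Field(0.01, gt=0, lt=1)
    grid_sizes: list[int] | None = None

    @field_validator("scenarios")
    @classmethod
    def _known(cls, v):
        from .evaluation import SCENARIOS

        unknown = [s for s in v if s not in SCENARIOS]
        if unknown:
            raise ValueError(f"unknown scenarios {unknown}; choose from {SCENARIOS}")
        return v


class RunConfig(_Strict):
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    seed: int = 0
    out: str = "out"


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; missing file fields use defaults."""
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
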