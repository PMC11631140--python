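"""Run configuration for the end-to-end pipeline.

A single YAML/JSON document controls a run: the input source (an
OMOP-lite directory or an inline synthetic-cohort configuration), the
cohort policy, screening thresholds, interval settings, masking
threshold and the stages to execute.  Validation collects *all*
problems in one pass rather than failing on the first.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .cohort import CohortPolicy, GenderPolicy
from .screen import ScreenConfig
from .synthetic import SyntheticConfig

Stage = Literal["screen", "metrics", "profile", "sensitivity"]
ALL_STAGES: tuple[Stage, ...] = ("screen", "metrics", "profile", "sensitivity")


class ConfigError(ValueError):
    """Invalid run configuration; message lists every problem found."""


class CohortPolicyConfig(BaseModel):
    require_binary_sex: bool = True
    gender_policy: Literal["cisgender_only", "include_all_binary_sex"] = "cisgender_only"

    def to_policy(self) -> CohortPolicy:
        return CohortPolicy(
            require_binary_sex=self.require_binary_sex,
            gender_policy=GenderPolicy(self.gender_policy),
        )


class RunConfig(BaseModel):
    input_dir: Path | None = None
    synthetic: SyntheticConfig | None = None
    output_dir: Path
    cohort: CohortPolicyConfig = Field(default_factory=CohortPolicyConfig)
    screen: ScreenConfig = Field(default_factory=ScreenConfig)
    z: float = Field(default=1.96, gt=0)
    ci_n_mode: Literal["total", "incongruent"] = "total"
    mask_threshold: int = Field(default=20, ge=0)
    seed: int = 0
    stages: list[Stage] = Field(default_factory=lambda: list(ALL_STAGES))
    strict_load: bool = True

    @model_validator(mode="after")
    def _check(self):
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one input source required: set input_dir or synthetic"
            )
        if self.input_dir is not None and Path(self.input_dir) == Path(self.output_dir):
            raise ValueError("output_dir must differ from input_dir")
        if not self.stages:
            raise ValueError("stages must be nonempty")
        return self


def validate_config(raw: str | dict) -> RunConfig:
    """Parse and validate a raw YAML/JSON document or mapping.

    Raises :class:`ConfigError` whose message enumerates every
    validation failure (field path and reason), never a partial config.
    """
    if isinstance(raw, str):
        try:
            data = yaml.safe_load(raw) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"config is not valid YAML/JSON: {exc}") from exc
    else:
        data = raw
    if not isinstance(data, dict):
        raise ConfigError("config document must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            "invalid run config:\n  " + "\n  ".join(lines)
        ) from exc
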