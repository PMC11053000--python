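"""Run configuration: schema-validated settings for the CLI analyses.

A run is reproducible from its config plus seed alone; every report
embeds a digest of the resolved config.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .biomarkers import Thresholds
from .intervention import Formulation, default_formulation
from .parameters import KineticParameters, healthy_parameters
from .population import GeneratorConfig
from .stress import StressScenario

#: the four study arms and the ingredient classes they administer
ARM_CLASSES: dict[str, set | None] = {
    "stressed": None,
    "micronutrients": {"vitamin", "mineral"},
    "botanicals": {"botanical"},
    "combined": {"botanical", "vitamin", "mineral"},
}


class StressConfig(BaseModel):
    inflammatory: float = 1.0
    oxidative: float = 1.0
    insulin: float = 1.0

    def scenario(self) -> StressScenario:
        return StressScenario(self.inflammatory, self.oxidative, self.insulin)


class PopulationConfig(BaseModel):
    n: int = Field(default=1000, ge=0)
    seed: int = 0


class ThresholdConfig(BaseModel):
    ros_percent: float = 10.0
    tnfa: float = 1.0e-3
    sbp: float = 120.0
    pss: float = 13.0

    def thresholds(self) -> Thresholds:
        return Thresholds(self.ros_percent, self.tnfa, self.sbp, self.pss)


class RunConfig(BaseModel):
    """Settings for one analysis run."""

    model_file: str | None = None
    formulation_file: str | None = None
    stress: StressConfig = Field(default_factory=StressConfig)
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    arms: list[str] = Field(default_factory=lambda: list(ARM_CLASSES))
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    out_dir: str = "results"

    @field_validator("arms")
    @classmethod
    def _known_arms(cls, v: list[str]) -> list[str]:
        for arm in v:
            if arm not in ARM_CLASSES:
                raise ValueError(f"unknown arm '{arm}'; expected one of {sorted(ARM_CLASSES)}")
        return v

    # -- resolved objects --------------------------------------------------
    def params(self) -> KineticParameters:
        if self.model_file:
            return KineticParameters.from_json(self.model_file)
        return healthy_parameters()

    def formulation(self) -> Formulation:
        if self.formulation_file:
            return Formulation.from_json(self.formulation_file)
        return default_formulation()

    def arm_formulations(self) -> list[tuple[str, Formulation | None]]:
        full = self.formulation()
        out: list[tuple[str, Formulation | None]] = []
        for arm in self.arms:
            classes = ARM_CLASSES[arm]
            out.append((arm, None if classes is None else full.subset(classes, name=arm)))
        return out

    def generator(self) -> GeneratorConfig:
        return GeneratorConfig()

    def digest(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML or JSON run configuration (defaults when path is None)."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig(**data)
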