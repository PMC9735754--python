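"""Pipeline configuration: every tunable of the analysis in one validated object."""
from __future__ import annotations

from pydantic import BaseModel, Field

from .ploidy import ClassificationThresholds


class ThresholdSettings(BaseModel):
    """ESACP decision constants (c-units; tolerances relative)."""

    diploid_center: float = Field(default=2.0, gt=0)
    tetraploid_center: float = Field(default=4.0, gt=0)
    relative_tolerance: float = Field(default=0.10, gt=0, lt=1)
    rare_event_cutoff: float = Field(default=9.0, gt=0)
    secondary_event_cutoff: float = Field(default=5.0, gt=0)
    doubling_tolerance: float = Field(default=0.10, gt=0, lt=1)

    def to_thresholds(self) -> ClassificationThresholds:
        return ClassificationThresholds(**self.model_dump())


class PipelineConfig(BaseModel):
    """Settings for the simulate/analyze/evaluate/regress pipeline."""

    thresholds: ThresholdSettings = ThresholdSettings()
    kde_bandwidth: float = Field(default=0.1, gt=0)
    min_stemline_fraction: float = Field(default=0.05, gt=0)
    min_stemline_cells: int = Field(default=5, ge=1)
    bin_width: float = Field(default=0.1, gt=0)
    ci_level: float = Field(default=0.95, gt=0, lt=1)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)
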