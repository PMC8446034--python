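"""Schema-validated pipeline configuration.

One YAML file drives the whole pipeline; unknown keys are rejected so a
typo cannot silently fall back to a default.  Every threshold the method
leaves implicit (detector operating points, neighbour-deviation delta,
young-adult references, device calibrations, triage operating points)
lives here.
"""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsSection(_Strict):
    data_dir: str = "."
    model_file: str | None = None
    out_dir: str = "out"


class QASection(_Strict):
    fracture_threshold: float = 0.5
    implant_threshold: float = 0.5
    vcf_threshold: float = 0.5
    neighbor_delta: float = 1.0
    #: apply neighbour exclusion to predicted T-scores (default) or BMD
    neighbor_metric: Literal["t_score", "bmd"] = "t_score"


class ReferenceEntry(_Strict):
    mean: float = Field(gt=0)
    sd: float = Field(gt=0)


class CalibrationEntry(_Strict):
    slope: float = 1.0
    intercept: float = 0.0


class TriageSection(_Strict):
    t1: float
    t2: float
    scale: Literal["bmd", "t_score"] = "t_score"

    @model_validator(mode="after")
    def _ordered(self):
        if not self.t1 < self.t2:
            raise ValueError("triage requires t1 < t2")
        return self


class TrainingSection(_Strict):
    epochs: int = 300
    hidden: int = 16
    learning_rate: float = 0.01
    augment_per_sample: int = 0


class PipelineConfig(_Strict):
    seed: int = 0
    site: Literal["hip", "spine"]
    paths: PathsSection = PathsSection()
    qa: QASection = QASection()
    reference: dict[str, ReferenceEntry] = {
        "hip": ReferenceEntry(mean=0.942, sd=0.122),
        "spine": ReferenceEntry(mean=1.047, sd=0.110),
    }
    calibration: dict[str, CalibrationEntry] = {}
    triage: TriageSection = TriageSection(t1=-2.9, t2=-2.3, scale="t_score")
    risk_model: Literal["toy_logistic", "none"] = "toy_logistic"
    detector: Literal["synthetic"] = "synthetic"
    training: TrainingSection = TrainingSection()
    log_level: str = "INFO"


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
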