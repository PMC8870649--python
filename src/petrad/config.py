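"""Pipeline configuration schema (validated before any stage runs)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "DiscretizationBlock",
    "GLCMBlock",
    "SelectionBlock",
    "CVBlock",
    "ResponseBlock",
    "SimulateBlock",
    "PathsBlock",
    "PipelineConfig",
    "load_config",
]


class DiscretizationBlock(BaseModel):
    lower: float = 0.0
    upper: float = 60.0
    n_bins: int = Field(default=64, ge=2)
    bin_width: float | None = Field(default=None, gt=0)

    @field_validator("upper")
    @classmethod
    def _upper_gt_lower(cls, v, info):
        if v <= info.data.get("lower", 0.0):
            raise ValueError("upper must exceed lower")
        return v


class GLCMBlock(BaseModel):
    distance: int = Field(default=1, ge=1)
    directions: str = "3D-13dir"

    @field_validator("directions")
    @classmethod
    def _known(cls, v):
        if v not in ("3D-13dir", "2D-4dir"):
            raise ValueError("directions must be '3D-13dir' or '2D-4dir'")
        return v


class SelectionBlock(BaseModel):
    sort_mode: str = "abs"
    p_value_mode: str = "lrt"
    include_cga_post: bool = False

    @field_validator("sort_mode")
    @classmethod
    def _sort(cls, v):
        if v not in ("abs", "signed"):
            raise ValueError("sort_mode must be 'abs' or 'signed'")
        return v

    @field_validator("p_value_mode")
    @classmethod
    def _pmode(cls, v):
        if v not in ("lrt", "coef"):
            raise ValueError("p_value_mode must be 'lrt' or 'coef'")
        return v


class CVBlock(BaseModel):
    k: int = Field(default=5, ge=2)
    seed: int = 1
    stratified: bool = True
    nested: bool = False
    group_by_patient: bool = False
    discriminant: str = "linear"

    @field_validator("discriminant")
    @classmethod
    def _da(cls, v):
        if v not in ("linear", "quadratic"):
            raise ValueError("discriminant must be 'linear' or 'quadratic'")
        return v


class ResponseBlock(BaseModel):
    threshold_percent: float = Field(default=25.0, gt=0)


class SimulateBlock(BaseModel):
    enabled: bool = False
    n_noise_features: int = Field(default=10, ge=0)
    correlation: float = Field(default=0.0, gt=-1, lt=1)


class PathsBlock(BaseModel):
    features_csv: str | None = None
    labels_csv: str | None = None
    t1_features_csv: str | None = None
    out_dir: str = "petrad_out"


class PipelineConfig(BaseModel):
    discretization: DiscretizationBlock = DiscretizationBlock()
    glcm: GLCMBlock = GLCMBlock()
    selection: SelectionBlock = SelectionBlock()
    cv: CVBlock = CVBlock()
    response: ResponseBlock = ResponseBlock()
    simulate: SimulateBlock = SimulateBlock()
    paths: PathsBlock = PathsBlock()
    label_column: str = "dichotomous"
    district_column: str = "district"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
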