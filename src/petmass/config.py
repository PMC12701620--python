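"""Validated pipeline configuration.

Every knob of the analysis chain lives here with its documented default;
unknown keys in a config file are rejected rather than ignored.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class PipelineConfig(BaseModel):
    """All tunable parameters of the segmentation/feature/analysis chain."""

    model_config = ConfigDict(extra="forbid")

    # segmentation
    threshold_suv: float = Field(4.0, gt=0, description="absolute SUV threshold (strict >)")
    connectivity: Literal[6, 26] = 26
    min_voxels: int = Field(1, ge=1, description="minimum component size kept")

    # massiveness features
    erosion_spacing_mm: float = Field(4.0, gt=0)
    structuring_element: Literal["cube", "cross"] = "cube"
    median_pooling: Literal["pooled", "per-lesion"] = "pooled"

    # survival analysis
    horizon_years: float = Field(5.0, gt=0)
    stepwise_retention_p: float = Field(0.15, gt=0, le=1.0)

    # cohort simulation (used by the `simulate`/`run` commands)
    n_patients: int = Field(176, ge=2)

    seed: int = 0
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
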