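"""Pipeline configuration: every tunable in one serializable object.

The content hash identifies a configuration independently of key order, so
outputs can be traced back to the exact settings that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .fgvf import FGVFParams


@dataclass
class PipelineConfig:
    # contrast enhancement
    clahe_clip_limit: float = 0.01
    clahe_tiles: int = 8
    # vessel removal
    vessel_smooth_sigma: float = 1.5
    # FGVF
    fgvf: FGVFParams = field(default_factory=FGVFParams)
    # GLCM
    glcm_levels: int = 8
    glcm_symmetric: bool = True
    glcm_averaged: bool = True
    # classifier
    svm_c: float = 1.0
    cv_folds: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        fgvf = FGVFParams(**data.pop("fgvf", {}))
        return cls(fgvf=fgvf, **data)
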