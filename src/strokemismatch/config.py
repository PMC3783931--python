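"""Run configuration: every tunable threshold in one serializable object.

A run's report always embeds the resolved configuration and its hash, so any
mask or decision can be audited back to the exact thresholds that produced
it.  Config files are flat TOML; command-line flags override file values.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .lesion_segmentation import SegmentationParams


@dataclass
class RunConfig:
    # brain masking / laterality
    closing_radius: int = 2
    min_laterality_score: float = 0.1
    # segmentation
    k: float = 2.0
    adc_max: float = 620e-6
    tau_s: float = 4.0
    neighborhood: int = 5
    min_cluster_mL: float = 0.2
    opening_radius: int = 1
    allow_midline_crossing: bool = False
    # decision
    ratio_convention: str = "pwi_over_dwi"
    volume_threshold_mL: float = 10.0
    ratio_threshold: float = 1.2
    window_h: float = 4.5
    # consensus
    consensus_cutoff: int = 3
    # acquisition defaults for map computation
    b_value: float = 1000.0

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            k=self.k,
            adc_max=self.adc_max,
            tau_s=self.tau_s,
            neighborhood=self.neighborhood,
            min_cluster_mL=self.min_cluster_mL,
            opening_radius=self.opening_radius,
            allow_midline_crossing=self.allow_midline_crossing,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat TOML config; keyword overrides win over file values."""
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
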