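"""Validated pipeline configuration (JSON; unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .opls import DEFAULT_LOG2_FLOOR


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sigma_log: float = Field(0.1, ge=0)
    blot_scale_low: float = Field(0.5, gt=0)
    blot_scale_high: float = Field(2.0, gt=0)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_kinases: int = Field(4, ge=1)
    n_replicates: int = Field(3, ge=1)
    n_selective_positions: int = Field(4, ge=0, le=9)
    preference_strength: float = Field(5.0, gt=0)
    n_background_sites: int = Field(1900, ge=0)
    n_implanted_sites: int = Field(100, ge=0)
    noise: NoiseConfig = NoiseConfig()


class PipelineConfig(BaseModel):
    """Every tunable of the end-to-end pipeline; ``seed`` is mandatory."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    floor: float = Field(DEFAULT_LOG2_FLOOR, gt=0)
    cap_exceptions: list[tuple[int, str]] = []
    include_acceptor: bool = True
    min_overlap: int = Field(150, ge=2)
    select_fraction: float = Field(0.10, gt=0, le=1)
    simulation: SimulationConfig = SimulationConfig()

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not 0 <= v < 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        return v

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def digest(self) -> str:
        """Stable short digest of the effective configuration."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
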