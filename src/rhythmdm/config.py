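"""Pipeline configuration.

Defaults reproduce the study protocol and analysis settings: 3-day cycles of
9 prompts, cycles valid with at most 2 missing prompts, inclusion from 3
valid cycles, 0.1 transition pseudocount, 100,000-step random walks, and
Benjamini-Hochberg FDR at alpha 0.05.
"""
from __future__ import annotations

import hashlib
import json
from typing import Literal

import yaml
from pydantic import BaseModel, Field


class PipelineConfig(BaseModel):
    """All tunable settings of the marker pipeline."""

    cycle_length_days: int = Field(3, ge=1)
    prompts_per_day: int = Field(3, ge=1)
    max_missing_per_cycle: int = Field(2, ge=0)
    min_valid_cycles: int = Field(3, ge=3)
    flat_tol_H: float = Field(1e-9, ge=0)
    flat_tol_SC: float = Field(1e-9, ge=0)
    pseudo_count: float = Field(0.1, gt=0)
    denominator: Literal["tokens", "prompts"] = "tokens"
    delta_gap_mode: Literal["skip", "strict"] = "skip"
    aggregation: Literal["pool_counts", "average_P"] = "pool_counts"
    include_self_hit: bool = True
    n_walk_steps: int = Field(100_000, ge=1)
    walk_start_state: int = Field(1, ge=1, le=9)
    fdr_alpha: float = Field(0.05, gt=0, lt=1)
    seed: int = 0

    @property
    def prompts_per_cycle(self) -> int:
        return self.cycle_length_days * self.prompts_per_day

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for provenance."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
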