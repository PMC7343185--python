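"""JSON-validated run configuration for end-to-end validation runs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from pydantic import BaseModel, Field, field_validator

from .hrf import HRFSpec, named_hrf
from .prf import GaussianPRF
from .stimulus import BarSweepSpec


class StimulusConfig(BaseModel):
    field_extent_deg: float = 20.0
    n_samples: int = 101
    bar_width_deg: float = 2.0
    seconds_per_sweep: float = 18.0
    frame_duration_sec: float = 1.0
    design: str = "sweep"  # "sweep" | "random"
    seed: int | None = None

    @field_validator("design")
    @classmethod
    def _check_design(cls, v):
        if v not in ("sweep", "random"):
            raise ValueError("design must be 'sweep' or 'random'")
        return v

    def to_spec(self) -> BarSweepSpec:
        return BarSweepSpec(
            bar_width_deg=self.bar_width_deg,
            seconds_per_sweep=self.seconds_per_sweep,
            frame_duration_sec=self.frame_duration_sec,
            randomize=self.design == "random",
            seed=self.seed,
        )


class PRFConfig(BaseModel):
    x0: float = 3.0
    y0: float = 3.0
    sigma: float = Field(2.0, gt=0)
    gain: float = 1.0

    def to_prf(self) -> GaussianPRF:
        return GaussianPRF(x0=self.x0, y0=self.y0, sigma_major=self.sigma, gain=self.gain)


class FitterConfig(BaseModel):
    hrf: str = "canonical"
    n_starts: int = Field(3, ge=1)
    seed: int = 0
    aggregate_k: int = Field(1, ge=1)


class RunConfig(BaseModel):
    """Full condition grid for a synthesize -> fit -> report run."""

    stimulus: StimulusConfig = StimulusConfig()
    prfs: Sequence[PRFConfig] = (PRFConfig(),)
    hrfs: Sequence[str] = ("canonical",)
    noise_levels: Sequence[str] = ("none",)
    repetitions: int = Field(1, ge=1)
    master_seed: int = 0
    amplitude_psc: float = Field(10.0, gt=0)
    fitter: FitterConfig = FitterConfig()

    @field_validator("prfs", "hrfs", "noise_levels")
    @classmethod
    def _non_empty(cls, v):
        if len(v) == 0:
            raise ValueError("condition lists must be non-empty")
        return v

    def resolve_hrfs(self, dt: float) -> dict[str, HRFSpec]:
        return {name: named_hrf(name, dt=dt) for name in self.hrfs}

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))
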