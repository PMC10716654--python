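"""Run configuration: schema-validated YAML round-tripping.

The default configuration reproduces the full calibration schedule
(25 000-model initial round, three 10 000-model refinement rounds, 0.25%
rejection tolerance) on the default 21 ka BP grid; the "desk" profile scales
the experiment to a workstation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .params import DEFAULT_PRIOR_RANGES


class GridConfig(BaseModel):
    rows: int = 24
    cols: int = 30
    cell_width_km: float = 86.6
    cell_height_km: float = 75.6
    t_start_bp: float = 21_000.0
    t_end_bp: float = 100.0
    step_years: float = 10.0


class SyntheticConfig(BaseModel):
    collapse_frac: float = 0.45
    collapse_depth: float = 0.5
    recovery_frac: float = 0.15
    landuse_frac: float = 0.8
    n_fossils: int = 120
    age_sd_years: float = 30.0


class RunConfig(BaseModel):
    """Top-level configuration of an end-to-end run."""

    grid: GridConfig = Field(default_factory=GridConfig)
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    priors: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            k: tuple(v) for k, v in DEFAULT_PRIOR_RANGES.items()
        }
    )
    round_sizes: tuple[int, ...] = (25_000, 10_000, 10_000, 10_000)
    tolerance: float = 0.0025
    scenarios: list[str] = Field(
        default_factory=lambda: ["no_hunting", "no_landuse", "no_human"]
    )
    seed: int = 0
    landscape_path: Optional[str] = None
    human_path: Optional[str] = None
    fossils_path: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        for name, (lo, hi) in self.priors.items():
            if lo > hi:
                raise ValueError(f"prior for {name} has lo > hi")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if any(n < 1 for n in self.round_sizes):
            raise ValueError("round sizes must be positive")
        return self

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def desk_profile(cls, **overrides) -> "RunConfig":
        """Workstation-scale profile: small grid, 300 + 2x200 simulations."""
        defaults = dict(
            grid=GridConfig(rows=20, cols=20, t_start_bp=3090, t_end_bp=100),
            round_sizes=(300, 200, 200),
            tolerance=0.20,
            synthetic=SyntheticConfig(n_fossils=60),
        )
        defaults.update(overrides)
        return cls(**defaults)
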