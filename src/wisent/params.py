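"""Demographic, niche and human-interaction parameters of one simulation.

One `DemographicParams` instance is a single point in the Latin-hypercube
prior: Ricker growth (r_max, r_sd), density-linked carrying capacity
(max_density), the Allee extirpation threshold, dispersal (fraction and
maximum distance), the generalized Holling harvest response (h_max, q_shape,
theta), the centre of the human-abundance sampling window (omega), and the
realized-niche descriptors (volume_fraction, marginality).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace


@dataclass(frozen=True)
class DemographicParams:
    #: per-generation intrinsic growth rate, ln of the finite rate R
    r_max: float = 0.18
    #: environmental s.d. of the per-generation growth rate
    r_sd: float = 0.05
    #: maximum population density at suitability 1, animals km^-2
    max_density: float = 0.3
    #: abundance per cell below which the local population is extirpated
    allee_threshold: float = 9.0
    #: proportion of each cell's population emigrating per generation
    dispersal_fraction: float = 0.05
    #: maximum dispersal distance, km
    dispersal_max_km: float = 110.0
    #: maximum harvested proportion of a cell's population per generation
    h_max: float = 0.12
    #: harvest functional-response exponent: 1 = type II, 2 = type III
    q_shape: float = 1.2
    #: half-saturation abundance of the harvest response, animals per cell
    theta: float = 200.0
    #: centre of the human-abundance sampling window in [-1, 1] s.d. units
    omega: float = 0.0
    #: fraction of the full niche's density mass retained by the realized niche
    volume_fraction: float = 0.65
    #: centroid displacement of the realized niche, in per-axis s.d. units
    marginality: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_sd", "allee_threshold", "marginality"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("dispersal_fraction", "h_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 1.0 <= self.q_shape <= 2.0:
            raise ValueError("q_shape must lie in [1, 2]")
        if not -1.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [-1, 1]")
        if not 0.0 < self.volume_fraction <= 1.0:
            raise ValueError("volume_fraction must lie in (0, 1]")
        if self.max_density <= 0:
            raise ValueError("max_density must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.dispersal_max_km < 0:
            raise ValueError("dispersal_max_km must be nonnegative")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def replace(self, **kw) -> "DemographicParams":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicParams":
        return cls(**{k: float(v) for k, v in d.items()})


#: Parameter names in canonical order (columns of posterior tables).
PARAM_NAMES: tuple[str, ...] = tuple(DemographicParams().to_dict().keys())

#: Wide plausible prior ranges for the LHS hypercube. Dispersal and harvest
#: bounds follow the study design (5-25% dispersing per generation, up to
#: 300 km; harvest up to ~30% per generation); the rest are broad uniform
#: windows around field estimates for large-bodied grazers.
DEFAULT_PRIOR_RANGES: dict[str, tuple[float, float]] = {
    "r_max": (0.05, 0.40),
    "r_sd": (0.0, 0.15),
    "max_density": (0.1, 1.5),
    "allee_threshold": (0.0, 50.0),
    "dispersal_fraction": (0.05, 0.25),
    "dispersal_max_km": (0.0, 300.0),
    "h_max": (0.0, 0.30),
    "q_shape": (1.0, 2.0),
    "theta": (50.0, 2000.0),
    "omega": (-1.0, 1.0),
    "volume_fraction": (0.3, 1.0),
    "marginality": (0.0, 1.0),
}
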