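"""Equal-area model grid and the generational time axis.

The simulation lattice is a rectangular grid of equal-area cells (defaults
match an Albers equal-area projection at 86.6 km x 75.6 km per cell) stepped
at one bison generation (10 years) between a start and end expressed in
calibrated years before present (BP, relative to 1950 CE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Calendar origin of the BP scale.
BP_REFERENCE_CE = 1950


def bp_to_ce(year_bp: float) -> float:
    """Convert years before present (1950) to calendar years CE."""
    return BP_REFERENCE_CE - year_bp


def ce_to_bp(year_ce: float) -> float:
    """Convert calendar years CE to years before present (1950)."""
    return BP_REFERENCE_CE - year_ce


def bp_ce_convert(year: float, direction: str) -> float:
    """Convert between BP and CE calendars.

    Parameters
    ----------
    year : float
        The year to convert.
    direction : {"bp_to_ce", "ce_to_bp"}
        Direction of conversion.
    """
    if direction == "bp_to_ce":
        return bp_to_ce(year)
    if direction == "ce_to_bp":
        return ce_to_bp(year)
    raise ValueError(f"unknown direction {direction!r}")


class GridConfigError(ValueError):
    """Raised for inconsistent grid/time-axis configuration."""


@dataclass(frozen=True)
class GridSpec:
    """Dimensions and time axis of the simulation lattice.

    Attributes
    ----------
    n_rows, n_cols : int
        Lattice shape; row 0 is the northern edge.
    cell_width_km, cell_height_km : float
        Cell dimensions on the equal-area projection.
    t_start_bp, t_end_bp : float
        First and last simulated generation, in years BP (start is older).
    step_years : float
        Generation length; one simulation step.
    """

    n_rows: int
    n_cols: int
    cell_width_km: float = 86.6
    cell_height_km: float = 75.6
    t_start_bp: float = 21_000.0
    t_end_bp: float = 100.0
    step_years: float = 10.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridConfigError("grid must have at least one row and column")
        if self.cell_width_km <= 0 or self.cell_height_km <= 0:
            raise GridConfigError("cell dimensions must be strictly positive")
        if self.step_years <= 0:
            raise GridConfigError("step_years must be positive")
        span = self.t_start_bp - self.t_end_bp
        if span <= 0:
            raise GridConfigError("t_start_bp must be older than t_end_bp")
        n, rem = divmod(span, self.step_years)
        if abs(rem) > 1e-9 and abs(rem - self.step_years) > 1e-9:
            raise GridConfigError(
                f"time span {span} is not a multiple of step {self.step_years}"
            )

    @property
    def cell_area_km2(self) -> float:
        return self.cell_width_km * self.cell_height_km

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_steps(self) -> int:
        return int(round((self.t_start_bp - self.t_end_bp) / self.step_years)) + 1

    @property
    def shape(self) -> tuple[int, int, int]:
        """(n_steps, n_rows, n_cols) array shape of a full space-time field."""
        return (self.n_steps, self.n_rows, self.n_cols)

    @property
    def times_bp(self) -> np.ndarray:
        """Time coordinate per step, years BP, descending (old -> young)."""
        return self.t_start_bp - self.step_years * np.arange(self.n_steps)

    @property
    def times_ce(self) -> np.ndarray:
        return bp_to_ce(self.times_bp)

    def step_of_bp(self, year_bp: float) -> int:
        """Index of the generational step containing ``year_bp`` (clamped)."""
        idx = int(round((self.t_start_bp - year_bp) / self.step_years))
        return min(max(idx, 0), self.n_steps - 1)

    def step_of_ce(self, year_ce: float) -> int:
        return self.step_of_bp(ce_to_bp(year_ce))

    def contains_bp(self, year_bp: float) -> bool:
        return self.t_end_bp <= year_bp <= self.t_start_bp

    def cell_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def cell_rowcol(self, cell_id: int) -> tuple[int, int]:
        return divmod(int(cell_id), self.n_cols)

    def cell_xy_km(self, row: int, col: int) -> tuple[float, float]:
        """Projected centre coordinates of a cell (x east, y north) in km."""
        x = (col + 0.5) * self.cell_width_km
        y = -(row + 0.5) * self.cell_height_km
        return x, y


def make_grid(
    rows: int,
    cols: int,
    t_start_bp: float = 21_000.0,
    t_end_bp: float = 100.0,
    step_years: float = 10.0,
    cell_width_km: float = 86.6,
    cell_height_km: float = 75.6,
) -> GridSpec:
    """Build a :class:`GridSpec`, validating that the span divides evenly."""
    return GridSpec(
        n_rows=rows,
        n_cols=cols,
        cell_width_km=cell_width_km,
        cell_height_km=cell_height_km,
        t_start_bp=t_start_bp,
        t_end_bp=t_end_bp,
        step_years=step_years,
    )
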