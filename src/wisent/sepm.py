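"""Spatially explicit population model (SEPM).

Each grid cell holds a scalar population governed, per ten-year generation,
by (in order): carrying-capacity update from habitat suitability, stochastic
Ricker growth, harvest by humans via a generalized Holling functional
response, distance-kernel dispersal through a friction landscape, and a hard
Allee extirpation threshold. Abundance is real-valued; the Allee threshold
supplies the discreteness of small-population collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xarray as xr
from scipy import ndimage

from .grid import GridSpec
from .landscape import LandscapeSeries
from .params import DemographicParams

#: extirpation_step sentinels
EXTANT = -1
NEVER_OCCUPIED = -2


def carrying_capacity(
    suitability: np.ndarray | float, max_density: float, cell_area_km2: float
) -> np.ndarray | float:
    """Cell carrying capacity: linear in habitat suitability.

    At suitability 1 the cell supports ``max_density * cell_area`` animals
    (0.3 km^-2 on an 86.6 km x 75.6 km cell is about 2000 bison); lower
    suitability reduces K proportionally.
    """
    return np.asarray(suitability) * max_density * cell_area_km2


def step_growth(
    N: np.ndarray,
    K: np.ndarray,
    r_max: float,
    r_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stochastic Ricker update N' = N exp(r_t (1 - N/K)), r_t ~ N(r_max, r_sd).

    Cells with K = 0 collapse to zero. One independent growth-rate draw per
    cell per generation (environmental stochasticity).
    """
    N = np.asarray(N, float)
    K = np.asarray(K, float)
    r = rng.normal(r_max, r_sd, size=N.shape) if r_sd > 0 else np.full(N.shape, r_max)
    return growth_with_rates(N, K, r)


def growth_with_rates(N: np.ndarray, K: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Ricker update with an externally supplied growth-rate field."""
    ratio = np.where(K > 0, N / np.where(K > 0, K, 1.0), 0.0)
    out = np.where(K > 0, N * np.exp(r * (1.0 - ratio)), 0.0)
    return np.where(N > 0, out, 0.0)


def step_harvest(
    N: np.ndarray,
    human: np.ndarray,
    h_max: float,
    q_shape: float,
    theta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Harvest offtake under a generalized Holling functional response.

    Offtake O = min(h_max N, h_max * human * N * N^q / (theta^q + N^q)) with
    q in [1, 2] interpolating a type II (q = 1) and type III (q = 2)
    response; ``human`` is the realized relative human abundance. Returns
    (post-harvest N, offtake).
    """
    N = np.asarray(N, float)
    human = np.asarray(human, float)
    with np.errstate(over="ignore"):
        Nq = np.where(N > 0, N**q_shape, 0.0)
        avail = np.where(N > 0, Nq / (theta**q_shape + Nq), 0.0)
    offtake = np.minimum(h_max * N, h_max * human * N * avail)
    offtake = np.clip(offtake, 0.0, N)
    return N - offtake, offtake


def dispersal_kernel(
    grid: GridSpec, dispersal_max_km: float
) -> np.ndarray | None:
    """Distance-decay kernel over grid offsets within the maximum distance.

    Weight exp(-d / lambda) with lambda = dispersal_max_km / 3, over offsets
    with grid-Euclidean distance 0 < d <= dispersal_max_km. Returns None when
    no neighbouring cell is reachable.
    """
    if dispersal_max_km <= 0:
        return None
    max_di = int(dispersal_max_km // grid.cell_height_km)
    max_dj = int(dispersal_max_km // grid.cell_width_km)
    if max_di == 0 and max_dj == 0:
        return None
    lam = dispersal_max_km / 3.0
    di = np.arange(-max_di, max_di + 1)[:, None]
    dj = np.arange(-max_dj, max_dj + 1)[None, :]
    d = np.hypot(di * grid.cell_height_km, dj * grid.cell_width_km)
    k = np.where((d > 0) & (d <= dispersal_max_km), np.exp(-d / lam), 0.0)
    if not np.any(k > 0):
        return None
    return k


def step_dispersal(
    N: np.ndarray,
    friction: np.ndarray,
    dispersal_fraction: float,
    dispersal_max_km: float,
    grid: GridSpec,
    rng: np.random.Generator | None = None,
    kernel: np.ndarray | None = None,
    stochastic: bool = False,
) -> np.ndarray:
    """Redistribute a fixed fraction of each cell's animals to neighbours.

    Destination weights are kernel(distance) * friction(destination); ice
    (friction 0) blocks settlement. Sources with no reachable destination
    keep their movers. Deterministic mode moves expected mass and conserves
    total abundance exactly; stochastic mode draws multinomial movers.
    """
    N = np.asarray(N, float)
    if dispersal_fraction <= 0:
        return N.copy()
    if kernel is None:
        kernel = dispersal_kernel(grid, dispersal_max_km)
    if kernel is None:
        return N.copy()

    f = np.asarray(friction, float)
    # normalization Z(src) = sum over destinations of k * friction(dest)
    Z = ndimage.correlate(f, kernel, mode="constant", cval=0.0)
    can_move = Z > 0
    movers = np.where(can_move, dispersal_fraction * N, 0.0)

    if not stochastic:
        src_term = np.where(can_move, movers / np.where(can_move, Z, 1.0), 0.0)
        # inflow(dest) = friction(dest) * sum_src k(src->dest) * movers/Z
        # kernel is symmetric in offset, so correlate == convolve here.
        inflow = f * ndimage.correlate(src_term, kernel, mode="constant", cval=0.0)
        return N - movers + inflow

    if rng is None:
        raise ValueError("stochastic dispersal requires an rng")
    out = N - movers
    R, C = N.shape
    ki, kj = kernel.shape
    oi, oj = ki // 2, kj // 2
    for r in range(R):
        for c in range(C):
            m = movers[r, c]
            if m <= 0:
                continue
            i0, i1 = max(0, r - oi), min(R, r + oi + 1)
            j0, j1 = max(0, c - oj), min(C, c + oj + 1)
            w = kernel[i0 - r + oi : i1 - r + oi, j0 - c + oj : j1 - c + oj] * f[i0:i1, j0:j1]
            tot = w.sum()
            if tot <= 0:
                out[r, c] += m
                continue
            counts = rng.multinomial(int(round(m)), (w / tot).ravel()).reshape(w.shape)
            out[i0:i1, j0:j1] += counts
    return out


def apply_allee(N: np.ndarray, allee_threshold: float) -> np.ndarray:
    """Local extirpation: cells strictly below the threshold drop to zero."""
    N = np.asarray(N, float)
    if allee_threshold <= 0:
        return N.copy()
    return np.where(N < allee_threshold, 0.0, N)


def extirpation_steps(abundance: np.ndarray) -> np.ndarray:
    """Per-cell first step after which the cell stays empty to the end.

    Returns EXTANT (-1) for cells occupied at the final step and
    NEVER_OCCUPIED (-2) for cells that were never occupied.
    """
    occ = abundance > 0
    T = occ.shape[0]
    ever = occ.any(axis=0)
    # index of last occupied step
    last = T - 1 - np.argmax(occ[::-1], axis=0)
    out = np.where(ever, last + 1, NEVER_OCCUPIED)
    out = np.where(ever & occ[-1], EXTANT, out)
    return out.astype(np.int32)


@dataclass
class SimResult:
    """Trajectories of one SEPM run."""

    grid: GridSpec
    abundance: np.ndarray        # (T, R, C)
    offtake: np.ndarray          # (T, R, C)
    extirpation_step: np.ndarray  # (R, C) int32; -1 extant, -2 never occupied

    @property
    def totals(self) -> np.ndarray:
        return self.abundance.sum(axis=(1, 2))

    @property
    def offtake_totals(self) -> np.ndarray:
        return self.offtake.sum(axis=(1, 2))

    def occupancy(self) -> np.ndarray:
        return self.abundance > 0

    def to_dataset(self) -> xr.Dataset:
        g = self.grid
        return xr.Dataset(
            {
                "abundance": (("time", "row", "col"), self.abundance),
                "offtake": (("time", "row", "col"), self.offtake),
                "extirpation_step": (("row", "col"), self.extirpation_step),
            },
            coords={
                "time": ("time", g.times_bp, {"units": "years BP"}),
                "row": np.arange(g.n_rows),
                "col": np.arange(g.n_cols),
            },
            attrs={
                "cell_width_km": g.cell_width_km,
                "cell_height_km": g.cell_height_km,
                "step_years": g.step_years,
            },
        )

    def to_netcdf(self, path: str | Path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "SimResult":
        times = np.asarray(ds["time"].values, float)
        grid = GridSpec(
            n_rows=ds.sizes["row"],
            n_cols=ds.sizes["col"],
            cell_width_km=float(ds.attrs["cell_width_km"]),
            cell_height_km=float(ds.attrs["cell_height_km"]),
            t_start_bp=float(times[0]),
            t_end_bp=float(times[-1]),
            step_years=float(ds.attrs["step_years"]),
        )
        return cls(
            grid=grid,
            abundance=np.asarray(ds["abundance"].values, float),
            offtake=np.asarray(ds["offtake"].values, float),
            extirpation_step=np.asarray(ds["extirpation_step"].values, np.int32),
        )

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "SimResult":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def simulate(
    params: DemographicParams,
    landscape: LandscapeSeries,
    human_realization: np.ndarray,
    seed: int | np.random.SeedSequence,
    init: str | np.ndarray = "at K",
    start_step: int = 0,
    h_max_factor: np.ndarray | None = None,
    stochastic_dispersal: bool = False,
) -> SimResult:
    """Run the SEPM over the landscape's full time axis.

    Per generation, in order: carrying-capacity update from that step's
    suitability, Ricker growth, harvest, dispersal, Allee threshold. The
    first recorded step is the initial state (no dynamics applied).

    Parameters
    ----------
    human_realization : (T, R, C) array
        Realized relative human abundance (see `humans.sample_human_surface`).
    init : "at K" or (R, C) array
        Initial abundance; "at K" starts every cell at its carrying capacity.
    start_step : int
        Index of the initial step; earlier steps are recorded as zero. Used
        by scenario branching (e.g. restart from a saved 1500 CE state).
    h_max_factor : optional (T,) array
        Per-step multiplier on h_max (harvest-escalation scans).
    """
    grid = landscape.grid
    T, R, C = grid.shape
    if human_realization.shape != (T, R, C):
        raise ValueError(
            f"human realization shape {human_realization.shape} != {grid.shape}"
        )
    rng = np.random.default_rng(seed)
    area = grid.cell_area_km2
    kernel = dispersal_kernel(grid, params.dispersal_max_km)

    # environmental growth noise is pre-drawn for the whole span, indexed by
    # step, so runs branched from a mid-series state share the same
    # generation-by-generation noise as their parent (common random numbers)
    if params.r_sd > 0:
        r_field = rng.normal(params.r_max, params.r_sd, size=(T, R, C))
    else:
        r_field = np.full((T, R, C), params.r_max)

    abundance = np.zeros((T, R, C))
    offtake = np.zeros((T, R, C))

    K0 = carrying_capacity(landscape.suitability[start_step], params.max_density, area)
    if isinstance(init, str):
        if init != "at K":
            raise ValueError(f"unknown init mode {init!r}")
        N = np.asarray(K0, float).copy()
    else:
        N = np.asarray(init, float).copy()
        if N.shape != (R, C):
            raise ValueError("init array shape mismatch")
    N = apply_allee(N, params.allee_threshold)
    abundance[start_step] = N

    for t in range(start_step + 1, T):
        K = carrying_capacity(landscape.suitability[t], params.max_density, area)
        N = growth_with_rates(N, K, r_field[t])
        h = params.h_max
        if h_max_factor is not None:
            h = h * float(h_max_factor[t])
        h = min(h, 1.0)
        N, O = step_harvest(N, human_realization[t], h, params.q_shape, params.theta)
        N = step_dispersal(
            N,
            landscape.friction[t],
            params.dispersal_fraction,
            params.dispersal_max_km,
            grid,
            rng=rng,
            kernel=kernel,
            stochastic=stochastic_dispersal,
        )
        N = apply_allee(N, params.allee_threshold)
        abundance[t] = N
        offtake[t] = O

    return SimResult(
        grid=grid,
        abundance=abundance,
        offtake=offtake,
        extirpation_step=extirpation_steps(abundance),
    )
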