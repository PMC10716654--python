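"""Synthetic landscapes, human fields and fossil records with known truth.

Generates inputs with the statistical structure the analysis assumes: a
spatially autocorrelated suitability field with an abrupt mid-series
collapse and gradual recovery (a Bolling-Allerod-style warming analogue), a
poleward-retreating ice mask, land-use onset late in the series reducing
forage biomass in a contiguous block, a monotonically expanding human field
with cell-wise uncertainty, and fossils sampled from a known-truth
simulation with Gaussian dating error and integer quality scores.

One master seed spawns independent substreams per operation (sequence-number
derivation), so each product can be regenerated independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fossils import FossilRecord
from .grid import GridSpec
from .landscape import HumanField, LandscapeSeries
from .params import DemographicParams
from . import niche as _niche
from . import humans as _humans
from . import sepm as _sepm

# substream sequence numbers per operation
_STREAM_LANDSCAPE = 0
_STREAM_HUMANS = 1
_STREAM_FOSSILS = 2
_STREAM_TRUTH_SIM = 3


def _substream(seed: int | np.random.SeedSequence, k: int) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.SeedSequence(seed.entropy, spawn_key=seed.spawn_key + (k,))
    return np.random.SeedSequence(seed, spawn_key=(k,))


def smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], blur_radius: float = 2.0
) -> np.ndarray:
    """Smoothed white noise rescaled to [0, 1]: the simplest spatially
    autocorrelated random field (Gaussian blur, radius 2 cells)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), blur_radius, mode="nearest")
    lo, hi = f.min(), f.max()
    if hi == lo:
        return np.full(shape, 0.5)
    return (f - lo) / (hi - lo)


def gen_landscape(
    grid: GridSpec,
    collapse_step: int,
    collapse_depth: float,
    recovery_steps: int,
    landuse_onset_step: int,
    seed: int | np.random.SeedSequence = 0,
    ice_rows_start_frac: float = 0.3,
    ice_free_step_frac: float = 0.5,
    landuse_min_mult: float = 0.4,
    landuse_friction: float = 0.6,
    noise_sd: float = 0.02,
) -> LandscapeSeries:
    """Generate an environmental time series with a mid-series collapse.

    Mean suitability drops by ``collapse_depth`` at ``collapse_step`` and
    recovers linearly over ``recovery_steps``; land use reduces biomass (and
    suitability, via the biomass axis of the niche) in the western block of
    columns from ``landuse_onset_step``; ice covers the northern rows at the
    start and retreats poleward monotonically, clearing by
    ``ice_free_step_frac`` of the series. Deterministic given the seed.
    """
    T, R, C = grid.shape
    if not 0 <= collapse_step < T:
        raise ValueError("collapse_step outside the time axis")
    if not 0.0 <= collapse_depth <= 1.0:
        raise ValueError("collapse_depth must lie in [0, 1]")
    rng = np.random.default_rng(_substream(seed, _STREAM_LANDSCAPE))

    base = 0.15 + 0.8 * smooth_field(rng, (R, C))  # keep away from hard 0/1

    # collapse severity profile in time: 0 before the event, 1 at the event,
    # decaying linearly back to 0 over the recovery
    g = np.zeros(T)
    if collapse_depth > 0:
        rec = max(int(recovery_steps), 1)
        for t in range(collapse_step, T):
            g[t] = max(1.0 - (t - collapse_step) / rec, 0.0)

    # the event hits regions unevenly (refugial areas lose little); the
    # spatial weight is normalized so the *mean* drop equals collapse_depth
    w = smooth_field(rng, (R, C))
    w = w / max(w.mean(), 1e-12)
    m_cell = np.clip(
        1.0 - g[:, None, None] * collapse_depth * w[None, :, :], 0.0, None
    )
    #: mean temporal modulation (used for the temperature excursion)
    m = 1.0 - g * collapse_depth

    # slow temporal noise, smoothed over steps so trajectories stay smooth
    eps = ndimage.gaussian_filter1d(rng.standard_normal(T), 2.0) * noise_sd

    suit_nolu = np.clip(
        base[None, :, :] * m_cell * (1.0 + eps)[:, None, None], 0.0, 1.0
    )

    # land use: contiguous western block, multiplier declining after onset
    landuse_mult = np.ones((T, R, C))
    block = np.zeros((R, C), bool)
    block[:, : max(C // 3, 1)] = True
    if landuse_onset_step < T:
        dur = max(T - 1 - landuse_onset_step, 1)
        for t in range(landuse_onset_step, T):
            frac = (t - landuse_onset_step) / dur
            mult = 1.0 - (1.0 - landuse_min_mult) * frac
            landuse_mult[t][block] = mult

    suitability = suit_nolu * landuse_mult

    # ice: northern rows, monotone poleward retreat
    ice = np.zeros((T, R, C), bool)
    rows0 = int(round(ice_rows_start_frac * R))
    t_free = max(int(ice_free_step_frac * T), 1)
    for t in range(T):
        n_ice = int(round(rows0 * max(0.0, 1.0 - t / t_free)))
        if n_ice > 0:
            ice[t, :n_ice, :] = True

    suitability = np.where(ice, 0.0, suitability)
    suit_nolu = np.where(ice, 0.0, suit_nolu)

    biomass_raw = (1.0 + 4.0 * base)[None, :, :] * m_cell * (1.0 + eps)[:, None, None]
    biomass_raw = np.clip(biomass_raw, 0.0, None)
    biomass_adjusted = biomass_raw * landuse_mult

    friction_nolu = np.where(ice, 0.0, 1.0)
    friction = np.where(
        ice, 0.0, np.where(landuse_mult < 1.0, landuse_friction, 1.0)
    )

    # temperature: latitudinal gradient + the warming event driving collapse
    lat_grad = np.linspace(-5.0, 8.0, R)[:, None] * np.ones((1, C))
    warm = 4.0 * (1.0 - m)  # collapse maps to a temperature excursion
    temperature = lat_grad[None, :, :] + warm[:, None, None] + eps[:, None, None]

    return LandscapeSeries(
        grid=grid,
        suitability=suitability,
        biomass_adjusted=biomass_adjusted,
        ice=ice,
        friction=friction,
        suitability_nolanduse=suit_nolu,
        biomass_raw=biomass_raw,
        friction_nolanduse=friction_nolu,
        temperature=temperature,
    )


def gen_human_field(
    grid: GridSpec,
    growth_rate: float,
    carrying_level: float = 1.0,
    sd_frac: float = 0.2,
    seed: int | np.random.SeedSequence = 0,
    n0_frac: float = 0.01,
    spatial_cv: float = 0.3,
) -> HumanField:
    """Logistic per-cell human expansion toward ``carrying_level``.

    Each cell follows n(t) = L_c n0 / (n0 + (L_c - n0) e^{-r t}) toward a
    spatially heterogeneous ceiling L_c (a smooth random fraction of
    ``carrying_level``, so late-series human pressure has persistent spatial
    structure and low-pressure refugia exist), with log-normal heterogeneity
    of coefficient of variation ``spatial_cv`` in the starting levels. The
    s.d. layer is ``sd_frac`` times the mean. Negative growth rates give
    declines.
    """
    if np.isnan(growth_rate):
        raise ValueError("growth_rate must not be NaN")
    if sd_frac < 0:
        raise ValueError("sd_frac must be nonnegative")
    T, R, C = grid.shape
    rng = np.random.default_rng(_substream(seed, _STREAM_HUMANS))
    if spatial_cv > 0:
        L = carrying_level * (0.1 + 0.9 * smooth_field(rng, (R, C)))
        sigma = np.sqrt(np.log1p(spatial_cv**2))
        het = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=(R, C)))
    else:
        L = np.full((R, C), float(carrying_level))
        het = np.ones((R, C))
    n0 = np.clip(n0_frac * L * het, 1e-12, L)
    t = np.arange(T)[:, None, None]
    if growth_rate == 0:
        mean = np.broadcast_to(n0, (T, R, C)).copy()
    else:
        mean = L * n0 / (n0 + (L - n0) * np.exp(-growth_rate * t))
    sd = sd_frac * mean
    return HumanField(
        mean=mean, sd=sd, times_bp=grid.times_bp, native_step_years=grid.step_years
    )


def gen_fossils(
    truth: "_sepm.SimResult",
    n_fossils: int,
    age_sd_years: float = 30.0,
    quality_range: tuple[int, int] = (5, 15),
    detection_prop_abundance: bool = True,
    seed: int | np.random.SeedSequence = 0,
) -> list[FossilRecord]:
    """Sample fossil records from the occupied (step, cell) pairs of a
    known-truth simulation.

    Detection probability is proportional to abundance when flagged (else
    uniform over occupied pairs); recorded ages get Gaussian error with
    s.d. ``age_sd_years``; quality scores are integers uniform on
    ``quality_range`` (inclusive).
    """
    grid = truth.grid
    occ = truth.abundance > 0
    idx = np.flatnonzero(occ.ravel())
    if idx.size == 0:
        raise ValueError("truth simulation has no occupied (step, cell) pairs")
    rng = np.random.default_rng(_substream(seed, _STREAM_FOSSILS))
    if n_fossils == 0:
        return []
    if detection_prop_abundance:
        w = truth.abundance.ravel()[idx]
        p = w / w.sum()
    else:
        p = None
    chosen = rng.choice(idx, size=n_fossils, replace=True, p=p)
    times_bp = grid.times_bp
    lo_q, hi_q = quality_range
    records = []
    for flat in chosen:
        s, cell = divmod(int(flat), grid.n_cells)
        row, col = grid.cell_rowcol(cell)
        age = float(times_bp[s])
        if age_sd_years > 0:
            age += float(rng.normal(0.0, age_sd_years))
        x, y = grid.cell_xy_km(row, col)
        records.append(
            FossilRecord(
                cell_id=cell,
                age_bp=age,
                age_sd=age_sd_years,
                quality_score=int(rng.integers(lo_q, hi_q + 1)),
                kind="fossil",
                lon=x,
                lat=y,
            )
        )
    return records


@dataclass
class TruthBundle:
    """A known-truth dataset for parameter-recovery experiments."""

    params: DemographicParams
    grid: GridSpec
    landscape: LandscapeSeries
    human_field: HumanField
    truth: "_sepm.SimResult"
    fossils: list[FossilRecord]
    #: cached full-niche projected density map used as a fast path when only
    #: the niche volume varies across parametrizations
    raw_density: np.ndarray | None = None
    seed: int = 0


def make_truth_bundle(
    params: DemographicParams,
    grid: GridSpec,
    seed: int | np.random.SeedSequence = 0,
    n_fossils: int = 60,
    age_sd_years: float = 30.0,
    collapse_frac: float = 0.45,
    collapse_depth: float = 0.5,
    recovery_frac: float = 0.15,
    landuse_frac: float = 0.8,
    max_tries: int = 25,
) -> TruthBundle:
    """Simulate one known-truth world and sample fossils from it.

    The landscape's suitability is treated as the full-niche projected
    density; the truth run uses the density truncated at the bundle's true
    ``volume_fraction``. If the truth population goes extinct before 10% of
    the steps have elapsed, the bundle is regenerated with a fresh substream
    (at most ``max_tries`` attempts).
    """
    T = grid.n_steps
    base_seed = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for attempt in range(max_tries):
        sub = np.random.SeedSequence(base_seed.entropy, spawn_key=(100 + attempt,))
        landscape = gen_landscape(
            grid,
            collapse_step=int(collapse_frac * T),
            collapse_depth=collapse_depth,
            recovery_steps=max(int(recovery_frac * T), 1),
            landuse_onset_step=int(landuse_frac * T),
            seed=sub,
        )
        human_field = gen_human_field(grid, growth_rate=8.0 / T, seed=sub)
        raw_density = landscape.suitability.copy()
        suit_truth = _niche.truncate_density_map(raw_density, params.volume_fraction)
        land_truth = landscape.copy()
        land_truth.suitability = np.where(landscape.ice, 0.0, suit_truth)
        human_real = _humans.sample_human_surface(
            human_field, params.omega, _substream(sub, 901)
        )
        truth = _sepm.simulate(
            params, land_truth, human_real, seed=_substream(sub, _STREAM_TRUTH_SIM)
        )
        alive = truth.totals > 0
        if alive[: max(T // 10, 1)].all() and truth.totals[-1] > 0:
            fossils = gen_fossils(
                truth,
                n_fossils,
                age_sd_years=age_sd_years,
                seed=sub,
            )
            return TruthBundle(
                params=params,
                grid=grid,
                landscape=landscape,
                human_field=human_field,
                truth=truth,
                fossils=fossils,
                raw_density=raw_density,
                seed=int(base_seed.entropy),
            )
        warnings.warn(
            f"truth simulation collapsed early (attempt {attempt + 1}); regenerating"
        )
    raise RuntimeError(
        f"could not generate a persistent truth simulation in {max_tries} tries"
    )
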