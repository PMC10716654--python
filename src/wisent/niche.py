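"""Multi-temporal ecological niche as a Gaussian kernel-density hypervolume.

The niche is estimated in a four-dimensional environmental space (annual
precipitation, winter temperature, spring-summer evapotranspiration, and
land-use-adjusted forage biomass), from the intersection of quality-filtered
fossil occurrences with per-generation environmental layers. A product
Gaussian KDE with cross-validated bandwidths defines the full potential
niche; realized niches are generated by truncating the density at the level
enclosing a requested fraction of total density mass (niche volume) and
displacing the centroid (niche marginality). Suitability projections are
scaled to [0, 1] by the pooled 95th percentile across all projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fossils import FossilRecord, filter_fossils  # re-exported: niche-side filter
from .grid import GridSpec

ENV_AXES = (
    "annual_precipitation",
    "winter_temperature",
    "spring_summer_evapotranspiration",
    "adjusted_biomass",
)


def generational_means(
    values: np.ndarray,
    times_years: np.ndarray,
    window_years: float = 30.0,
    step_years: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Average finer-resolution layers to the generational step.

    Each output step is the mean of input slices whose time lies within the
    centred ``window_years`` window; windows truncate at the series edges.
    ``times_years`` may be BP (descending) or CE (ascending).

    Returns (out_values, out_times).
    """
    values = np.asarray(values, float)
    times = np.asarray(times_years, float)
    if values.shape[0] != times.shape[0]:
        raise ValueError("time axis length mismatch")
    if values.shape[0] == 0:
        raise ValueError("empty input series")
    t0, t1 = float(times[0]), float(times[-1])
    if values.shape[0] == 1:
        return values.copy(), times.copy()
    direction = 1.0 if t1 > t0 else -1.0
    n_out = int(abs(t1 - t0) // step_years) + 1
    out_times = t0 + direction * step_years * np.arange(n_out)
    half = window_years / 2.0
    out = np.empty((n_out,) + values.shape[1:])
    for i, tc in enumerate(out_times):
        sel = np.abs(times - tc) <= half + 1e-9
        if not np.any(sel):
            raise ValueError(f"empty averaging window at t={tc}")
        out[i] = values[sel].mean(axis=0)
    return out, out_times


def intersect_occurrences(
    records: list[FossilRecord],
    env_layers: np.ndarray,
    grid: GridSpec,
) -> np.ndarray:
    """Intersect occurrences with environmental layers in space-time.

    For each record, one environmental point is taken at its cell for every
    generational step within +-2 s.d. of its calibrated age (sightings with
    age_sd = 0 contribute their single deposition step). Duplicate
    (cell, step) bins arising from overlapping records are collapsed to one
    point. Records outside the grid span are skipped (count reported via
    the returned array's ``skipped`` attribute is not kept; callers needing
    it should pre-filter).

    Parameters
    ----------
    env_layers : (T, R, C, n_axes) array
        Per-step environmental state.

    Returns
    -------
    (n_points, n_axes) array of unique environmental points.
    """
    T, R, C, A = env_layers.shape
    if (T, R, C) != grid.shape:
        raise ValueError("environmental layers do not match the grid")
    seen: set[tuple[int, int]] = set()
    pts = []
    n_skipped = 0
    for rec in records:
        row, col = grid.cell_rowcol(rec.cell_id)
        if not (0 <= row < R and 0 <= col < C):
            n_skipped += 1
            continue
        lo_bp = rec.age_bp - 2 * rec.age_sd
        hi_bp = rec.age_bp + 2 * rec.age_sd
        if hi_bp < grid.t_end_bp or lo_bp > grid.t_start_bp:
            n_skipped += 1
            continue
        s_lo = grid.step_of_bp(hi_bp)  # older age -> smaller index
        s_hi = grid.step_of_bp(lo_bp)
        for s in range(s_lo, s_hi + 1):
            key = (s, rec.cell_id)
            if key in seen:
                continue
            seen.add(key)
            pts.append(env_layers[s, row, col])
    if n_skipped:
        import logging

        logging.getLogger(__name__).info(
            "intersect_occurrences: skipped %d record(s) outside the grid span",
            n_skipped,
        )
    if not pts:
        return np.empty((0, A))
    return np.asarray(pts)


def _product_gaussian_density(
    x: np.ndarray, points: np.ndarray, bandwidths: np.ndarray
) -> np.ndarray:
    """Mean of product-Gaussian kernels centred on ``points``, evaluated at x."""
    x = np.atleast_2d(x)
    # (n_eval, n_train, d)
    z = (x[:, None, :] - points[None, :, :]) / bandwidths
    norm = np.prod(bandwidths) * (2 * np.pi) ** (points.shape[1] / 2)
    return np.exp(-0.5 * (z**2).sum(axis=2)).sum(axis=1) / (len(points) * norm)


def silverman_bandwidths(points: np.ndarray) -> np.ndarray:
    """Silverman's rule-of-thumb per-axis bandwidths for a d-dim product KDE."""
    n, d = points.shape
    sd = points.std(axis=0, ddof=1)
    return sd * (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0))


def _lscv_score(points: np.ndarray, h_mult: float, base: np.ndarray, n_folds: int, seed: int) -> float:
    """K-fold least-squares CV score (integrated squared error estimate).

    score(h) = int f_hat^2 - 2 E_heldout[f_hat], with the integral term in
    closed form for a product-Gaussian KDE.
    """
    h = h_mult * base
    n, d = points.shape
    # closed-form integral of f_hat^2: mean over pairs of N(0, 2h^2) kernels
    z = (points[:, None, :] - points[None, :, :]) / (np.sqrt(2.0) * h)
    norm2 = np.prod(np.sqrt(2.0) * h) * (2 * np.pi) ** (d / 2)
    int_f2 = np.exp(-0.5 * (z**2).sum(axis=2)).sum() / (n * n * norm2)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    held = 0.0
    for f in folds:
        mask = np.ones(n, bool)
        mask[f] = False
        train = points[mask]
        held += _product_gaussian_density(points[f], train, h).sum()
    return float(int_f2 - 2.0 * held / n)


@dataclass
class NicheModel:
    """A (possibly subsampled) Gaussian hypervolume niche.

    Suitability of an environmental point is its kernel density under the
    training cloud, shifted by the marginality displacement and zeroed below
    ``density_threshold``; projections scale it to [0, 1].
    """

    points: np.ndarray                  # (n, d) standardized training points
    bandwidths: np.ndarray              # (d,) per-axis
    axis_means: np.ndarray              # (d,) standardization offsets
    axis_sds: np.ndarray                # (d,) standardization scales
    volume_fraction: float = 1.0
    marginality: float = 0.0
    density_threshold: float = 0.0
    centroid_shift: np.ndarray | None = None  # (d,) in standardized units

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        self.bandwidths = np.asarray(self.bandwidths, float)
        if np.any(self.bandwidths <= 0):
            raise ValueError("bandwidths must be positive")
        if not 0.0 < self.volume_fraction <= 1.0:
            raise ValueError("volume_fraction must lie in (0, 1]")
        if self.centroid_shift is None:
            self.centroid_shift = np.zeros(self.points.shape[1])

    @property
    def n_axes(self) -> int:
        return self.points.shape[1]

    def standardize(self, env: np.ndarray) -> np.ndarray:
        return (np.asarray(env, float) - self.axis_means) / self.axis_sds

    def density(
        self, env: np.ndarray, standardized: bool = False, apply_threshold: bool = True
    ) -> np.ndarray:
        """Raw (shifted, optionally truncated) kernel density of points."""
        x = np.atleast_2d(np.asarray(env, float))
        if x.shape[1] != self.n_axes:
            raise ValueError(
                f"expected {self.n_axes} environmental axes, got {x.shape[1]}"
            )
        z = x if standardized else self.standardize(x)
        d = _product_gaussian_density(z - self.centroid_shift, self.points, self.bandwidths)
        if apply_threshold and self.density_threshold > 0:
            d = np.where(d >= self.density_threshold, d, 0.0)
        return d

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw standardized points from the (full, unshifted) KDE mixture."""
        idx = rng.integers(0, len(self.points), size=n)
        return self.points[idx] + rng.standard_normal((n, self.n_axes)) * self.bandwidths


def fit_hypervolume(
    env_points: np.ndarray,
    n_folds: int = 5,
    bandwidth_grid: np.ndarray | None = None,
    seed: int = 0,
) -> NicheModel:
    """Fit the full potential niche: a product-Gaussian KDE.

    Axes are standardized to zero mean and unit variance over the training
    points. Per-axis bandwidths are a common multiplier on the per-axis
    (unit) s.d., tuned by K-fold least-squares cross-validation — the
    multiplier minimizing the estimated integrated squared error over a
    log-spaced grid.
    """
    env_points = np.asarray(env_points, float)
    if env_points.ndim != 2:
        raise ValueError("env_points must be 2-D (n_points, n_axes)")
    n, d = env_points.shape
    if n < 10:
        raise ValueError(f"need at least 10 environmental points, got {n}")
    if np.any(~np.isfinite(env_points)):
        raise ValueError("environmental points contain non-finite values")
    sds = env_points.std(axis=0, ddof=1)
    for j, s in enumerate(sds):
        if s == 0:
            raise ValueError(
                f"degenerate environmental axis {j}"
                + (f" ({ENV_AXES[j]})" if j < len(ENV_AXES) else "")
                + ": zero variance"
            )
    means = env_points.mean(axis=0)
    z = (env_points - means) / sds

    base = silverman_bandwidths(z)
    if bandwidth_grid is None:
        bandwidth_grid = np.logspace(np.log10(0.25), np.log10(4.0), 13)
    scores = [
        _lscv_score(z, float(m), base, n_folds, seed) for m in bandwidth_grid
    ]
    best = float(bandwidth_grid[int(np.argmin(scores))])
    return NicheModel(
        points=z,
        bandwidths=best * base,
        axis_means=means,
        axis_sds=sds,
    )


def subsample_niche(
    full: NicheModel,
    volume_fraction: float,
    marginality: float,
    seed: int | np.random.SeedSequence,
    n_mc: int = 20_000,
) -> NicheModel:
    """Generate one plausible realized niche from the full hypervolume.

    The density is truncated at the level enclosing ``volume_fraction`` of
    the total density mass (threshold estimated by Monte-Carlo sampling of
    the KDE itself), and the niche centroid is displaced by ``marginality``
    per-axis standard deviations along a seeded random unit direction.
    """
    if not 0.0 < volume_fraction <= 1.0:
        raise ValueError("volume_fraction must lie in (0, 1]")
    if marginality < 0:
        raise ValueError("marginality must be nonnegative")
    rng = np.random.default_rng(seed)

    if volume_fraction < 1.0:
        samples = full.sample(n_mc, rng)
        dens = _product_gaussian_density(samples, full.points, full.bandwidths)
        threshold = float(np.quantile(dens, 1.0 - volume_fraction))
    else:
        threshold = 0.0

    if marginality > 0:
        u = rng.standard_normal(full.n_axes)
        u /= np.linalg.norm(u)
        shift = marginality * u  # axes are standardized: per-axis s.d. = 1
    else:
        shift = np.zeros(full.n_axes)

    return NicheModel(
        points=full.points,
        bandwidths=full.bandwidths,
        axis_means=full.axis_means,
        axis_sds=full.axis_sds,
        volume_fraction=volume_fraction,
        marginality=marginality,
        density_threshold=threshold,
        centroid_shift=shift,
    )


def scale_suitability(raw_density: np.ndarray, percentile: float = 95.0) -> np.ndarray:
    """Scale raw densities to [0, 1] by the pooled percentile across all
    steps and cells; values above the percentile clip to 1."""
    raw_density = np.asarray(raw_density, float)
    p = float(np.percentile(raw_density, percentile))
    if p <= 0:
        return np.zeros_like(raw_density)
    return np.clip(raw_density / p, 0.0, 1.0)


def project_suitability(
    niche: NicheModel,
    env_layers: np.ndarray,
    percentile: float = 95.0,
) -> np.ndarray:
    """Project the niche into geographic space at every generational step.

    Kernel density is evaluated at each (step, cell) environmental point and
    the pooled distribution over all steps and cells is scaled by its 95th
    percentile (clipped at 1), so suitability is comparable across time. The
    scale is computed on the untruncated density, so shrinking the niche
    volume only removes cells and never raises the suitability of survivors.
    """
    env_layers = np.asarray(env_layers, float)
    T, R, C, A = env_layers.shape
    if A != niche.n_axes:
        raise ValueError(f"expected {niche.n_axes} axes, got {A}")
    flat = env_layers.reshape(-1, A)
    dens = np.empty(flat.shape[0])
    chunk = 4096
    for i in range(0, flat.shape[0], chunk):
        dens[i : i + chunk] = niche.density(flat[i : i + chunk], apply_threshold=False)
    out = scale_suitability(dens, percentile)
    if niche.density_threshold > 0:
        out = np.where(dens >= niche.density_threshold, out, 0.0)
    return out.reshape(T, R, C)


def truncate_density_map(
    raw_density: np.ndarray, volume_fraction: float, percentile: float = 95.0
) -> np.ndarray:
    """Volume-fraction truncation applied directly to a projected density map.

    Fast path for calibration runs where only the niche volume varies: the
    cached full-niche density map is thresholded at the level enclosing
    ``volume_fraction`` of its total density mass (cells weighted by their
    own density, mirroring the hypervolume construction), then rescaled by
    the pooled 95th percentile.
    """
    if not 0.0 < volume_fraction <= 1.0:
        raise ValueError("volume_fraction must lie in (0, 1]")
    d = np.asarray(raw_density, float)
    out = scale_suitability(d, percentile)
    if volume_fraction < 1.0:
        flat = np.sort(d.ravel())[::-1]
        mass = np.cumsum(flat)
        total = mass[-1]
        if total > 0:
            k = int(np.searchsorted(mass, volume_fraction * total))
            thr = flat[min(k, flat.size - 1)]
            out = np.where(d >= thr, out, 0.0)
    return out
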