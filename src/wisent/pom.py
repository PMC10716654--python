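"""Pattern-oriented validation with approximate Bayesian computation.

Each simulated parametrization is summarized by a multivariate target:
(i) the fraction of fossil occurrences correctly matched in space-time,
(ii) the persistence penalty (years of premature extirpation summed over
named refugia relative to 1850 CE) and (iii) the absolute difference between
the simulated and expected number of refugial populations at 1850 CE.
ABC rejection keeps the closest fraction of parametrizations; priors are
iteratively refined around the accepted sets; convergence is judged by the
overlap of successive posterior samples; the accepted ensemble is averaged
with inverse-distance weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import qmc

from .fossils import FossilRecord
from .grid import GridSpec, ce_to_bp, bp_to_ce
from .params import DemographicParams, PARAM_NAMES
from .sepm import SimResult

SUMMARY_NAMES = ("occurrence_match", "persistence_penalty", "refugia_diff")

#: 8-connectivity structuring element for refugium patch labelling
_MOORE = np.ones((3, 3), dtype=int)


@dataclass
class TargetSpec:
    """The multivariate validation target."""

    fossils: list[FossilRecord]
    refugium_cells: dict[str, list[int]]
    expected_refugia_count: int = 2
    persistence_end_ce: float = 1850.0

    def __post_init__(self) -> None:
        for name, cells in self.refugium_cells.items():
            if len(cells) == 0:
                raise ValueError(f"refugium set {name!r} is empty")

    @property
    def summary_target(self) -> np.ndarray:
        """A perfect match: all fossils matched, no penalty, expected count."""
        return np.array([1.0, 0.0, 0.0])


def sample_priors_lhs(
    ranges: dict[str, tuple[float, float]],
    n: int,
    seed: int | np.random.SeedSequence,
    base: DemographicParams | None = None,
) -> list[DemographicParams]:
    """Latin hypercube sample of the parameter hypercube.

    Each 1-D margin is stratified into n equal bins with exactly one sample
    per bin. Parameters not named in ``ranges`` keep the values of ``base``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    names = [k for k in PARAM_NAMES if k in ranges]
    unknown = set(ranges) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
    base = base or DemographicParams()
    if isinstance(seed, np.random.SeedSequence):
        seed = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    u = sampler.random(n)
    out = []
    base_d = base.to_dict()
    for i in range(n):
        d = dict(base_d)
        for j, name in enumerate(names):
            lo, hi = ranges[name]
            if lo > hi:
                raise ValueError(f"prior for {name} has lo > hi")
            d[name] = lo + (hi - lo) * u[i, j]
        out.append(DemographicParams(**d))
    return out


def occurrence_match(
    sim: SimResult, fossils: list[FossilRecord], grid: GridSpec | None = None
) -> float:
    """Fraction of fossils matched by the simulation in space-time.

    A fossil matches if abundance is positive in its cell or any of its
    eight Moore neighbours at any generational step within +-2 s.d. of its
    calibrated age; historical sightings (age_sd = 0) use only their
    deposition step.
    """
    if not fossils:
        raise ValueError("occurrence_match requires at least one fossil")
    grid = grid or sim.grid
    occ = sim.abundance > 0
    # dilate spatially so a cell's entry covers its Moore neighbourhood
    occ_dil = ndimage.binary_dilation(occ, structure=_MOORE[None, :, :])
    matched = 0
    for rec in fossils:
        row, col = grid.cell_rowcol(rec.cell_id)
        s_lo = grid.step_of_bp(rec.age_bp + 2 * rec.age_sd)
        s_hi = grid.step_of_bp(rec.age_bp - 2 * rec.age_sd)
        if occ_dil[s_lo : s_hi + 1, row, col].any():
            matched += 1
    return matched / len(fossils)


def persistence_penalty(
    sim: SimResult,
    refugium_cells: dict[str, list[int]],
    end_year_ce: float = 1850.0,
) -> float:
    """Years of premature refugial extirpation, summed over refugia.

    Per refugium: max(0, end_year - CE year of the last step at which any
    cell of the set was occupied); a refugium never occupied counts from the
    simulation start.
    """
    grid = sim.grid
    occ = sim.abundance > 0
    times_ce = grid.times_ce
    total = 0.0
    for name, cells in refugium_cells.items():
        rows, cols = zip(*(grid.cell_rowcol(c) for c in cells))
        series = occ[:, list(rows), list(cols)].any(axis=1)
        if series.any():
            last_ce = float(times_ce[np.flatnonzero(series)[-1]])
        else:
            last_ce = float(times_ce[0])
        total += max(0.0, end_year_ce - last_ce)
    return total


def refugia_diff(
    sim: SimResult, expected: int = 2, at_year_ce: float = 1850.0
) -> int:
    """|observed - expected| count of refugial populations at a calendar year.

    Populations are spatially contiguous occupied patches (8-connectivity)
    at the generational step containing the target year.
    """
    step = sim.grid.step_of_ce(at_year_ce)
    occ = sim.abundance[step] > 0
    _, n = ndimage.label(occ, structure=_MOORE)
    return abs(int(n) - int(expected))


def summarize(sim: SimResult, target: TargetSpec) -> np.ndarray:
    """The three-component summary vector of one simulation."""
    return np.array(
        [
            occurrence_match(sim, target.fossils),
            persistence_penalty(sim, target.refugium_cells, target.persistence_end_ce),
            refugia_diff(sim, target.expected_refugia_count, target.persistence_end_ce),
        ]
    )


def summary_scales(summaries: np.ndarray) -> np.ndarray:
    """Across-simulation scale per summary component.

    Median absolute deviation (scaled to the normal) with a fallback to the
    standard deviation, then to 1, so a fraction, a year count and a patch
    count mix on comparable scales.
    """
    s = np.asarray(summaries, float)
    med = np.median(s, axis=0)
    mad = 1.4826 * np.median(np.abs(s - med), axis=0)
    sd = s.std(axis=0)
    scales = np.where(mad > 0, mad, np.where(sd > 0, sd, 1.0))
    return scales


def abc_distance(
    summary: np.ndarray, target: np.ndarray, scales: np.ndarray
) -> float:
    """Euclidean distance between scaled summary vectors."""
    summary = np.asarray(summary, float)
    target = np.asarray(target, float)
    scales = np.asarray(scales, float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    return float(np.sqrt((((summary - target) / scales) ** 2).sum()))


def abc_reject(
    distances: np.ndarray, tolerance_fraction: float = 0.0025
) -> np.ndarray:
    """Indices of the accepted (closest) parametrizations.

    Keeps the ceil(n * tolerance) smallest distances; ties break toward the
    lower index (stable order).
    """
    if tolerance_fraction <= 0:
        raise ValueError("tolerance_fraction must be positive")
    d = np.asarray(distances, float)
    n = d.shape[0]
    if n == 0:
        raise ValueError("no distances supplied")
    m = min(int(math.ceil(n * tolerance_fraction)), n)
    order = np.argsort(d, kind="stable")
    return np.sort(order[:m])


def refine_priors(
    accepted: np.ndarray | list[DemographicParams],
    names: list[str],
    original: dict[str, tuple[float, float]],
    expansion: float = 1.1,
) -> dict[str, tuple[float, float]]:
    """Informed uniform priors from an accepted set.

    Per parameter: the accepted min-max range expanded by ``expansion``
    about its midpoint, intersected with the original bounds.
    """
    if isinstance(accepted, list):
        accepted = np.array([[p.to_dict()[k] for k in names] for p in accepted])
    accepted = np.asarray(accepted, float)
    if accepted.shape[0] < 2:
        raise ValueError("need at least 2 accepted parametrizations")
    out = {}
    for j, name in enumerate(names):
        lo, hi = accepted[:, j].min(), accepted[:, j].max()
        mid = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo) * expansion
        olo, ohi = original[name]
        out[name] = (max(mid - half, olo), min(mid + half, ohi))
    return out


def overlap_coefficient(a: np.ndarray, b: np.ndarray, n_bins: int = 10) -> float:
    """Histogram overlap of two samples on shared bins over the union range."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(np.minimum(pa / pa.sum(), pb / pb.sum()).sum())


def convergence_check(
    rounds: list[np.ndarray],
    names: list[str] | None = None,
    threshold: float = 0.8,
    n_bins: int = 10,
) -> tuple[bool, dict[str, float]]:
    """Posterior-convergence diagnostic between the last two rounds.

    Per-parameter overlap coefficient between the accepted samples of the
    two most recent rounds; converged when the minimum overlap reaches the
    threshold.
    """
    if len(rounds) < 2:
        raise ValueError("need at least two rounds")
    prev, last = np.asarray(rounds[-2], float), np.asarray(rounds[-1], float)
    if prev.ndim == 1:
        prev = prev[:, None]
        last = last[:, None]
    k = prev.shape[1]
    names = names or [f"p{j}" for j in range(k)]
    stats = {
        names[j]: overlap_coefficient(prev[:, j], last[:, j], n_bins)
        for j in range(k)
    }
    return min(stats.values()) >= threshold, stats


def goodness_of_fit(
    accepted_summaries: np.ndarray,
    target: np.ndarray,
    scales: np.ndarray | None = None,
    n_reps: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Posterior-predictive goodness-of-fit p-value.

    The null distribution is built from leave-one-out pseudo-observations:
    each draw takes one accepted summary as pseudo-observed and measures its
    scaled distance to the centroid of the remainder. p is the fraction of
    null distances at least as large as the distance of the real target to
    the centroid of all accepted summaries; p > 0.05 indicates the target is
    typical of the accepted cloud (a good fit).
    """
    s = np.asarray(accepted_summaries, float)
    m = s.shape[0]
    if m < 2:
        raise ValueError("need at least 2 accepted summaries")
    if scales is None:
        scales = summary_scales(s)
    rng = np.random.default_rng(seed)
    obs = abc_distance(np.asarray(target, float), s.mean(axis=0), scales)
    total = s.sum(axis=0)
    idx = rng.integers(0, m, size=n_reps)
    null = np.empty(n_reps)
    for r, i in enumerate(idx):
        rest_mean = (total - s[i]) / (m - 1)
        null[r] = abc_distance(s[i], rest_mean, scales)
    return float(np.mean(null >= obs))


@dataclass
class EnsembleResult:
    """Inverse-distance-weighted ensemble of accepted simulations."""

    grid: GridSpec
    weights: np.ndarray              # (n_models,) summing to 1
    mean_abundance: np.ndarray       # (T, R, C) weighted
    totals: np.ndarray               # (T,)
    occupancy_fraction: np.ndarray   # (T, R, C) unweighted model agreement
    extirpation_step: np.ndarray     # (R, C) from the weighted mean map


def ensemble_weights(distances: np.ndarray) -> np.ndarray:
    """Normalized inverse-distance weights; zero distances get a tiny floor."""
    d = np.asarray(distances, float).copy()
    if d.size == 0:
        raise ValueError("no distances supplied")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    pos = d[d > 0]
    eps = (pos.min() * 1e-6) if pos.size else 1.0
    d[d == 0] = eps
    w = 1.0 / d
    return w / w.sum()


def ensemble_average(
    results: list[SimResult], distances: np.ndarray
) -> EnsembleResult:
    """Inverse-distance weighted ensemble mean of accepted simulations."""
    if not results:
        raise ValueError("no results supplied")
    if len(results) != len(distances):
        raise ValueError("results and distances length mismatch")
    w = ensemble_weights(distances)
    mean_ab = np.zeros_like(results[0].abundance)
    occ_frac = np.zeros_like(results[0].abundance)
    for wi, r in zip(w, results):
        mean_ab += wi * r.abundance
        occ_frac += (r.abundance > 0).astype(float)
    occ_frac /= len(results)
    from .sepm import extirpation_steps

    return EnsembleResult(
        grid=results[0].grid,
        weights=w,
        mean_abundance=mean_ab,
        totals=mean_ab.sum(axis=(1, 2)),
        occupancy_fraction=occ_frac,
        extirpation_step=extirpation_steps(mean_ab),
    )


@dataclass
class TrendReport:
    """Comparison of ensemble totals against an external relative series."""

    correlation: float
    inside_fraction: float
    inside_all: bool
    flagged_low_correlation: bool


def compare_trend(
    ensemble_totals: list[np.ndarray] | np.ndarray,
    external: np.ndarray,
    min_correlation: float = 0.3,
) -> TrendReport:
    """Compare relative population change against an independent series.

    Both the ensemble members and the external series (e.g. an ancient-DNA
    N_e trend) are normalized to their own maxima; the report gives the
    correlation of per-step changes between the external series and the
    ensemble mean, and whether the external series lies within the ensemble
    min-max envelope at every step.
    """
    members = np.atleast_2d(np.asarray(ensemble_totals, float))
    external = np.asarray(external, float)
    if members.shape[1] != external.shape[0]:
        raise ValueError("series lengths do not overlap")
    norm_members = members / members.max(axis=1, keepdims=True)
    norm_ext = external / external.max()
    env_lo = norm_members.min(axis=0)
    env_hi = norm_members.max(axis=0)
    inside = (norm_ext >= env_lo - 1e-12) & (norm_ext <= env_hi + 1e-12)
    mean_member = norm_members.mean(axis=0)
    d_ext = np.diff(norm_ext)
    d_mean = np.diff(mean_member)
    if d_ext.std() == 0 or d_mean.std() == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(d_ext, d_mean)[0, 1])
    return TrendReport(
        correlation=corr,
        inside_fraction=float(inside.mean()),
        inside_all=bool(inside.all()),
        flagged_low_correlation=corr < min_correlation,
    )
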