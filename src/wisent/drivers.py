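"""Drivers of abundance: centennial binning and penalized smooth regression.

Ensemble abundance series are aggregated to 100-year bins (removing decadal
variation and temporal autocorrelation) together with three covariates
averaged over each model's occupied cells: mean annual temperature (climate),
relative human abundance (hunting pressure) and the human-driven fractional
reduction of vegetation biomass (land use change). Abundance is regressed on
penalized B-spline smooths of the covariates with a model-ID random effect;
a double penalty (wiggliness plus null space) lets uninformative covariates
shrink to zero. Model comparison uses a chi-squared test on twice the
difference in the maximized (profile) likelihood between fits with and
without interaction terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, stats

from .landscape import HumanField, LandscapeSeries
from .sepm import SimResult

COVARIATES = ("mean_temperature", "mean_human_abundance", "mean_landuse_change")

EPOCHS = {
    "pleistocene": (21_000.0, 11_700.0),
    "early_mid_holocene": (11_700.0, 4_250.0),
    "late_holocene": (4_250.0, 450.0),
}


def epoch_of(bp: float) -> str:
    """Epoch label of a time in years BP; boundaries belong to the older
    epoch (the transition instant closes it)."""
    if bp >= 11_700:
        return "pleistocene"
    if bp >= 4_250:
        return "early_mid_holocene"
    if bp >= 450:
        return "late_holocene"
    return "post"


def bin_drivers(
    results: list[SimResult],
    landscape: LandscapeSeries,
    human: HumanField,
    bin_years: float = 100.0,
) -> pd.DataFrame:
    """Aggregate per-generation series to centennial bins per ensemble member.

    Covariates are averaged over the cells occupied by that member in that
    generation; generations with no occupied cell contribute nothing to
    their bin. Land-use change is the fractional biomass reduction
    (raw - adjusted) / raw.
    """
    grid = landscape.grid
    if landscape.temperature is None:
        raise ValueError("landscape has no temperature layer")
    temp = landscape.temperature
    hum = human.mean
    if landscape.biomass_raw is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            lu = np.where(
                landscape.biomass_raw > 0,
                (landscape.biomass_raw - landscape.biomass_adjusted)
                / np.where(landscape.biomass_raw > 0, landscape.biomass_raw, 1.0),
                0.0,
            )
    else:
        lu = np.zeros(grid.shape)

    times = grid.times_bp
    steps_per_bin = max(int(round(bin_years / grid.step_years)), 1)
    rows = []
    for mid, sim in enumerate(results):
        occ = sim.abundance > 0
        totals = sim.totals
        with np.errstate(invalid="ignore"):
            n_occ = occ.sum(axis=(1, 2)).astype(float)
            mt = np.where(n_occ > 0, (temp * occ).sum(axis=(1, 2)) / np.maximum(n_occ, 1), np.nan)
            mh = np.where(n_occ > 0, (hum * occ).sum(axis=(1, 2)) / np.maximum(n_occ, 1), np.nan)
            ml = np.where(n_occ > 0, (lu * occ).sum(axis=(1, 2)) / np.maximum(n_occ, 1), np.nan)
        for b0 in range(0, grid.n_steps - steps_per_bin + 1, steps_per_bin):
            sl = slice(b0, b0 + steps_per_bin)
            if np.all(np.isnan(mt[sl])):
                continue
            bin_start = float(times[b0])
            rows.append(
                {
                    "model_id": mid,
                    "bin_start_bp": bin_start,
                    "epoch": epoch_of(bin_start - bin_years / 2.0),
                    "mean_abundance": float(np.mean(totals[sl])),
                    "mean_temperature": float(np.nanmean(mt[sl])),
                    "mean_human_abundance": float(np.nanmean(mh[sl])),
                    "mean_landuse_change": float(np.nanmean(ml[sl])),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# penalized additive Gaussian model (B-spline smooths, double penalty)
# ---------------------------------------------------------------------------


def _bspline_basis(x: np.ndarray, n_basis: int, xmin: float, xmax: float) -> np.ndarray:
    """Cubic B-spline basis with evenly spaced interior knots."""
    k = 3
    n_interior = max(n_basis - k - 1, 0)
    if xmax <= xmin:
        raise ValueError("degenerate covariate range")
    inner = np.linspace(xmin, xmax, n_interior + 2)[1:-1]
    t = np.concatenate([[xmin] * (k + 1), inner, [xmax] * (k + 1)])
    xc = np.clip(x, xmin, xmax)
    return interpolate.BSpline.design_matrix(xc, t, k).toarray()


@dataclass
class _SmoothTerm:
    name: str
    basis: np.ndarray          # (n, m) centered
    col_means: np.ndarray
    penalties: list[np.ndarray]
    xmin: float
    xmax: float
    n_basis: int


def _make_smooth(name: str, x: np.ndarray, n_basis: int) -> _SmoothTerm:
    if x.max() - x.min() <= 1e-12 * (abs(x).max() + 1.0):
        raise ValueError(f"rank-deficient design: covariate {name!r} is constant")
    xmin, xmax = float(x.min()), float(x.max())
    B = _bspline_basis(x, n_basis, xmin, xmax)
    mu = B.mean(axis=0)
    Bc = B - mu
    m = B.shape[1]
    D = np.diff(np.eye(m), n=2, axis=0)
    S_w = D.T @ D
    # double penalty: null space of the wiggliness penalty gets its own
    # shrinkage so whole terms can be annihilated
    evals, evecs = np.linalg.eigh(S_w)
    null = evecs[:, evals < 1e-10 * evals.max()]
    S_n = null @ null.T
    return _SmoothTerm(name, Bc, mu, [S_w, S_n], xmin, xmax, n_basis)


@dataclass
class DriverModelFit:
    """A fitted penalized additive model of binned abundance."""

    terms: list[_SmoothTerm]
    coef: np.ndarray
    intercept: float
    lambdas: np.ndarray
    edf: float
    rss: float
    n: int
    llf: float                      # maximized Gaussian profile log-likelihood
    with_interactions: bool
    term_slices: dict[str, slice]
    response_sd: float
    y_checksum: float
    interaction_rank: int = 0

    @property
    def ml_criterion(self) -> float:
        """Minimized -2 log-likelihood (the quantity compared across fits)."""
        return -2.0 * self.llf

    def partial_effect(self, name: str, x: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Centered partial-effect curve of one smooth term."""
        term = next(t for t in self.terms if t.name == name)
        if x is None:
            x = np.linspace(term.xmin, term.xmax, 100)
        B = _bspline_basis(np.asarray(x, float), term.n_basis, term.xmin, term.xmax)
        eff = (B - term.col_means) @ self.coef[self.term_slices[name]]
        return np.asarray(x, float), eff


def _interaction_columns(xs: dict[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """Fixed-df pairwise interaction block: products of centered linear and
    quadratic covariate transforms (4 columns per pair, 12 for 3 covariates)."""
    std = {}
    for name, x in xs.items():
        z = (x - x.mean()) / x.std()
        std[name] = (z, z**2 - (z**2).mean())
    cols, names = [], []
    keys = list(xs)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a1, a2 = std[keys[i]]
            b1, b2 = std[keys[j]]
            for u, un in ((a1, "l"), (a2, "q")):
                for v, vn in ((b1, "l"), (b2, "q")):
                    c = u * v
                    cols.append(c - c.mean())
                    names.append(f"{keys[i]}:{keys[j]}:{un}{vn}")
    return np.column_stack(cols), names


_LAMBDA_GRID = np.logspace(-3, 5, 9)


def fit_driver_model(
    binned: pd.DataFrame,
    epoch: str | None = None,
    with_interactions: bool = False,
    n_basis: int = 8,
    lambdas: np.ndarray | None = None,
    min_bins: int = 30,
) -> DriverModelFit:
    """Fit the penalized additive driver model on centennial bins.

    Abundance (standardized) is regressed on cubic B-spline smooths of the
    three covariates plus a model-ID random effect (ridge-shrunk dummies).
    Per-penalty smoothing parameters are chosen by GCV over a log-spaced
    grid (coordinate descent) unless ``lambdas`` is supplied — model
    comparisons reuse the null fit's smoothing parameters so the
    interaction block is the only difference between nested fits.
    """
    df = binned if epoch is None else binned[binned["epoch"] == epoch]
    df = df.dropna(subset=["mean_abundance", *COVARIATES])
    n = len(df)
    if n < min_bins:
        raise ValueError(f"need at least {min_bins} bins, got {n}")

    y_raw = df["mean_abundance"].to_numpy(float)
    y_sd = y_raw.std() or 1.0
    y = (y_raw - y_raw.mean()) / y_sd

    terms: list[_SmoothTerm] = []
    blocks: list[np.ndarray] = []
    penalties: list[tuple[slice, np.ndarray]] = []
    term_slices: dict[str, slice] = {}
    pos = 0
    for name in COVARIATES:
        t = _make_smooth(name, df[name].to_numpy(float), n_basis)
        sl = slice(pos, pos + t.basis.shape[1])
        term_slices[name] = sl
        for S in t.penalties:
            penalties.append((sl, S))
        blocks.append(t.basis)
        terms.append(t)
        pos = sl.stop

    # model-ID random effect: centered dummies with a ridge penalty
    ids = pd.Categorical(df["model_id"])
    Z = pd.get_dummies(ids).to_numpy(float)
    Z = Z - Z.mean(axis=0)
    sl = slice(pos, pos + Z.shape[1])
    term_slices["model_id"] = sl
    penalties.append((sl, np.eye(Z.shape[1])))
    blocks.append(Z)
    pos = sl.stop

    interaction_rank = 0
    if with_interactions:
        X_int, _ = _interaction_columns(
            {name: df[name].to_numpy(float) for name in COVARIATES}
        )
        sl = slice(pos, pos + X_int.shape[1])
        term_slices["interactions"] = sl
        blocks.append(X_int)  # unpenalized fixed-df block
        interaction_rank = X_int.shape[1]
        pos = sl.stop

    X = np.column_stack(blocks)
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y

    def solve(lam: np.ndarray) -> tuple[np.ndarray, float, float]:
        A = XtX.copy()
        for (slc, S), l in zip(penalties, lam):
            A[slc, slc] += l * S
        try:
            c, low = linalg.cho_factor(A + 1e-10 * np.eye(p))
            beta = linalg.cho_solve((c, low), Xty)
            Ainv_Xt = linalg.cho_solve((c, low), X.T)
        except linalg.LinAlgError as exc:
            raise ValueError(f"rank-deficient design: {exc}") from exc
        fitted = X @ beta
        rss = float(((y - fitted) ** 2).sum())
        edf = float(np.einsum("ij,ji->", X, Ainv_Xt))
        return beta, rss, edf

    n_pen = len(penalties)
    if lambdas is None:
        lam = np.ones(n_pen)
        for _ in range(2):  # coordinate-descent passes
            for k in range(n_pen):
                best, best_gcv = lam[k], np.inf
                for cand in _LAMBDA_GRID:
                    lam[k] = cand
                    _, rss, edf = solve(lam)
                    denom = max(n - edf, 1e-6)
                    gcv = n * rss / denom**2
                    if gcv < best_gcv:
                        best_gcv, best = gcv, cand
                lam[k] = best
    else:
        lam = np.asarray(lambdas, float)
        if lam.shape[0] != n_pen:
            raise ValueError("lambdas length does not match the penalty count")

    beta, rss, edf = solve(lam)
    llf = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return DriverModelFit(
        terms=terms,
        coef=beta,
        intercept=float(y_raw.mean()),
        lambdas=lam,
        edf=edf,
        rss=rss,
        n=n,
        llf=float(llf),
        with_interactions=with_interactions,
        term_slices=term_slices,
        response_sd=float(y_sd),
        y_checksum=float(y.sum()),
        interaction_rank=interaction_rank,
    )


def compare_models(
    fit_null: DriverModelFit, fit_interaction: DriverModelFit
) -> tuple[float, float, float]:
    """Chi-squared comparison of nested fits with and without interactions.

    statistic = 2 |ML_null - ML_interaction| (twice the difference in the
    maximized profile likelihood); df = difference in effective parameters;
    p from the chi-squared tail.
    """
    if fit_null.n != fit_interaction.n or fit_null.y_checksum != fit_interaction.y_checksum:
        raise ValueError("fits are not on the same data")
    if fit_null.with_interactions or not fit_interaction.with_interactions:
        raise ValueError("fits are not nested (null must lack interactions)")
    stat = 2.0 * abs(fit_interaction.llf - fit_null.llf)
    df = fit_interaction.edf - fit_null.edf
    if df <= 0:
        return stat, df, 1.0
    p = float(stats.chi2.sf(stat, df))
    return stat, float(df), p
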