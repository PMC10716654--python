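"""Relative human abundance surfaces.

Effective-population-size (N_e) grids from an upstream human demographic
model are used as a proxy for relative human abundance: scaled to [0, 1] by
the pooled 95th percentile, linearly interpolated from the 25-year native
step to the 10-year generational step, and sampled within the +-1 s.d.
envelope from a lognormal whose window centre (omega) is itself a calibrated
model parameter.
"""

from __future__ import annotations

import numpy as np

from .landscape import HumanField


def scale_ne(
    raw_mean: np.ndarray,
    raw_sd: np.ndarray | None = None,
    times_bp: np.ndarray | None = None,
    native_step_years: float = 25.0,
) -> HumanField:
    """Scale raw N_e to [0, 1] using the pooled 95th percentile as ceiling.

    Values above the 95th percentile clip to 1; the s.d. layer is scaled by
    the same factor (clipping does not apply to sd). An all-zero field stays
    all zero.
    """
    raw_mean = np.asarray(raw_mean, float)
    if np.any(raw_mean < 0):
        raise ValueError("raw N_e must be nonnegative")
    if raw_sd is None:
        raw_sd = np.zeros_like(raw_mean)
    raw_sd = np.asarray(raw_sd, float)
    if times_bp is None:
        times_bp = np.arange(raw_mean.shape[0], dtype=float)[::-1]
    p95 = float(np.percentile(raw_mean, 95))
    if p95 <= 0:
        mean = np.zeros_like(raw_mean)
        sd = np.zeros_like(raw_sd)
    else:
        mean = np.clip(raw_mean / p95, 0.0, 1.0)
        sd = raw_sd / p95
    return HumanField(
        mean=mean, sd=sd, times_bp=np.asarray(times_bp, float),
        native_step_years=native_step_years,
    )


def interp_steps(field: HumanField, target_step_years: float = 10.0) -> HumanField:
    """Linearly interpolate the field in time to a finer step.

    Endpoints are preserved; a single-slice input extends as a constant.
    """
    times = field.times_bp
    if field.n_steps == 1:
        return HumanField(
            mean=field.mean.copy(), sd=field.sd.copy(),
            times_bp=times.copy(), native_step_years=target_step_years,
        )
    if field.native_step_years <= target_step_years:
        raise ValueError("target step must be finer than the native step")
    t_start, t_end = float(times[0]), float(times[-1])
    n_new = int(round((t_start - t_end) / target_step_years)) + 1
    new_times = t_start - target_step_years * np.arange(n_new)
    # np.interp needs ascending x; BP axes descend
    xp = times[::-1]
    T, R, C = field.mean.shape
    flat_mean = field.mean.reshape(T, -1)[::-1]
    flat_sd = field.sd.reshape(T, -1)[::-1]
    x_new = new_times[::-1]
    out_mean = np.empty((n_new, R * C))
    out_sd = np.empty((n_new, R * C))
    for j in range(R * C):
        out_mean[:, j] = np.interp(x_new, xp, flat_mean[:, j])
        out_sd[:, j] = np.interp(x_new, xp, flat_sd[:, j])
    return HumanField(
        mean=out_mean[::-1].reshape(n_new, R, C),
        sd=out_sd[::-1].reshape(n_new, R, C),
        times_bp=new_times,
        native_step_years=target_step_years,
    )


def sample_human_surface(
    field: HumanField,
    omega: float,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Draw one plausible relative-abundance realization per (step, cell).

    Each value is drawn from a lognormal with median ``mean + omega * sd``
    (omega in [-1, 1] positions the sampling window within the +-1 s.d.
    envelope) and shape sigma = asinh(sd / median), so one lognormal
    log-unit spans the envelope half-width. Draws are rejection-truncated to
    [max(0, mean - sd), mean + sd]. Cells with sd = 0 (or a nonpositive
    median) return the window centre floored at zero.
    """
    if not -1.0 <= omega <= 1.0:
        raise ValueError("omega must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    mean = field.mean
    sd = field.sd
    med = mean + omega * sd
    lo = np.maximum(0.0, mean - sd)
    hi = mean + sd

    out = np.clip(med, lo, hi)
    active = (sd > 0) & (med > 0)
    if not np.any(active):
        return out

    mu = np.log(med[active])
    sigma = np.arcsinh(sd[active] / med[active])
    lo_a, hi_a = lo[active], hi[active]
    draws = np.empty(mu.shape)
    todo = np.ones(mu.shape, bool)
    for _ in range(200):
        n = int(todo.sum())
        if n == 0:
            break
        z = rng.standard_normal(n)
        cand = np.exp(mu[todo] + sigma[todo] * z)
        ok = (cand >= lo_a[todo]) & (cand <= hi_a[todo])
        idx = np.flatnonzero(todo)
        draws[idx[ok]] = cand[ok]
        todo[idx[ok]] = False
    if np.any(todo):
        # pathological windows (rejection nearly never succeeds): fall back
        # to the clipped window centre
        draws[todo] = np.clip(med[active][todo], lo_a[todo], hi_a[todo])
    out[active] = draws
    return out
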