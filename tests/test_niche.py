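import numpy as np
import pytest

from wisent.fossils import FossilRecord, filter_fossils
from wisent.grid import GridSpec
from wisent.niche import (
    _product_gaussian_density,
    fit_hypervolume,
    generational_means,
    intersect_occurrences,
    project_suitability,
    scale_suitability,
    silverman_bandwidths,
    subsample_niche,
    truncate_density_map,
)


def rec(cell=0, age=500.0, sd=0.0, q=15, kind="fossil"):
    return FossilRecord(cell_id=cell, age_bp=age, age_sd=sd, quality_score=q, kind=kind)


class TestQualityFilter:
    def test_strictly_greater_than_ten(self):
        records = [rec(q=10), rec(q=11)]
        kept = filter_fossils(records)
        assert [r.quality_score for r in kept] == [11]

    def test_empty_input(self):
        assert filter_fossils([]) == []

    def test_enumerated_scores(self):
        records = [rec(q=s) for s in (5, 10, 11, 15)]
        assert len(filter_fossils(records)) == 2

    def test_order_preserved(self):
        records = [rec(q=12, age=a) for a in (900, 300, 600)]
        assert [r.age_bp for r in filter_fossils(records)] == [900, 300, 600]


class TestGenerationalMeans:
    def test_constant_input(self):
        t = np.arange(0, 101, 5.0)
        v = np.full_like(t, 3.5)
        out, _ = generational_means(v, t)
        assert np.allclose(out, 3.5)

    def test_linear_ramp_equals_window_centres(self):
        t = np.arange(0, 301, 1.0)
        v = t.copy()  # v(t) = t
        out, ot = generational_means(v, t, window_years=30, step_years=10)
        # interior windows are symmetric around the centre
        assert np.allclose(out[2:-2], ot[2:-2])

    def test_single_slice_truncated_window(self):
        v = np.array([[7.0]])
        out, _ = generational_means(v, np.array([100.0]), window_years=30)
        assert out.shape == (1, 1) and out[0, 0] == 7.0


class TestIntersectOccurrences:
    @pytest.fixture()
    def grid(self):
        return GridSpec(n_rows=3, n_cols=3, t_start_bp=1000, t_end_bp=100)

    @pytest.fixture()
    def env(self, grid):
        rng = np.random.default_rng(0)
        return rng.normal(size=grid.shape + (4,))

    def test_sharp_date_gives_one_point(self, grid, env):
        pts = intersect_occurrences([rec(cell=4, age=500, sd=0)], env, grid)
        assert pts.shape == (1, 4)
        s = grid.step_of_bp(500)
        assert np.array_equal(pts[0], env[s, 1, 1])

    def test_dating_uncertainty_spans_five_steps(self, grid, env):
        # +-2 s.d. of 10 y = a 40-year window = 5 generational steps
        pts = intersect_occurrences([rec(cell=4, age=500, sd=10)], env, grid)
        assert pts.shape == (5, 4)

    def test_overlapping_records_deduplicated(self, grid, env):
        records = [rec(cell=4, age=500, sd=10), rec(cell=4, age=510, sd=10)]
        pts = intersect_occurrences(records, env, grid)
        # windows 460-540 and 470-550 overlap: union spans 460..550 -> 6 bins
        assert pts.shape == (6, 4)

    def test_out_of_span_record_skipped(self, grid, env):
        pts = intersect_occurrences([rec(cell=4, age=5000, sd=0)], env, grid)
        assert pts.shape[0] == 0


class TestHypervolumeFit:
    def test_cv_bandwidth_near_silverman_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((500, 4))
        model = fit_hypervolume(pts, seed=1)
        silv = silverman_bandwidths(model.points)
        ratio = model.bandwidths / silv
        assert np.all(ratio >= 0.5) and np.all(ratio <= 2.0)

    def test_duplicated_cloud_same_bandwidth_multiplier(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((100, 2))
        m1 = fit_hypervolume(pts, seed=3)
        m2 = fit_hypervolume(np.vstack([pts, pts]), seed=3)
        # same chosen grid multiplier relative to each sample's Silverman value
        r1 = m1.bandwidths / silverman_bandwidths(m1.points)
        r2 = m2.bandwidths / silverman_bandwidths(m2.points)
        assert np.allclose(r1 / r1[0], r2 / r2[0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_hypervolume(np.zeros((5, 4)) + np.arange(5)[:, None])

    def test_degenerate_axis_named(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((50, 4))
        pts[:, 2] = 1.0
        with pytest.raises(ValueError, match="axis 2"):
            fit_hypervolume(pts)

    def test_kernel_density_matches_bruteforce_sum(self):
        """Product-Gaussian KDE equals an explicit sum of Gaussians."""
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((50, 2))
        h = np.array([0.4, 0.7])
        x = rng.standard_normal((20, 2))
        fast = _product_gaussian_density(x, pts, h)
        slow = np.zeros(20)
        for i, xi in enumerate(x):
            acc = 0.0
            for p in pts:
                z = (xi - p) / h
                acc += np.exp(-0.5 * np.dot(z, z)) / (2 * np.pi * h[0] * h[1])
            slow[i] = acc / len(pts)
        assert np.allclose(fast, slow, atol=1e-10)


@pytest.fixture(scope="module")
def full4(): 
    rng = np.random.default_rng(5)
    return fit_hypervolume(rng.standard_normal((400, 4)), seed=5)


@pytest.fixture(scope="module")
def full3():
    rng = np.random.default_rng(6)
    return fit_hypervolume(rng.standard_normal((200, 3)), seed=6)


class TestNicheSubsampling:

    def test_identity_when_full_volume(self, full4):
        sub = subsample_niche(full4, 1.0, 0.0, seed=0)
        x = np.random.default_rng(0).standard_normal((50, 4))
        assert np.max(np.abs(sub.density(x, standardized=True) - full4.density(x, standardized=True))) < 1e-12

    def test_retained_mass_matches_volume_fraction(self, full4):
        sub = subsample_niche(full4, 0.65, 0.0, seed=1, n_mc=40_000)
        # Monte-Carlo oracle: fraction of fresh KDE samples above threshold
        rng = np.random.default_rng(99)
        samples = full4.sample(100_000, rng)
        dens = full4.density(samples, standardized=True)
        retained = np.mean(dens >= sub.density_threshold)
        assert retained == pytest.approx(0.65, abs=0.01)

    def test_marginality_displacement_exact(self, full4):
        sub = subsample_niche(full4, 1.0, 0.37, seed=2)
        assert np.linalg.norm(sub.centroid_shift) == pytest.approx(0.37, abs=1e-6)

    def test_zero_volume_rejected(self, full4):
        with pytest.raises(ValueError):
            subsample_niche(full4, 0.0, 0.0, seed=0)


class TestSuitabilityProjection:

    def test_common_envpoint_saturates(self, full3):
        centroid = full3.axis_means.copy()
        env = np.tile(centroid, (4, 2, 2, 1))
        suit = project_suitability(full3, env)
        assert np.allclose(suit, 1.0)

    def test_far_environment_scores_zero_against_occupied_core(self, full3):
        rng = np.random.default_rng(7)
        core = rng.standard_normal((4, 2, 2, 3)) * full3.axis_sds + full3.axis_means
        env = core.copy()
        env[:, 1, 1, :] = full3.axis_means + 50.0 * full3.axis_sds  # >10 bandwidths out
        suit = project_suitability(full3, env)
        assert np.all(suit[:, 1, 1] < 1e-6)

    def test_pooled_p95_scaling(self, full3):
        rng = np.random.default_rng(8)
        env = rng.standard_normal((5, 3, 3, 3)) * full3.axis_sds + full3.axis_means
        suit = project_suitability(full3, env)
        dens = full3.density(env.reshape(-1, 3))
        expected = np.clip(dens / np.percentile(dens, 95), 0, 1).reshape(5, 3, 3)
        assert np.allclose(suit, expected)
        # about 5% of pooled cells sit at the clipped ceiling
        assert (suit == 1.0).mean() == pytest.approx(0.05, abs=0.05)

    def test_axis_mismatch_rejected(self, full3):
        with pytest.raises(ValueError):
            project_suitability(full3, np.zeros((2, 1, 1, 4)))

    def test_shrinking_volume_never_raises_suitability(self, full3):
        rng = np.random.default_rng(9)
        env = rng.standard_normal((5, 3, 3, 3)) * full3.axis_sds + full3.axis_means
        prev = project_suitability(full3, env)
        for vf in (0.9, 0.7, 0.5, 0.3):
            sub = subsample_niche(full3, vf, 0.0, seed=10)
            cur = project_suitability(sub, env)
            assert np.all(cur <= prev + 1e-12)
            prev = cur


class TestDensityMapTruncation:
    def test_volume_one_is_pure_scaling(self):
        rng = np.random.default_rng(10)
        d = rng.uniform(0, 2, size=(6, 4, 4))
        assert np.allclose(truncate_density_map(d, 1.0), scale_suitability(d))

    def test_retained_mass_fraction(self):
        rng = np.random.default_rng(11)
        d = rng.uniform(0, 1, size=(10, 8, 8))
        out = truncate_density_map(d, 0.6)
        kept_mass = d[out > 0].sum() / d.sum()
        # threshold is the smallest value whose inclusion reaches 60% mass
        assert kept_mass == pytest.approx(0.6, abs=0.01)

    def test_monotone_in_volume_fraction(self):
        rng = np.random.default_rng(12)
        d = rng.uniform(0, 1, size=(5, 6, 6))
        prev = truncate_density_map(d, 1.0)
        for vf in (0.8, 0.5, 0.2):
            cur = truncate_density_map(d, vf)
            assert np.all(cur <= prev + 1e-12)
            prev = cur
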