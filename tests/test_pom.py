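import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wisent.fossils import FossilRecord
from wisent.grid import GridSpec
from wisent.params import DemographicParams
from wisent.pom import (
    TargetSpec,
    abc_distance,
    abc_reject,
    compare_trend,
    convergence_check,
    ensemble_average,
    ensemble_weights,
    goodness_of_fit,
    occurrence_match,
    overlap_coefficient,
    persistence_penalty,
    refine_priors,
    refugia_diff,
    sample_priors_lhs,
)
from wisent.sepm import SimResult, extirpation_steps


def make_sim(abundance, grid=None):
    abundance = np.asarray(abundance, float)
    if abundance.shape[0] == 1 and grid is None:
        abundance = np.repeat(abundance, 2, axis=0)  # grids need >= 2 steps
    if grid is None:
        T, R, C = abundance.shape
        grid = GridSpec(
            n_rows=R, n_cols=C, t_start_bp=100 + 10 * (T - 1), t_end_bp=100
        )
    return SimResult(
        grid=grid,
        abundance=abundance,
        offtake=np.zeros_like(abundance),
        extirpation_step=extirpation_steps(abundance),
    )


class TestLatinHypercube:
    def test_margins_stratified(self):
        ranges = {"h_max": (0.0, 1.0), "omega": (-1.0, 1.0)}
        params = sample_priors_lhs(ranges, 10, seed=0)
        for name, (lo, hi) in ranges.items():
            v = np.array([p.to_dict()[name] for p in params])
            bins = np.floor((v - lo) / (hi - lo) * 10).astype(int)
            assert sorted(bins) == list(range(10))

    def test_degenerate_range(self):
        params = sample_priors_lhs({"r_max": (0.2, 0.2)}, 5, seed=1)
        assert all(p.r_max == 0.2 for p in params)

    def test_round_size(self):
        params = sample_priors_lhs({"h_max": (0, 0.3)}, 250, seed=2)
        assert len(params) == 250

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            sample_priors_lhs({"h_max": (0, 1)}, 0, seed=0)

    def test_unsampled_params_keep_base(self):
        base = DemographicParams(theta=123.0)
        params = sample_priors_lhs({"h_max": (0, 1)}, 3, seed=3, base=base)
        assert all(p.theta == 123.0 for p in params)


class TestOccurrenceMatch:
    def test_direct_hit(self):
        ab = np.zeros((3, 3, 3))
        ab[1, 1, 1] = 5.0
        sim = make_sim(ab)
        f = FossilRecord(cell_id=4, age_bp=sim.grid.times_bp[1], age_sd=0, quality_score=12)
        assert occurrence_match(sim, [f]) == 1.0

    def test_empty_landscape(self):
        sim = make_sim(np.zeros((2, 2, 2)))
        f = FossilRecord(cell_id=0, age_bp=sim.grid.times_bp[0], age_sd=0, quality_score=12)
        assert occurrence_match(sim, [f]) == 0.0

    def test_neighbour_counts_as_match(self):
        ab = np.zeros((2, 3, 3))
        ab[0, 0, 0] = 1.0
        sim = make_sim(ab)
        f = FossilRecord(cell_id=4, age_bp=sim.grid.times_bp[0], age_sd=0, quality_score=12)
        assert occurrence_match(sim, [f]) == 1.0  # (1,1) touches (0,0)

    def test_matches_bruteforce_enumeration(self):
        """Vectorized matcher equals an exhaustive per-fossil triple loop."""
        rng = np.random.default_rng(5)
        ab = (rng.random((8, 5, 5)) < 0.25) * rng.uniform(1, 9, (8, 5, 5))
        sim = make_sim(ab)
        grid = sim.grid
        fossils = [
            FossilRecord(
                cell_id=int(rng.integers(0, 25)),
                age_bp=float(rng.uniform(grid.t_end_bp, grid.t_start_bp)),
                age_sd=float(rng.choice([0.0, 10.0, 25.0])),
                quality_score=12,
            )
            for _ in range(6)
        ]

        def brute(sim, fossils):
            hits = 0
            occ = sim.abundance > 0
            for f in fossils:
                row, col = grid.cell_rowcol(f.cell_id)
                ok = False
                for s in range(grid.n_steps):
                    t = grid.times_bp[s]
                    if abs(t - f.age_bp) > 2 * f.age_sd + grid.step_years / 2:
                        continue
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = row + dr, col + dc
                            if 0 <= r2 < 5 and 0 <= c2 < 5 and occ[s, r2, c2]:
                                ok = True
                hits += ok
            return hits / len(fossils)

        assert occurrence_match(sim, fossils) == pytest.approx(brute(sim, fossils))

    def test_no_fossils_rejected(self):
        sim = make_sim(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            occurrence_match(sim, [])


class TestPersistencePenalty:
    def grid(self, T=200):
        # spans 1850 CE: 100 BP is the final step
        return GridSpec(n_rows=2, n_cols=2, t_start_bp=100 + 10 * (T - 1), t_end_bp=100)

    def test_no_penalty_when_occupied_through_1850(self):
        g = self.grid()
        ab = np.ones(g.shape)
        sim = make_sim(ab, g)
        pen = persistence_penalty(sim, {"a": [0], "b": [3]})
        assert pen == 0.0

    def test_early_extirpation_counts_years(self):
        g = self.grid()
        ab = np.ones(g.shape)
        cut = g.step_of_ce(1700.0)
        ab[cut + 1 :, 0, 0] = 0.0  # cell 0 last occupied 1700 CE
        sim = make_sim(ab, g)
        assert persistence_penalty(sim, {"a": [0]}) == pytest.approx(150.0)

    def test_never_occupied_counts_from_simulation_start(self):
        T = 200
        g = self.grid(T)
        sim = make_sim(np.zeros(g.shape), g)
        start_ce = 1950 - g.t_start_bp
        pen = persistence_penalty(sim, {"a": [0], "b": [3]})
        assert pen == pytest.approx(2 * (1850 - start_ce))


class TestRefugiaCount:
    def test_two_patches_match_expectation(self):
        ab = np.zeros((1, 5, 5))
        ab[0, 0, 0] = 1.0
        ab[0, 4, 4] = 1.0
        assert refugia_diff(make_sim(ab), expected=2) == 0

    def test_five_patches(self):
        ab = np.zeros((1, 5, 5))
        for r, c in [(0, 0), (0, 4), (2, 2), (4, 0), (4, 4)]:
            ab[0, r, c] = 1.0
        assert refugia_diff(make_sim(ab), expected=2) == 3

    def test_empty_map(self):
        assert refugia_diff(make_sim(np.zeros((1, 4, 4))), expected=2) == 2

    def test_diagonal_contact_is_one_patch(self):
        ab = np.zeros((1, 3, 3))
        ab[0, 0, 0] = ab[0, 1, 1] = 1.0
        assert refugia_diff(make_sim(ab), expected=1) == 0


class TestDistanceAndRejection:
    def test_perfect_match_distance_zero(self):
        s = np.array([1.0, 0.0, 0.0])
        assert abc_distance(s, s, np.ones(3)) == 0.0

    def test_single_component(self):
        d = abc_distance(np.array([2.0]), np.array([5.0]), np.array([1.5]))
        assert d == pytest.approx(2.0)

    def test_three_component_hand_case(self):
        s = np.array([0.8, 100.0, 1.0])
        t = np.array([1.0, 0.0, 0.0])
        sc = np.array([0.1, 50.0, 1.0])
        assert abc_distance(s, t, sc) == pytest.approx(np.sqrt(4 + 4 + 1))

    def test_best_quarter_percent_of_ten_thousand(self):
        rng = np.random.default_rng(0)
        d = rng.random(10_000)
        acc = abc_reject(d, 0.0025)
        assert len(acc) == 25

    def test_zero_distance_ranked_first(self):
        d = np.array([0.4, 0.0, 0.9, 0.2])
        acc = abc_reject(d, 0.25)
        assert list(acc) == [1]

    def test_tie_break_prefers_lower_index(self):
        d = np.array([0.5, 0.5, 0.5, 0.5])
        acc = abc_reject(d, 0.5)
        assert list(acc) == [0, 1]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=1000), st.floats(0.001, 1.0))
    def test_equals_full_sort_oracle(self, dist, tol):
        d = np.array(dist)
        acc = abc_reject(d, tol)
        m = int(np.ceil(len(d) * tol))
        oracle = np.sort(np.argsort(d, kind="stable")[: min(m, len(d))])
        assert np.array_equal(acc, oracle)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            abc_reject(np.array([1.0]), 0.0)


class TestPriorRefinement:
    def test_collapsed_range_for_identical_accepted(self):
        acc = np.full((5, 1), 0.3)
        out = refine_priors(acc, ["h_max"], {"h_max": (0.0, 1.0)})
        assert out["h_max"] == (0.3, 0.3)

    def test_expansion_arithmetic(self):
        acc = np.array([[0.2], [0.4]])
        out = refine_priors(acc, ["h_max"], {"h_max": (0.0, 1.0)}, expansion=1.1)
        lo, hi = out["h_max"]
        assert lo == pytest.approx(0.19) and hi == pytest.approx(0.41)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=50))
    def test_refined_range_within_original(self, vals):
        acc = np.array(vals)[:, None]
        out = refine_priors(acc, ["h_max"], {"h_max": (0.0, 1.0)})
        lo, hi = out["h_max"]
        assert 0.0 <= lo <= hi <= 1.0


class TestConvergence:
    def test_identical_samples_converged(self):
        a = np.random.default_rng(0).random((50, 2))
        conv, stats = convergence_check([a, a.copy()])
        assert conv
        assert all(v == pytest.approx(1.0) for v in stats.values())

    def test_disjoint_supports_not_converged(self):
        a = np.zeros((20, 1))
        b = np.ones((20, 1))
        conv, stats = convergence_check([a, b])
        assert not conv and min(stats.values()) == 0.0

    def test_normals_one_sd_apart_overlap(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20_000)
        b = rng.normal(1, 1, 20_000)
        # closed form: 2 Phi(-1/2) ~ 0.617
        ov = overlap_coefficient(a, b, n_bins=60)
        assert ov == pytest.approx(0.617, abs=0.03)


class TestGoodnessOfFit:
    def test_target_at_centroid_fits_well(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=(40, 3))
        p = goodness_of_fit(s, s.mean(axis=0), n_reps=500, seed=0)
        assert p >= 0.5

    def test_distant_target_rejected(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=(40, 3))
        far = s.mean(axis=0) + 10 * s.std(axis=0)
        p = goodness_of_fit(s, far, n_reps=500, seed=0)
        assert p < 0.05

    def test_reproducible_and_bounded(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=(10, 3))
        p1 = goodness_of_fit(s, np.zeros(3), seed=9)
        p2 = goodness_of_fit(s, np.zeros(3), seed=9)
        assert p1 == p2 and 0.0 <= p1 <= 1.0


class TestEnsemble:
    def test_weights_sum_to_one(self):
        w = ensemble_weights(np.array([0.1, 2.0, 5.0, 0.0]))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_inverse_distance_formula(self):
        w = ensemble_weights(np.array([1.0, 3.0]))
        assert w[0] == pytest.approx(0.75) and w[1] == pytest.approx(0.25)

    def test_equal_distances_arithmetic_mean(self):
        a = make_sim(np.full((2, 2, 2), 10.0))
        b = make_sim(np.full((2, 2, 2), 20.0))
        ens = ensemble_average([a, b], np.array([2.0, 2.0]))
        assert np.allclose(ens.mean_abundance, 15.0)

    def test_single_member_unchanged(self):
        a = make_sim(np.full((2, 2, 2), 7.0))
        ens = ensemble_average([a], np.array([0.5]))
        assert np.array_equal(ens.mean_abundance, a.abundance)

    def test_weighted_scalar_case(self):
        a = make_sim(np.full((2, 1, 1), 10.0))
        b = make_sim(np.full((2, 1, 1), 20.0))
        ens = ensemble_average([a, b], np.array([1.0, 3.0]))
        assert ens.mean_abundance[0, 0, 0] == pytest.approx(12.5)

    def test_identical_members_equal_any_member(self):
        a = make_sim(np.full((3, 2, 2), 4.0))
        ens = ensemble_average([a, a, a], np.array([1.0, 2.0, 3.0]))
        assert np.allclose(ens.mean_abundance, a.abundance)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([], np.array([]))


class TestTrendComparison:
    def test_member_always_inside_envelope(self):
        m1 = np.array([10.0, 8.0, 6.0, 5.0])
        m2 = np.array([12.0, 9.0, 5.0, 4.0])
        rep = compare_trend([m1, m2], m1)
        assert rep.inside_all

    def test_flat_external_flagged(self):
        members = [np.array([10.0, 8.0, 6.0, 4.0])]
        rep = compare_trend(members, np.array([5.0, 5.0, 5.0, 5.0]))
        assert rep.flagged_low_correlation

    def test_hand_enumerated_envelope(self):
        m1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m2 = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        ext = np.array([3.0, 3.0, 3.0, 3.0, 3.0])
        rep = compare_trend([m1, m2], ext)
        # external normalizes to a constant 1; the member envelope only
        # reaches 1 at the two endpoints
        assert rep.inside_fraction == pytest.approx(0.4)
        assert not rep.inside_all

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_trend([np.ones(4)], np.ones(5))
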