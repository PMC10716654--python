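import numpy as np
import pytest

from wisent.grid import GridSpec
from wisent.landscape import LandscapeSeries
from wisent.params import DemographicParams
from wisent.sepm import (
    apply_allee,
    carrying_capacity,
    dispersal_kernel,
    extirpation_steps,
    simulate,
    step_dispersal,
    step_growth,
    step_harvest,
    EXTANT,
    NEVER_OCCUPIED,
)


class TestCarryingCapacity:
    def test_posterior_density_on_reference_cell(self):
        # 0.3 animals/km2 on an 86.6 x 75.6 km cell is ~2000 animals
        k = carrying_capacity(1.0, 0.3, 86.6 * 75.6)
        assert round(k / 100) * 100 == 2000

    def test_zero_suitability(self):
        assert carrying_capacity(0.0, 0.3, 6547) == 0

    def test_linear_reduction(self):
        assert carrying_capacity(0.5, 1.0, 100.0) == pytest.approx(50.0)


class TestRickerGrowth:
    def test_fixed_point_at_k(self):
        rng = np.random.default_rng(0)
        N = np.array([1000.0])
        out = step_growth(N, np.array([1000.0]), r_max=0.2, r_sd=0.0, rng=rng)
        assert out[0] == pytest.approx(1000.0)

    def test_closed_form_below_k(self):
        rng = np.random.default_rng(0)
        out = step_growth(
            np.array([100.0]), np.array([1000.0]), r_max=0.2, r_sd=0.0, rng=rng
        )
        assert out[0] == pytest.approx(100.0 * np.exp(0.18), rel=1e-12)

    def test_zero_k_collapses(self):
        rng = np.random.default_rng(0)
        out = step_growth(np.array([50.0]), np.array([0.0]), 0.2, 0.1, rng)
        assert out[0] == 0.0

    def test_matches_scalar_reference_over_100_steps(self):
        """Deterministic vectorized Ricker equals a scalar-loop reference."""
        rng = np.random.default_rng(0)
        r, K = 0.25, 800.0
        N_vec = np.array([37.0])
        N_ref = 37.0
        for _ in range(100):
            N_vec = step_growth(N_vec, np.array([K]), r, 0.0, rng)
            N_ref = N_ref * np.exp(r * (1.0 - N_ref / K))
        assert N_vec[0] == pytest.approx(N_ref, rel=1e-12)


class TestHarvest:
    def test_no_humans_no_offtake(self):
        N = np.array([500.0])
        out, off = step_harvest(N, np.array([0.0]), h_max=0.2, q_shape=1.0, theta=100)
        assert off[0] == 0.0 and out[0] == 500.0

    def test_cap_binds_at_high_abundance(self):
        N = np.array([1e9])
        _, off = step_harvest(N, np.array([1.0]), h_max=0.15, q_shape=1.5, theta=100)
        assert off[0] / N[0] == pytest.approx(0.15, rel=1e-6)

    def test_type_iii_half_saturation(self):
        # q=2, N=theta, full human presence: availability = 1/2
        N = np.array([200.0])
        _, off = step_harvest(N, np.array([1.0]), h_max=0.1, q_shape=2.0, theta=200)
        assert off[0] == pytest.approx(0.1 * 200 / 2)

    def test_type_ii_form(self):
        N = np.array([300.0])
        _, off = step_harvest(N, np.array([0.7]), h_max=0.1, q_shape=1.0, theta=100)
        assert off[0] == pytest.approx(0.1 * 0.7 * 300 * 300 / (100 + 300))

    def test_offtake_never_exceeds_abundance(self):
        N = np.linspace(0, 50, 11)
        out, off = step_harvest(N, np.ones(11), h_max=1.0, q_shape=1.3, theta=1.0)
        assert np.all(off <= N) and np.all(out >= 0)


class TestAllee:
    def test_below_threshold_extirpated(self):
        assert apply_allee(np.array([8.0]), 9.0)[0] == 0.0

    def test_at_threshold_survives(self):
        assert apply_allee(np.array([9.0]), 9.0)[0] == 9.0

    def test_zero_threshold_identity(self):
        N = np.array([0.5, 3.0])
        assert np.array_equal(apply_allee(N, 0.0), N)


class TestDispersal:
    @pytest.fixture()
    def grid2(self):
        return GridSpec(n_rows=1, n_cols=2, t_start_bp=200, t_end_bp=100)

    def test_zero_fraction_is_identity(self, grid2):
        N = np.array([[100.0, 0.0]])
        out = step_dispersal(N, np.ones((1, 2)), 0.0, 100.0, grid2)
        assert np.array_equal(out, N)

    def test_blocked_landscape_movers_stay(self, grid2):
        N = np.array([[100.0, 0.0]])
        friction = np.array([[1.0, 0.0]])
        out = step_dispersal(N, friction, 0.05, 100.0, grid2)
        assert np.array_equal(out, N)

    def test_two_cell_transfer_is_exact_fraction(self, grid2):
        N = np.array([[100.0, 0.0]])
        out = step_dispersal(N, np.ones((1, 2)), 0.05, 100.0, grid2)
        assert out[0, 0] == pytest.approx(95.0)
        assert out[0, 1] == pytest.approx(5.0)

    def test_mass_conserved_on_random_landscapes(self):
        rng = np.random.default_rng(3)
        grid = GridSpec(n_rows=8, n_cols=9, t_start_bp=200, t_end_bp=100)
        for _ in range(10):
            N = rng.uniform(0, 500, size=(8, 9))
            friction = rng.uniform(0, 1, size=(8, 9))
            friction[rng.random((8, 9)) < 0.2] = 0.0
            out = step_dispersal(N, friction, 0.2, 250.0, grid)
            assert out.sum() == pytest.approx(N.sum(), rel=1e-9)
            assert np.all(out >= -1e-12)

    def test_kernel_respects_maximum_distance(self):
        grid = GridSpec(n_rows=9, n_cols=9, t_start_bp=200, t_end_bp=100)
        k = dispersal_kernel(grid, 160.0)
        # 160 km allows one cell east/west (86.6) and two north/south (75.6x2=151.2)
        assert k.shape == (5, 3)
        assert k[2, 1] == 0.0  # no self-destination
        # corner offset distance = hypot(151.2, 86.6) = 174 km > 160 -> excluded
        assert k[0, 0] == 0.0

    def test_unreachable_maximum_distance_no_op(self):
        grid = GridSpec(n_rows=3, n_cols=3, t_start_bp=200, t_end_bp=100)
        N = np.full((3, 3), 10.0)
        out = step_dispersal(N, np.ones((3, 3)), 0.2, 50.0, grid)  # < cell size
        assert np.array_equal(out, N)


class TestExtirpationBookkeeping:
    def test_sentinels(self):
        ab = np.zeros((4, 1, 2))
        ab[:2, 0, 0] = 5.0  # extirpated after step 1
        ext = extirpation_steps(ab)
        assert ext[0, 0] == 2
        assert ext[0, 1] == NEVER_OCCUPIED

    def test_extant_cell(self):
        ab = np.ones((3, 1, 1))
        assert extirpation_steps(ab)[0, 0] == EXTANT


class TestSimulate:
    def test_equilibrium_with_static_landscape(self, flat_landscape):
        p = DemographicParams(
            r_sd=0.0, h_max=0.0, allee_threshold=0.0, dispersal_fraction=0.0
        )
        human = np.zeros(flat_landscape.grid.shape)
        sim = simulate(p, flat_landscape, human, seed=0)
        assert np.allclose(sim.totals, sim.totals[0], rtol=1e-9)

    def test_dispersal_edge_drift_settles(self, flat_landscape):
        # on a bounded uniform grid, dispersal redistributes toward a nearby
        # equilibrium; totals move by well under 1% and stabilize
        p = DemographicParams(
            r_sd=0.0, h_max=0.0, allee_threshold=0.0, dispersal_fraction=0.1
        )
        human = np.zeros(flat_landscape.grid.shape)
        sim = simulate(p, flat_landscape, human, seed=0)
        assert np.all(np.abs(sim.totals / sim.totals[0] - 1.0) < 0.01)
        assert abs(sim.totals[-1] - sim.totals[-2]) < 1e-4 * sim.totals[-1]

    def test_totals_track_suitability_collapse(self, flat_landscape):
        land = flat_landscape.copy()
        T = land.grid.n_steps
        land.suitability[T // 2 :] *= 0.5
        p = DemographicParams(
            r_max=0.5, r_sd=0.0, h_max=0.0, allee_threshold=0.0,
            dispersal_fraction=0.0,
        )
        human = np.zeros(land.grid.shape)
        sim = simulate(p, land, human, seed=0)
        pre = sim.totals[T // 2 - 1]
        assert sim.totals[T // 2 + 5] == pytest.approx(0.5 * pre, rel=0.05)

    def test_deterministic_under_fixed_seed(
        self, default_params, small_landscape, small_human_real
    ):
        a = simulate(default_params, small_landscape, small_human_real, seed=11)
        b = simulate(default_params, small_landscape, small_human_real, seed=11)
        assert np.array_equal(a.abundance, b.abundance)
        assert np.array_equal(a.offtake, b.offtake)

    def test_no_occupancy_on_ice(self, small_sim, small_landscape):
        assert np.all(small_sim.abundance[small_landscape.ice] == 0)

    def test_abundance_nonnegative_offtake_bounded(self, small_sim):
        assert np.all(small_sim.abundance >= 0)
        assert np.all(small_sim.offtake >= 0)

    def test_harvest_monotonicity_in_h_max(
        self, small_landscape, small_human_real
    ):
        base = DemographicParams(r_sd=0.0)
        totals = []
        for h in (0.0, 0.1, 0.2, 0.3):
            sim = simulate(
                base.replace(h_max=h), small_landscape, small_human_real, seed=3
            )
            totals.append(sim.totals)
        for lo, hi in zip(totals[1:], totals[:-1]):
            assert np.all(lo <= hi + 1e-9)
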