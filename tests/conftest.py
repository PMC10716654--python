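import numpy as np
import pytest

from wisent.grid import GridSpec
from wisent.landscape import HumanField, LandscapeSeries
from wisent.params import DemographicParams


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """10x10 grid over 2 000 years at 10-year generations (191 steps)."""
    return GridSpec(n_rows=10, n_cols=10, t_start_bp=2000, t_end_bp=100)


@pytest.fixture(scope="session")
def small_landscape(small_grid):
    from wisent.synthetic import gen_landscape

    T = small_grid.n_steps
    return gen_landscape(
        small_grid,
        collapse_step=int(0.45 * T),
        collapse_depth=0.5,
        recovery_steps=int(0.15 * T),
        landuse_onset_step=int(0.8 * T),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_human_field(small_grid):
    from wisent.synthetic import gen_human_field

    return gen_human_field(small_grid, growth_rate=0.05, seed=43)


@pytest.fixture(scope="session")
def small_human_real(small_human_field):
    from wisent.humans import sample_human_surface

    return sample_human_surface(small_human_field, omega=0.0, seed=44)


@pytest.fixture(scope="session")
def default_params() -> DemographicParams:
    return DemographicParams()


@pytest.fixture(scope="session")
def small_sim(default_params, small_landscape, small_human_real):
    from wisent.sepm import simulate

    return simulate(default_params, small_landscape, small_human_real, seed=7)


@pytest.fixture(scope="session")
def flat_landscape():
    """Uniform, static, ice-free landscape for analytic checks."""
    grid = GridSpec(n_rows=4, n_cols=4, t_start_bp=1000, t_end_bp=100)
    shape = grid.shape
    return LandscapeSeries(
        grid=grid,
        suitability=np.full(shape, 0.8),
        biomass_adjusted=np.ones(shape),
        ice=np.zeros(shape, bool),
        friction=np.ones(shape),
    )


@pytest.fixture(scope="session")
def desk_fit_bundle():
    """A tiny calibrated fit shared by model/scenario/driver tests."""
    import warnings

    from wisent.config import RunConfig
    from wisent.pipeline import build_model_from_config

    cfg = RunConfig.desk_profile(seed=5)
    cfg = cfg.model_copy(
        update={
            "round_sizes": (60, 40),
            "grid": cfg.grid.model_copy(update={"rows": 12, "cols": 12, "t_start_bp": 2100}),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, bundle = build_model_from_config(cfg)
    fit = model.fit(round_sizes=cfg.round_sizes, tolerance=cfg.tolerance, seed=5)
    return model, bundle, fit
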