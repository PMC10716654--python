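"""Counterfactual scenarios, harvest-escalation scans and cause attribution.

Counterfactual reruns remove one human stressor at a time (no hunting, no
land-use change, or both) under common random numbers, so differences from
the baseline isolate that stressor. The harvest scan escalates the
post-1500 CE harvest rate in 10% increments and compares the final
population against the 1870 CE historical estimate. Per-cell attribution
labels each baseline-extirpated cell by the mildest counterfactual under
which it survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import humans as _humans
from .landscape import HumanField, LandscapeSeries
from .model import RangeDynamicsModel, RangeFitResults
from .params import DemographicParams
from .sepm import SimResult, simulate

SCENARIO_NAMES = ("baseline", "no_hunting", "no_landuse", "no_human", "harvest_scan")

#: Historical 1870 CE validation constant: refugial population estimates.
CAUCASUS_1870 = 2000
BIALOWIEZA_1870 = 1560
HISTORICAL_TOTAL_1870 = CAUCASUS_1870 + BIALOWIEZA_1870

#: Attribution codes
CAUSE_LABELS = {
    -1: "not_extirpated",
    0: "climate",
    1: "hunting",
    2: "land_use",
    3: "human_combined",
}


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    harvest_multiplier_post1500: float = 0.0
    end_year_ce: float = 1500.0

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; one of {SCENARIO_NAMES}")
        if self.harvest_multiplier_post1500 < 0:
            raise ValueError("harvest multiplier must be nonnegative")


def apply_scenario(
    landscape: LandscapeSeries,
    human: HumanField,
    params: DemographicParams,
    spec: ScenarioSpec,
) -> tuple[LandscapeSeries, HumanField, DemographicParams, np.ndarray | None]:
    """Return (landscape, human, params, h_max_factor) for a scenario run.

    no_hunting sets h_max to zero throughout; no_landuse restores the
    unmodified biomass/suitability and sets land-use friction to 1;
    no_human combines both; harvest_scan scales h_max by
    (1 + multiplier) from the step containing 1500 CE.
    """
    h_factor = None
    if spec.name == "baseline":
        return landscape, human, params, None
    if spec.name in ("no_hunting", "no_human"):
        params = params.replace(h_max=0.0)
    if spec.name in ("no_landuse", "no_human"):
        land = landscape.copy()
        if landscape.suitability_nolanduse is not None:
            land.suitability = landscape.suitability_nolanduse.copy()
        if landscape.biomass_raw is not None:
            land.biomass_adjusted = landscape.biomass_raw.copy()
        if landscape.friction_nolanduse is not None:
            land.friction = landscape.friction_nolanduse.copy()
        landscape = land
    if spec.name == "harvest_scan":
        grid = landscape.grid
        h_factor = np.ones(grid.n_steps)
        start = grid.step_of_ce(1500.0)
        h_factor[start:] = 1.0 + spec.harvest_multiplier_post1500
    return landscape, human, params, h_factor


def run_scenario(
    model: RangeDynamicsModel,
    params: DemographicParams,
    spec: ScenarioSpec,
    seed: int | np.random.SeedSequence,
) -> SimResult:
    """Run one parametrization under a scenario, with the same random
    substreams as the corresponding baseline run (common random numbers)."""
    landscape, human, p, h_factor = apply_scenario(
        model.landscape, model.human_field, params, spec
    )
    scen_model = RangeDynamicsModel(
        landscape=landscape,
        human_field=human,
        target=model.target,
        priors=model.priors,
        base_params=model.base_params,
        raw_density=None if spec.name in ("no_landuse", "no_human") else model.raw_density,
    )
    return scen_model.simulate_params(p, seed, h_max_factor=h_factor)


def scenario_ensemble(
    results: RangeFitResults, spec: ScenarioSpec
) -> list[SimResult]:
    """Rerun every accepted parametrization under a scenario (shared seeds)."""
    r = len(results.rounds) - 1
    fr = results.final_round
    return [
        run_scenario(
            results.model,
            fr["params"][i],
            spec,
            results.model._run_seed(r, i, results.seed),
        )
        for i in fr["accepted"]
    ]


def harvest_scan(
    results: RangeFitResults,
    multipliers: np.ndarray | None = None,
    end_year_ce: float = 1870.0,
    validation_total: float = HISTORICAL_TOTAL_1870,
) -> pd.DataFrame:
    """Escalate post-1500 CE harvest and report final population totals.

    Each accepted parametrization is branched from its saved 1500 CE state
    (seeds preserved) with h_max scaled by (1 + multiplier) from 1500 CE,
    and run to the step containing ``end_year_ce`` (clamped to the grid's
    final step). Returns a tidy frame (multiplier, model, final_total,
    ensemble weighted total, validation target).
    """
    if multipliers is None:
        multipliers = np.round(np.arange(0.1, 1.01, 0.1), 10)
    model = results.model
    grid = model.landscape.grid
    start = grid.step_of_ce(1500.0)
    end = grid.step_of_ce(end_year_ce)
    fr = results.final_round
    r = len(results.rounds) - 1
    w = results.weights
    baseline = results.accepted_results()

    rows = []
    for m in np.asarray(multipliers, float):
        finals = []
        for j, i in enumerate(fr["accepted"]):
            p = fr["params"][i]
            seed = model._run_seed(r, i, results.seed)
            h_factor = np.ones(grid.n_steps)
            h_factor[start:] = 1.0 + m
            land = model._landscape_for(p)
            # branch from the saved 1500 CE state of the baseline run
            init = baseline[j].abundance[start]
            human_seed = np.random.SeedSequence(seed.entropy, spawn_key=seed.spawn_key + (1,))
            sim_seed = np.random.SeedSequence(seed.entropy, spawn_key=seed.spawn_key + (2,))
            human_real = _humans.sample_human_surface(
                model.human_field, p.omega, human_seed
            )
            sim = simulate(
                p, land, human_real, seed=sim_seed, init=init,
                start_step=start, h_max_factor=h_factor,
            )
            finals.append(float(sim.abundance[end].sum()))
        finals = np.asarray(finals)
        rows.append(
            {
                "multiplier": float(m),
                "mean_final_total": float(finals.mean()),
                "weighted_final_total": float(np.average(finals, weights=w)),
                "min_final_total": float(finals.min()),
                "max_final_total": float(finals.max()),
                "validation_total_1870": float(validation_total),
            }
        )
    return pd.DataFrame(rows)


def occupancy_agreement(
    results_list: list[SimResult],
    weights: np.ndarray,
    step: int,
    agreement: float = 0.25,
    low_abundance: float = 50.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Agreement-masked ensemble abundance map at one step.

    A cell is shown only where at least ``agreement`` of the models place
    animals; shown values are the inverse-distance-weighted ensemble
    abundance; cells below ``low_abundance`` animals are flagged (map
    hatching for very low abundance).

    Returns (masked_abundance, shown_mask, low_flag).
    """
    if not 0.0 < agreement <= 1.0:
        raise ValueError("agreement must lie in (0, 1]")
    occ = np.stack([r.abundance[step] > 0 for r in results_list])
    frac = occ.mean(axis=0)
    shown = frac >= agreement
    wmean = np.zeros_like(results_list[0].abundance[step])
    for wi, r in zip(weights, results_list):
        wmean += wi * r.abundance[step]
    masked = np.where(shown, wmean, np.nan)
    low = shown & (wmean < low_abundance)
    return masked, shown, low


def _ensemble_occupied(
    results_list: list[SimResult], step: int, agreement: float
) -> np.ndarray:
    occ = np.stack([r.abundance[step] > 0 for r in results_list])
    return occ.mean(axis=0) >= agreement


def attribute_extirpation(
    baseline: list[SimResult],
    counterfactuals: dict[str, list[SimResult]],
    at_year_ce: float = 1500.0,
    agreement: float = 0.25,
) -> np.ndarray:
    """Label the cause of each baseline extirpation at a reference year.

    For cells extirpated in the baseline ensemble by ``at_year_ce``
    (ensemble agreement below threshold): "hunting" if occupied under
    no_hunting, else "land_use" if occupied under no_landuse, else
    "human_combined" if occupied only under the combined no_human scenario,
    else "climate". Returns an (R, C) int array of cause codes
    (see CAUSE_LABELS); cells occupied in the baseline get -1.
    """
    grid = baseline[0].grid
    for name, ens in counterfactuals.items():
        if ens and ens[0].grid.shape != grid.shape:
            raise ValueError(f"grid mismatch in counterfactual {name!r}")
    step = grid.step_of_ce(at_year_ce)
    base_occ = _ensemble_occupied(baseline, step, agreement)
    occ = {
        name: _ensemble_occupied(ens, step, agreement)
        for name, ens in counterfactuals.items()
    }
    no_hunt = occ.get("no_hunting", np.zeros_like(base_occ))
    no_lu = occ.get("no_landuse", np.zeros_like(base_occ))
    no_hum = occ.get("no_human", np.zeros_like(base_occ))

    out = np.full(grid.shape[1:], 0, dtype=np.int8)  # default: climate
    out[no_hum & ~no_hunt & ~no_lu] = 3
    out[no_lu & ~no_hunt] = 2
    out[no_hunt] = 1
    out[base_occ] = -1
    return out
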