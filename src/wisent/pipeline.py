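"""End-to-end orchestration: synthetic inputs -> calibration -> scenarios ->
driver analysis, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import drivers as _drivers
from . import pom as _pom
from . import scenarios as _scenarios
from . import synthetic as _synthetic
from .config import RunConfig
from .fossils import read_fossils_csv, write_fossils_csv
from .grid import GridSpec
from .landscape import HumanField, LandscapeSeries
from .model import RangeDynamicsModel, RangeFitResults
from .params import DemographicParams
from .pom import TargetSpec


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _grid_from_config(cfg: RunConfig) -> GridSpec:
    g = cfg.grid
    return GridSpec(
        n_rows=g.rows,
        n_cols=g.cols,
        cell_width_km=g.cell_width_km,
        cell_height_km=g.cell_height_km,
        t_start_bp=g.t_start_bp,
        t_end_bp=g.t_end_bp,
        step_years=g.step_years,
    )


def refugia_from_truth(truth, grid, at_year_ce: float = 1850.0, max_refugia: int = 2):
    """Derive named refugium cell sets from the truth run's occupied patches."""
    from scipy import ndimage

    step = grid.step_of_ce(at_year_ce)
    occ = truth.abundance[step] > 0
    lab, n = ndimage.label(occ, structure=np.ones((3, 3)))
    sizes = ndimage.sum_labels(occ, lab, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1][:max_refugia]
    out = {}
    for rank, k in enumerate(order):
        cells = [
            grid.cell_index(r, c) for r, c in zip(*np.nonzero(lab == k + 1))
        ]
        out[f"refugium_{rank + 1}"] = cells
    return out, int(n)


def build_model_from_config(cfg: RunConfig) -> tuple[RangeDynamicsModel, "_synthetic.TruthBundle | None"]:
    """Assemble the model from configured inputs, generating synthetic data
    when no input paths are given."""
    grid = _grid_from_config(cfg)
    if cfg.landscape_path or cfg.human_path or cfg.fossils_path:
        if not (cfg.landscape_path and cfg.human_path and cfg.fossils_path):
            raise PipelineError("inputs", "landscape, human and fossils paths must all be set")
        for p in (cfg.landscape_path, cfg.human_path, cfg.fossils_path):
            if not Path(p).exists():
                raise PipelineError("inputs", f"missing input path {p}")
        landscape = LandscapeSeries.from_netcdf(cfg.landscape_path)
        human = HumanField.from_netcdf(cfg.human_path)
        fossils = read_fossils_csv(cfg.fossils_path)
        refugia = {"refugium_1": [landscape.grid.cell_index(landscape.grid.n_rows - 1, 0)]}
        target = TargetSpec(fossils=fossils, refugium_cells=refugia)
        return RangeDynamicsModel(landscape, human, target, cfg.priors), None

    s = cfg.synthetic
    truth_params = DemographicParams()
    bundle = _synthetic.make_truth_bundle(
        truth_params,
        grid,
        seed=cfg.seed,
        n_fossils=s.n_fossils,
        age_sd_years=s.age_sd_years,
        collapse_frac=s.collapse_frac,
        collapse_depth=s.collapse_depth,
        recovery_frac=s.recovery_frac,
        landuse_frac=s.landuse_frac,
    )
    refugia, n_ref = refugia_from_truth(bundle.truth, grid)
    target = TargetSpec(
        fossils=bundle.fossils,
        refugium_cells=refugia,
        expected_refugia_count=min(n_ref, 2),
    )
    model = RangeDynamicsModel(
        bundle.landscape,
        bundle.human_field,
        target,
        cfg.priors,
        raw_density=bundle.raw_density,
    )
    return model, bundle


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Run every stage and write artifacts plus a manifest.

    Stages: synthetic inputs (or load), POM calibration, ensemble, scenario
    counterfactuals, harvest scan, driver GAMs. Deterministic stages are
    bit-stable for a fixed configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed}

    try:
        model, bundle = build_model_from_config(cfg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("inputs", str(exc)) from exc

    try:
        if bundle is not None:
            bundle.landscape.to_netcdf(outdir / "landscape.nc")
            bundle.human_field.to_netcdf(outdir / "human.nc")
            write_fossils_csv(bundle.fossils, outdir / "fossils.csv")
            (outdir / "truth_params.yaml").write_text(
                yaml.safe_dump(bundle.params.to_dict())
            )
    except Exception as exc:
        raise PipelineError("synthetic", str(exc)) from exc

    try:
        fit = model.fit(
            round_sizes=cfg.round_sizes, tolerance=cfg.tolerance, seed=cfg.seed
        )
        pf = fit.params_frame()
        pf.to_csv(outdir / "posterior.csv", index=False)
        pd.DataFrame(
            fit.final_round["summaries"], columns=list(_pom.SUMMARY_NAMES)
        ).assign(distance=fit.final_round["distances"]).to_csv(
            outdir / "distances.csv", index=False
        )
        conv, overlap = fit.convergence()
        report = {
            "converged": bool(conv),
            "overlap": {k: float(v) for k, v in overlap.items()},
            "gof_p": float(fit.gof()),
            "n_accepted": len(fit.accepted_params),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("pom", str(exc)) from exc

    try:
        ens = fit.ensemble()
        np.savetxt(outdir / "ensemble_totals.csv", np.column_stack(
            [model.landscape.grid.times_bp, ens.totals]
        ), delimiter=",", header="time_bp,total_abundance", comments="")
    except Exception as exc:
        raise PipelineError("ensemble", str(exc)) from exc

    try:
        counterfactuals = {}
        for name in cfg.scenarios:
            spec = _scenarios.ScenarioSpec(name=name)
            counterfactuals[name] = _scenarios.scenario_ensemble(fit, spec)
        if counterfactuals:
            causes = _scenarios.attribute_extirpation(
                fit.accepted_results(), counterfactuals
            )
            np.savetxt(outdir / "extirpation_causes.csv", causes, fmt="%d", delimiter=",")
        scan = _scenarios.harvest_scan(fit)
        scan.to_csv(outdir / "harvest_scan.csv", index=False)
        report["harvest_scan_multipliers"] = len(scan)
    except Exception as exc:
        raise PipelineError("scenarios", str(exc)) from exc

    try:
        binned = _drivers.bin_drivers(
            fit.accepted_results(), model.landscape, model.human_field
        )
        binned.to_csv(outdir / "binned_drivers.csv", index=False)
        if len(binned.dropna()) >= 30:
            g0 = _drivers.fit_driver_model(binned)
            g1 = _drivers.fit_driver_model(
                binned, with_interactions=True, lambdas=g0.lambdas
            )
            stat, dof, p = _drivers.compare_models(g0, g1)
            report["driver_gam"] = {
                "ml_null": g0.ml_criterion,
                "ml_interaction": g1.ml_criterion,
                "chi2": float(stat),
                "df": float(dof),
                "p": float(p),
            }
    except Exception as exc:
        raise PipelineError("drivers", str(exc)) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2))

    # manifest: configuration + hashes of the key tabular outputs
    manifest["config"] = cfg.model_dump()
    hashes = {}
    for f in ("posterior.csv", "distances.csv", "harvest_scan.csv"):
        p = outdir / f
        if p.exists():
            hashes[f] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest["output_hashes"] = hashes
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return outdir
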