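"""End-to-end pipeline orchestration.

Stage order: synthetic landscape (or user rasters) → mined-land
suitability → scenario demand (LP + linear interpolation) → logit
fitting and yearly spatial allocation → landscape metrics → evaluation
(relative error, Kappa against a generator-truth reference run).
Every stage writes plain-text artifacts so stages are independently
re-runnable and the whole run is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, constants as C
from . import allocation, demand as demand_mod, evaluation, metrics as metrics_mod
from . import suitability
from .config import PipelineConfig
from .raster import LandUseGrid, read_factors, read_landuse, write_factors, write_landuse
from .synthetic import (
    SyntheticConfig,
    delineate_aml_patches,
    generate_landscape,
    true_probabilities,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    outdir: Path
    base: LandUseGrid
    final: LandUseGrid
    demands_2020: dict[int, float]
    relative_errors: dict[int, float]
    metrics: metrics_mod.MetricsReport
    kappa: float | None
    log_lines: list[str] = field(default_factory=list)


def _synthetic_config(config: PipelineConfig) -> SyntheticConfig:
    return SyntheticConfig(
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        n_active_cells=config.n_active_cells,
        n_aml_patches=config.n_aml_patches,
        clump_scale=config.clump_scale,
        seed=config.seed,
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 compute_reference_kappa: bool = True) -> PipelineResult:
    """Execute every stage and write the artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    note(f"minescape {__version__} | config {config.digest()} | seed {config.seed}")

    # --- synthetic landscape (or user rasters) -------------------------
    stage = "synth"
    try:
        syn_cfg = _synthetic_config(config)
        if config.base_map is not None:
            base = read_landuse(config.base_map)
            factors = read_factors(sorted(Path(config.factors_dir).glob("*.asc")))
            patchset = delineate_aml_patches(base)
            note(f"loaded base map {config.base_map} ({base.n_valid} cells)")
        else:
            base, factors, patchset = generate_landscape(syn_cfg)
            note(f"generated landscape: {base.n_valid} cells, "
                 f"{len(patchset)} AML patches")
        write_landuse(base, outdir / "base.asc")
        write_factors(factors, outdir / "factors")
        patchset.to_csv(outdir / "aml_patches.csv")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- mined-land suitability ----------------------------------------
    stage = "mls"
    try:
        criteria = suitability.CriteriaTable.default()
        results = suitability.assess_patchset(patchset, criteria)
        suitability.results_to_dataframe(results).to_csv(
            outdir / "suitability.csv", index=False)
        mls_bounds = suitability.aggregate_bounds(
            results, [p.area_hm2 for p in patchset])
        (outdir / "mls_bounds.json").write_text(json.dumps(mls_bounds, indent=1))
        note(f"MLS bounds (hm²): {mls_bounds}")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- scenario demand ------------------------------------------------
    stage = "demand"
    try:
        lp_bounds = None
        if config.use_mls_bounds:
            lp_bounds = {suitability.USE_TO_CLASS[u]: v for u, v in mls_bounds.items()}
        demands, solution = demand_mod.scenario_demand(
            config.scenario,
            bounds=lp_bounds,
            reclamation_slack=config.reclamation_slack,
            include_x12_in_total=config.include_x12_in_total,
        )
        for msg in solution.problem.notes:
            note(f"LP: {msg}")
        note(f"scenario {config.scenario!r} objective {solution.objective:.1f}")
        base_areas = {c: float(v) for c, v in base.class_areas().items()}
        base_total = sum(base_areas.values())
        target_total = sum(demands.values())
        if abs(base_total - target_total) > config.reclamation_slack:
            factor = base_total / target_total
            demands = {c: v * factor for c, v in demands.items()}
            note(f"demands rescaled by {factor:.6f} to the landscape total "
                 f"({base_total:.0f} hm²)")
        trajectory = demand_mod.interpolate_demand(
            base_areas, demands, config.base_year, config.horizon_year,
            cell_area_hm2=base.cell_area_hm2,
        )
        trajectory.to_csv(outdir / "demand.csv")
        (outdir / "lp_solution.json").write_text(json.dumps(
            {"objective": solution.objective, "x": solution.as_dict(),
             "demands": {C.CLASS_NAMES[k]: v for k, v in demands.items()}}, indent=1))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- logit fitting and allocation ------------------------------------
    stage = "simulate"
    try:
        models = allocation.fit_all_logits(base, factors)
        allocation.models_to_dataframe(models).to_csv(
            outdir / "logit_models.csv", index=False)
        aucs = {code: allocation.auc(m, base, factors) for code, m in models.items()}
        pd.Series({C.CLASS_NAMES[k]: v for k, v in aucs.items()}, name="auc") \
            .to_csv(outdir / "roc_auc.csv")
        note("ROC AUC per class: " + ", ".join(
            f"{C.CLASS_NAMES[k]}={v:.3f}" for k, v in sorted(aucs.items())))
        probs = {code: m.predict(factors, base.valid_mask) for code, m in models.items()}
        rules = allocation.TransitionRules(elas=config.elas_by_code())
        maps, states = allocation.simulate_with_states(
            base, trajectory, rules, probs,
            tolerance=config.tolerance, max_iter=config.max_iter,
            eta=config.eta, elas_mode=config.elas_mode,
        )
        (outdir / "maps").mkdir(exist_ok=True)
        for year, grid in zip(trajectory.years[1:], maps):
            write_landuse(grid, outdir / "maps" / f"map_{year}.asc")
        for year, st in zip(trajectory.years[1:], states):
            note(f"year {year}: {st.iterations} iterations, converged={st.converged}")
        final = maps[-1]
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- landscape metrics ----------------------------------------------
    stage = "metrics"
    try:
        report = metrics_mod.compute_metrics(
            final, connectivity=config.connectivity,
            connect_threshold=config.connect_threshold,
        )
        (outdir / "metrics.json").write_text(json.dumps(report.to_dict(), indent=1))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- evaluation -------------------------------------------------------
    stage = "evaluate"
    try:
        simulated = {c: float(v) for c, v in final.class_areas().items()}
        demand_2020 = {c: float(trajectory.areas.loc[config.horizon_year, c])
                       for c in trajectory.areas.columns}
        rel = evaluation.relative_error(demand_2020, simulated)
        crosstab = evaluation.transition_crosstab(base, final, focus=C.AML)
        crosstab.areas.to_csv(outdir / "aml_transitions.csv")
        kap = None
        if config.base_map is None and compute_reference_kappa:
            ref_probs = true_probabilities(syn_cfg, factors, base.valid_mask)
            ref_maps = allocation.simulate(
                base, trajectory, rules, ref_probs,
                tolerance=config.tolerance, max_iter=config.max_iter,
                eta=config.eta, elas_mode=config.elas_mode,
            )
            kap = evaluation.kappa(final, ref_maps[-1]).kappa
            note(f"Kappa against generator-truth reference: {kap:.4f}")
        payload = {
            "relative_error_pct": {C.CLASS_NAMES[k]: v for k, v in rel.items()},
            "kappa_vs_reference": kap,
        }
        (outdir / "evaluation.json").write_text(json.dumps(payload, indent=1))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    config.save(outdir / "config.yaml")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return PipelineResult(
        outdir=outdir,
        base=base,
        final=final,
        demands_2020=demands,
        relative_errors=rel,
        metrics=report,
        kappa=kap,
        log_lines=log,
    )
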