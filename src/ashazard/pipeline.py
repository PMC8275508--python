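"""End-to-end orchestration: simulate → screen → fit → map → exposure → health.

Each stage is a plain function taking explicit inputs; :func:`run_pipeline`
chains them, writes every report (screening table, combination and
coefficient tables, probability/exceedance/band rasters, exposure and
health tables) under an output directory, and records the seed and config
hash so a run can be replayed exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import hazard, health, io, preprocess, screening, synthetic
from .config import PipelineConfig
from .grids import GridGeometry

log = logging.getLogger("ashazard")


@dataclass
class PipelineResult:
    config: PipelineConfig
    stack: synthetic.PredictorStack
    wells: pd.DataFrame
    dataset: preprocess.BinaryDataset
    screening: dict[float, screening.ScreeningResult]
    summaries: dict[float, ens.EnsembleSummary]
    finals: dict[float, ens.FinalModel]
    cutoffs: dict[float, float]
    band_map: hazard.BandMap | None
    exposure: pd.DataFrame | None
    health_table: pd.DataFrame | None


def simulate_stage(cfg: PipelineConfig):
    """Generate the synthetic study region: stack, true model, wells, population."""
    geometry = GridGeometry(0.0, 0.0, cfg.cell_size, cfg.nrows, cfg.ncols)
    stack = synthetic.generate_stack(
        cfg.base_seed, cfg.nrows, cfg.ncols, cfg.n_continuous, cfg.n_categorical,
        cfg.smoothing_radius, geometry=geometry,
    )
    truth = synthetic.calibrate_true_model(
        stack, list(cfg.active_variables), list(cfg.true_coefficients),
        {t: synthetic.DEFAULT_EXCEEDANCE_FRACTIONS[t] for t in cfg.thresholds},
    )
    wells = synthetic.sample_wells(stack, truth, cfg.n_wells, cfg.base_seed + 1)
    density, _ = synthetic.generate_population(
        stack, cfg.base_seed + 2, cfg.total_population
    )
    log.info("simulate: %d wells on %dx%d stack of %d layers",
             len(wells), cfg.nrows, cfg.ncols, len(stack.layers))
    return stack, truth, wells, density


def model_stage(cfg: PipelineConfig, dataset, thresholds=None):
    """Screen and run the ensemble at each threshold; select final models."""
    thresholds = thresholds or cfg.thresholds
    screens, summaries, finals = {}, {}, {}
    for t in thresholds:
        scr = screening.screen(
            dataset, t, n_repeats=cfg.n_repeats, base_seed=cfg.base_seed,
            train_fraction=cfg.train_fraction, p_cutoff=cfg.p_cutoff,
            vif_cutoff=cfg.vif_cutoff, vif_variant=cfg.vif_variant,
        )
        screens[t] = scr
        if not scr.retained:
            log.warning("threshold %g: no variable survived screening", t)
            continue
        summ = ens.run_ensemble(
            dataset, t, scr.retained, n_runs=cfg.n_runs,
            base_seed=cfg.base_seed, train_fraction=cfg.train_fraction,
            hl_groups=cfg.hl_groups, hl_alpha=cfg.hl_alpha,
            start=cfg.stepwise_start,
        )
        summaries[t] = summ
        if summ.combinations:
            finals[t] = ens.select_final(summ)
            log.info(
                "threshold %g: %d/%d passed HL, final=%s AUC=%.3f",
                t, summ.n_passed, summ.n_runs, finals[t].variables,
                finals[t].mean_test_auc,
            )
    return screens, summaries, finals


def map_stage(cfg: PipelineConfig, dataset, finals, stack):
    """Probability grids, calibrated cutoffs, exceedance maps, band map."""
    cutoffs, exceed, probs = {}, {}, {}
    for t in cfg.map_thresholds:
        if t not in finals:
            continue
        fm = finals[t]
        grid = hazard.probability_grid(fm, stack, dataset.norm_stats)
        probs[t] = grid
        sample_probs = fm.predict(dataset.columns(fm.variables))
        if cfg.fixed_cutoff is not None:
            cut = cfg.fixed_cutoff
        else:
            curves = hazard.cutoff_curves(
                sample_probs, dataset.labels[t], cfg.cutoff_grid_step
            )
            cut = hazard.crossover_cutoff(curves)
        cutoffs[t] = cut
        exceed[t] = hazard.exceedance_grid(grid, cut)
    band_map = (
        hazard.pseudo_contour(exceed, stack.geometry, cutoffs) if exceed else None
    )
    return probs, cutoffs, band_map


def exposure_health_stage(cfg: PipelineConfig, band_map, density):
    """Exposure table and, when dose-response params are configured, health."""
    pops = health.band_population(
        band_map, density, band_map.geometry, cfg.density_threshold
    )
    exposure = health.exposed_population(pops, cfg.f_rural, cfg.f_urban)
    table = None
    if cfg.dr_params:
        params = {
            cancer: {sex: health.DoseResponseParams(**p) for sex, p in by_sex.items()}
            for cancer, by_sex in cfg.dr_params.items()
        }
        concs = cfg.band_concs or health.default_band_concentrations(cfg.map_thresholds)
        table = health.aggregate_health(
            exposure, {str(k): v for k, v in concs.items()},
            synthetic.default_age_structure(), params,
        )
    else:
        log.warning("health stage skipped: no dose-response parameters configured")
    return exposure, table


def run_pipeline(cfg: PipelineConfig, outdir) -> PipelineResult:
    """Run every stage on a synthetic study region and write all artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        stack, truth, wells, density = simulate_stage(cfg)
        io.write_wells(wells, outdir / "wells.csv")
        io.write_stack(stack, outdir / "stack")
        io.write_asc(density, stack.geometry, outdir / "population.asc")

        stage = "preprocess"
        report = preprocess.exclude_invalid(wells)
        dataset = preprocess.build_dataset(stack, report.table, cfg.thresholds)

        stage = "model"
        screens, summaries, finals = model_stage(cfg, dataset)
        screening.screening_report(list(screens.values())).to_csv(
            outdir / "screening.tsv", sep="\t"
        )
        pd.concat(
            {t: s.as_frame() for t, s in summaries.items()}, names=["threshold"]
        ).to_csv(outdir / "combinations.tsv", sep="\t")
        if finals:
            ens.coefficient_report(list(finals.values())).to_csv(
                outdir / "coefficients.tsv", sep="\t"
            )

        stage = "map"
        probs, cutoffs, band_map = map_stage(cfg, dataset, finals, stack)
        for t, grid in probs.items():
            io.write_asc(grid, stack.geometry, outdir / f"prob_{t:g}.asc")
        for t in cutoffs:
            io.write_model_json(
                finals[t], dataset.norm_stats, cutoffs[t],
                outdir / f"model_{t:g}.json",
            )
        exposure = table = None
        if band_map is not None:
            io.write_asc(
                np.where(band_map.bands < 0, np.nan, band_map.bands),
                band_map.geometry, outdir / "bands.asc",
            )
            (outdir / "bands_legend.json").write_text(
                json.dumps({i: lab for i, lab in enumerate(band_map.labels)}, indent=2)
            )
            stage = "exposure"
            exposure, table = exposure_health_stage(cfg, band_map, density)
            exposure.to_csv(outdir / "exposure.tsv", sep="\t")
            if table is not None:
                table.to_csv(outdir / "health.tsv", sep="\t")
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    (outdir / "runlog.json").write_text(
        json.dumps(
            {
                "config_hash": cfg.digest(),
                "base_seed": cfg.base_seed,
                "n_wells": int(len(wells)),
                "hl_passed": {str(t): s.n_passed for t, s in summaries.items()},
                "cutoffs": {str(t): c for t, c in cutoffs.items()},
            },
            indent=2,
        )
    )
    return PipelineResult(
        cfg, stack, wells, dataset, screens, summaries, finals, cutoffs,
        band_map, exposure, table,
    )
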