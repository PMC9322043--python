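"""End-to-end pipeline: cubes -> spectra -> models -> selection -> maps.

Order of operations: generate (or read) raw cubes; white/dark calibration;
ROI segmentation at the high-transmission band; mean ROI spectrum; spectral
crop to the effective range; SNV; SPXY split (2/3 calibration); full-spectrum
PLSR and LSSVM; CARS wavelength selection on the calibration set; simplified
PLSR and LSSVM on the selected wavelengths; four-row metrics table
(two learners x {full, selected} variables); pixel-wise chemical maps with
the best simplified model.

Every random choice is derived from one top-level seed, so reruns of the
same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .hsi_io import SpectraTable, apply_mask_mean_spectrum, calibrate_cube, crop_spectral_range, segment_roi
from .mapping import ChemicalMap, predict_pixelwise, render_map
from .preprocessing import snv, spxy_split
from .regression import (
    LSSVMRegressor,
    PLSRRegressor,
    compute_metrics,
    grid_search_lssvm,
    kfold_cv,
    select_n_lv,
)
from .selection import cars

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a reproducible run needs."""

    seed: int = 0
    storage_days: tuple = synthetic.DEFAULT_STORAGE_DAYS
    eggs_per_day: int = 18
    cube_shape: tuple = (64, 64)
    reference_cv: float = synthetic.REFERENCE_CV
    crop_min_nm: float = 435.0
    roi_band_nm: float = 700.4
    roi_threshold: float = 0.1
    calib_fraction: float = 2.0 / 3.0
    cv_folds: int = 5
    max_lv: int = 16
    lv_tol: float = 0.02
    lssvm_log2_range: tuple = (-8.0, 8.0)
    cars_runs: int = 100
    cars_mc_fraction: float = 0.8
    n_map_eggs: int = 3
    out_dir: str | None = None


@dataclass
class PipelineResult:
    """Computed artifacts of one run; ``bundle`` is the JSON-serializable part."""

    bundle: dict
    spectra: SpectraTable
    truth: pd.DataFrame
    split: object
    models: dict
    cars_result: object
    maps: dict = field(default_factory=dict)


class _StageTracker:
    """Names the failing stage in any pipeline abort."""

    def __init__(self):
        self.name = "setup"

    def __call__(self, name):
        self.name = name
        logger.info("pipeline stage: %s", name)


def _subset_stats(y: np.ndarray) -> dict:
    return {
        "n": int(y.size),
        "min": float(y.min()),
        "max": float(y.max()),
        "mean": float(y.mean()),
        "sd": float(y.std(ddof=1)),
        "range": float(y.max() - y.min()),
    }


def _model_row(name, n_vars, model, Xc, yc, Xp, yp, cv_metrics):
    cal = compute_metrics(yc, model.predict(Xc))
    pred = compute_metrics(yp, model.predict(Xp))
    return {
        "model": name,
        "variable_number": int(n_vars),
        "r2_c": cal.r2,
        "rmsec": cal.rmse,
        "r2_cv": cv_metrics.r2,
        "rmsecv": cv_metrics.rmse,
        "r2_p": pred.r2,
        "rmsep": pred.rmse,
    }


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    _stage = _StageTracker()
    try:
        return _run(config, _stage)
    except Exception as err:
        raise RuntimeError(f"pipeline aborted in stage '{_stage.name}': {err}") from err


def _run(config: PipelineConfig, _stage) -> PipelineResult:
    seeds = [int(s % 2**31) for s in np.random.SeedSequence(config.seed).generate_state(6)]
    seed_lv, seed_plsr_cv, seed_grid, seed_cars, seed_lssvm_cv, _ = seeds

    design = synthetic.StorageDesign(
        storage_days=config.storage_days,
        eggs_per_day=config.eggs_per_day,
        seed=config.seed,
    )

    _stage("generate + calibrate + extract spectra")
    ref_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(design.n_samples + 1)[0])
    white, dark = synthetic.make_reference_cubes(config.cube_shape, ref_rng)

    # eggs whose calibrated cubes are kept for mapping: evenly spaced over
    # the sample list (first egg of spread-out storage days)
    n = design.n_samples
    map_positions = sorted(
        {int(round(t)) for t in np.linspace(0, n - 1, min(config.n_map_eggs, n))}
    )
    spectra_rows, ids, truths = [], [], []
    kept_cubes = {}
    for pos, egg in enumerate(
        synthetic.iter_eggs(design, config.cube_shape, config.reference_cv)
    ):
        cal_cube = calibrate_cube(egg.cube, white, dark)
        mask = segment_roi(cal_cube, config.roi_band_nm, config.roi_threshold)
        spectra_rows.append(apply_mask_mean_spectrum(cal_cube, mask))
        ids.append(egg.truth.sample_id)
        truths.append(egg.truth)
        if pos in map_positions:
            kept_cubes[egg.truth.sample_id] = (cal_cube, mask, egg.truth)

    wavelengths = synthetic.make_wavelength_grid()
    table_full = SpectraTable(np.array(spectra_rows), wavelengths, ids)
    truth_df = pd.DataFrame([dataclasses.asdict(t) for t in truths])
    y = truth_df["reference_content"].to_numpy()

    _stage("crop + SNV")
    table = crop_spectral_range(table_full, config.crop_min_nm)
    X = snv(table.spectra)

    _stage("SPXY split")
    split = spxy_split(X, y, config.calib_fraction, sample_ids=ids)
    ci, pi = split.calibration_idx, split.prediction_idx
    Xc, yc, Xp, yp = X[ci], y[ci], X[pi], y[pi]

    _stage("full-spectrum PLSR")
    n_lv = select_n_lv(Xc, yc, config.max_lv, config.lv_tol, config.cv_folds, seed_lv)
    plsr_full = PLSRRegressor(n_components=n_lv).fit(Xc, yc)
    plsr_full_cv = kfold_cv(PLSRRegressor(n_components=n_lv), Xc, yc, config.cv_folds, seed_plsr_cv)

    _stage("full-spectrum LSSVM grid search")
    grid_full = grid_search_lssvm(Xc, yc, config.lssvm_log2_range, config.cv_folds, seed_grid)
    lssvm_full = LSSVMRegressor(gamma=grid_full.gamma, sigma=grid_full.sigma).fit(Xc, yc)
    lssvm_full_cv = kfold_cv(
        LSSVMRegressor(gamma=grid_full.gamma, sigma=grid_full.sigma),
        Xc, yc, config.cv_folds, seed_lssvm_cv,
    )

    _stage("CARS wavelength selection")
    cars_res = cars(
        Xc, yc,
        n_runs=config.cars_runs,
        cv_folds=config.cv_folds,
        mc_fraction=config.cars_mc_fraction,
        seed=seed_cars,
        wavelengths_nm=table.wavelengths_nm,
    )
    sel = cars_res.selected_indices
    Xc_s, Xp_s = Xc[:, sel], Xp[:, sel]

    _stage("simplified models")
    n_lv_s = select_n_lv(
        Xc_s, yc, min(config.max_lv, sel.size), config.lv_tol, config.cv_folds, seed_lv
    )
    plsr_sel = PLSRRegressor(n_components=n_lv_s).fit(Xc_s, yc)
    plsr_sel_cv = kfold_cv(PLSRRegressor(n_components=n_lv_s), Xc_s, yc, config.cv_folds, seed_plsr_cv)
    grid_sel = grid_search_lssvm(Xc_s, yc, config.lssvm_log2_range, config.cv_folds, seed_grid)
    lssvm_sel = LSSVMRegressor(gamma=grid_sel.gamma, sigma=grid_sel.sigma).fit(Xc_s, yc)
    lssvm_sel_cv = kfold_cv(
        LSSVMRegressor(gamma=grid_sel.gamma, sigma=grid_sel.sigma),
        Xc_s, yc, config.cv_folds, seed_lssvm_cv,
    )

    metrics_table = [
        _model_row("LSSVM", X.shape[1], lssvm_full, Xc, yc, Xp, yp, lssvm_full_cv),
        _model_row("PLSR", X.shape[1], plsr_full, Xc, yc, Xp, yp, plsr_full_cv),
        _model_row("LSSVM", sel.size, lssvm_sel, Xc_s, yc, Xp_s, yp, lssvm_sel_cv),
        _model_row("PLSR", sel.size, plsr_sel, Xc_s, yc, Xp_s, yp, plsr_sel_cv),
    ]

    _stage("chemical maps (simplified LSSVM)")
    maps, map_summaries = {}, []
    for sid, (cal_cube, mask, truth) in kept_cubes.items():
        cmap = predict_pixelwise(
            cal_cube, mask, lssvm_sel, feature_indices=sel, min_nm=config.crop_min_nm
        )
        maps[sid] = cmap
        vals = cmap.roi_values()
        map_summaries.append(
            {
                "sample_id": sid,
                "storage_day": int(truth.storage_day),
                "reference_content": float(truth.reference_content),
                "map_mean": float(vals.mean()),
                "map_sd": float(vals.std()),
                "n_pixels": int(vals.size),
            }
        )

    bundle = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_samples": int(n),
        "n_bands_total": int(wavelengths.size),
        "n_bands_effective": int(table.wavelengths_nm.size),
        "reference_stats": {
            "calibration": _subset_stats(yc),
            "prediction": _subset_stats(yp),
        },
        "split": {
            "calibration_ids": list(split.calibration_ids),
            "prediction_ids": list(split.prediction_ids),
        },
        "plsr_n_lv": int(n_lv),
        "plsr_n_lv_selected": int(n_lv_s),
        "lssvm_full_log2": [grid_full.log2_gamma, grid_full.log2_inv_sigma2],
        "lssvm_selected_log2": [grid_sel.log2_gamma, grid_sel.log2_inv_sigma2],
        "selected_wavelengths_nm": [float(w) for w in cars_res.wavelengths_nm],
        "n_selected_wavelengths": int(sel.size),
        "cars_best_run": int(cars_res.best_run),
        "metrics_table": metrics_table,
        "map_summaries": map_summaries,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "results.json", "w") as f:
            json.dump(bundle, f, indent=2)
        pd.DataFrame(metrics_table).to_csv(out / "metrics_table.csv", index=False)
        table.to_csv(out / "spectra_effective.csv")
        split.to_csv(out / "split.csv")
        truth_df.to_csv(out / "ground_truth.csv", index=False)
        cars_res.to_json(out / "cars_result.json")
        cars_res.trace_to_csv(out / "cars_trace.csv")
        for sid, cmap in maps.items():
            render_map(cmap, out / f"map_{sid}.png", title=sid)

    return PipelineResult(
        bundle=bundle,
        spectra=table,
        truth=truth_df,
        split=split,
        models={
            "plsr_full": plsr_full,
            "lssvm_full": lssvm_full,
            "plsr_selected": plsr_sel,
            "lssvm_selected": lssvm_sel,
        },
        cars_result=cars_res,
        maps=maps,
    )
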