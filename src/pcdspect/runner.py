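"""Experiment orchestration: the accuracy, detectability, and MLP-capacity sweeps.

This module is the reproducibility entry point.  Each sweep builds every
input from the library modules (phantoms, spectrum, DRF, calibration grids),
runs the decomposition models under matched conditions, and returns a tidy
``pandas.DataFrame``; CSVs are written when an output directory is set.
Every emitted row carries provenance (config hash, seed list, package
version).  Re-running with an identical config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .decomp import (CalibrationGrid, MLPHyper, decompose, fit_mlp, fit_poly2,
                     fit_svr, features_for_thicknesses, make_calibration_grid,
                     to_features)
from .detect import run_efroc_task
from .detector import (DetectorConfig, ThresholdConfig, apply_sharing,
                       build_drf, expected_bin_counts, fit_sharing_kernel,
                       rebin, sample_poisson)
from .evalq import DEFAULT_ROI_MARGIN_MM, measure_inserts
from .phantom import build_quant_phantom
from .physics import load_spectrum, photons_to_mas
from ._mlp import parameter_count

log = logging.getLogger("pcdspect")

#: the three evaluated open-beam fluences (photons per macro-pixel)
DEFAULT_DOSES_PHOTONS = (1e5, 2.3e6, 1e7)

SUPPORTED_GRIDS = (3, 5, 8)
SUPPORTED_THRESHOLD_COUNTS = (2, 3, 4, 5, 6)
SUPPORTED_MODELS = ("poly2", "mlp", "svr")


@dataclass
class ExperimentConfig:
    doses_photons: tuple[float, ...] = DEFAULT_DOSES_PHOTONS
    grid_sizes: tuple[int, ...] = (3, 5, 8)
    threshold_counts: tuple[int, ...] = (2, 4, 6)
    models: tuple[str, ...] = SUPPORTED_MODELS
    n_realizations: int = 5          # noise seeds for bias/RMSE
    efroc_r: int = 10                # paired realizations per EFROC point
    seed_base: int = 0
    grid_sweep_thresholds: int = 2   # M fixed during the calibration-grid sweep
    efroc_grid: int = 8              # calibration grid fixed for EFROC
    efroc_thresholds: int = 4        # M fixed for EFROC
    roi_margin_mm: float = DEFAULT_ROI_MARGIN_MM
    mlp_hyper: MLPHyper = field(default_factory=MLPHyper)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not set(self.grid_sizes) <= set(SUPPORTED_GRIDS):
            raise ValueError(f"grid sizes must be among {SUPPORTED_GRIDS}")
        if not set(self.threshold_counts) <= set(SUPPORTED_THRESHOLD_COUNTS):
            raise ValueError(
                f"threshold counts must be among {SUPPORTED_THRESHOLD_COUNTS}")
        if not set(self.models) <= set(SUPPORTED_MODELS):
            raise ValueError(f"models must be among {SUPPORTED_MODELS}")
        if self.n_realizations < 1 or self.efroc_r < 1:
            raise ValueError("need at least one realization")
        if any(d <= 0 for d in self.doses_photons):
            raise ValueError("doses must be positive")

    @property
    def doses_mas(self) -> tuple[float, ...]:
        return tuple(photons_to_mas(d) for d in self.doses_photons)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("doses_photons", "grid_sizes", "threshold_counts", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "mlp_hyper" in raw:
            h = dict(raw["mlp_hyper"])
            if "hidden" in h:
                h["hidden"] = tuple(h["hidden"])
            raw["mlp_hyper"] = MLPHyper(**h)
        if "detector" in raw:
            raw["detector"] = DetectorConfig(**raw["detector"])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _fit_models(config: ExperimentConfig, grid: CalibrationGrid) -> dict:
    models = {}
    for kind in config.models:
        if kind == "poly2":
            models[kind] = fit_poly2(grid)
        elif kind == "mlp":
            models[kind] = fit_mlp(grid, config.mlp_hyper)
        elif kind == "svr":
            models[kind] = fit_svr(grid)
    return models


def _provenance(config: ExperimentConfig, seeds: list[int]) -> dict:
    return {"config_hash": config.config_hash,
            "seeds": ";".join(map(str, seeds)),
            "version": __version__}


def run_accuracy_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Per-insert bias/RMSE over the calibration-grid and threshold sweeps.

    The grid sweep varies (dose, G) at fixed M; the threshold sweep varies M
    at the highest dose and the densest grid, matching the study design.
    Noisy stacks depend only on (dose, M, seed) and are shared across models
    and grids.
    """
    spectrum = load_spectrum()
    drf = build_drf(config.detector)
    kernel = fit_sharing_kernel(config.detector)
    phantom = build_quant_phantom()
    seeds = [config.seed_base + i for i in range(config.n_realizations)]
    prov = _provenance(config, seeds)

    def realizations(thresholds: ThresholdConfig, dose_mas: float):
        mean = expected_bin_counts(phantom.maps, spectrum, drf, thresholds,
                                   exposure_mas=dose_mas)
        shared = apply_sharing(mean, kernel)
        feats = []
        for seed in seeds:
            macro = rebin(sample_poisson(shared, seed))
            feats.append(to_features(macro, macro))
        return feats

    rows: list[dict] = []

    def evaluate(models: dict, feats, sweep: dict) -> None:
        for kind, model in models.items():
            decomposed = [decompose(model, f) for f in feats]
            for rec in measure_inserts(decomposed, phantom,
                                       margin=config.roi_margin_mm):
                rows.append({"model": kind, **sweep,
                             "insert_id": rec.insert_id,
                             "material": rec.material,
                             "t_true_mm": rec.t_true, "bias_mm": rec.bias,
                             "rmse_mm": rec.rmse, "std_mm": rec.std,
                             "n_realizations": rec.n_realizations, **prov})

    # calibration-grid sweep at fixed M
    m = config.grid_sweep_thresholds
    thresholds = ThresholdConfig.equally_spaced(m)
    grids = {g: make_calibration_grid(g, spectrum, drf, thresholds)
             for g in config.grid_sizes}
    models_by_grid = {g: _fit_models(config, grid)
                      for g, grid in grids.items()}
    for dose_mas in config.doses_mas:
        log.info("grid sweep: dose %.3f mAs", dose_mas)
        feats = realizations(thresholds, dose_mas)
        for g in config.grid_sizes:
            evaluate(models_by_grid[g], feats,
                     {"sweep": "grid", "dose_mAs": dose_mas, "grid": g,
                      "thresholds": m})

    # threshold sweep at the highest dose, densest grid
    dose_mas = max(config.doses_mas)
    g = max(config.grid_sizes)
    for m in config.threshold_counts:
        log.info("threshold sweep: M=%d", m)
        thresholds = ThresholdConfig.equally_spaced(m)
        grid = make_calibration_grid(g, spectrum, drf, thresholds)
        models = _fit_models(config, grid)
        feats = realizations(thresholds, dose_mas)
        evaluate(models, feats,
                 {"sweep": "threshold", "dose_mAs": dose_mas, "grid": g,
                  "thresholds": m})

    df = pd.DataFrame(rows)
    _maybe_write(df, config, "accuracy_sweep.csv")
    return df


def run_efroc_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """EFROC area per (task, model, dose) at fixed G and M."""
    spectrum = load_spectrum()
    drf = build_drf(config.detector)
    thresholds = ThresholdConfig.equally_spaced(config.efroc_thresholds)
    grid = make_calibration_grid(config.efroc_grid, spectrum, drf, thresholds)
    models = _fit_models(config, grid)
    prov = _provenance(config, [config.seed_base + i
                                for i in range(config.efroc_r)])

    rows = []
    for task in ("al_lcd", "pmma_lcd"):
        for dose_mas in config.doses_mas:
            for kind, model in models.items():
                log.info("EFROC %s %s %.3f mAs", task, kind, dose_mas)
                res = run_efroc_task(task, model, dose_mas, spectrum, drf,
                                     thresholds,
                                     detector_config=config.detector,
                                     r=config.efroc_r,
                                     seed_base=config.seed_base)
                rows.append({"task": task, "model": kind,
                             "dose_mAs": dose_mas, "A_FE": res.a_fe,
                             "sigma": res.sigma, "I": res.n_tp,
                             "J": res.n_fp, "N": res.n_absent,
                             "acceptance_radius_mm":
                                 res.sweep["acceptance_radius_mm"],
                             "fp_percentile": res.sweep["fp_percentile"],
                             "seed_base": config.seed_base, **prov})
    df = pd.DataFrame(rows)
    _maybe_write(df, config, "efroc_sweep.csv")
    return df


DEFAULT_STUDY_LAYERS = (1, 2, 3)
DEFAULT_STUDY_WIDTHS = (32, 64, 128, 256)


def run_mlp_architecture_study(config: ExperimentConfig,
                               layers: tuple[int, ...] = DEFAULT_STUDY_LAYERS,
                               widths: tuple[int, ...] = DEFAULT_STUDY_WIDTHS,
                               n_seeds: int = 3,
                               validation_n: int = 25) -> pd.DataFrame:
    """Validation RMSE and parameter count per MLP architecture.

    Each architecture is trained on the noise-free calibration grid (the
    EFROC G and M) over ``n_seeds`` initialization seeds and evaluated on a
    dense validation lattice over the calibration ranges, excluding training
    nodes.
    """
    spectrum = load_spectrum()
    drf = build_drf(config.detector)
    thresholds = ThresholdConfig.equally_spaced(config.efroc_thresholds)
    grid = make_calibration_grid(config.efroc_grid, spectrum, drf, thresholds)
    val_t, val_f = make_validation_set(grid, spectrum, drf, thresholds,
                                       n=validation_n)
    prov = _provenance(config, [config.seed_base + i for i in range(n_seeds)])

    rows = []
    for n_layers in layers:
        for width in widths:
            hidden = (width,) * n_layers
            rmse_al, rmse_pm = [], []
            for s in range(n_seeds):
                hyper = MLPHyper(hidden=hidden, seed=config.seed_base + s,
                                 dropout=config.mlp_hyper.dropout,
                                 weight_decay=config.mlp_hyper.weight_decay,
                                 lr=config.mlp_hyper.lr,
                                 epochs=config.mlp_hyper.epochs)
                model = fit_mlp(grid, hyper)
                pred = model.predict(val_f)
                err = pred - val_t
                rmse_al.append(np.sqrt(np.mean(err[:, 0] ** 2)))
                rmse_pm.append(np.sqrt(np.mean(err[:, 1] ** 2)))
            rmse_al, rmse_pm = np.array(rmse_al), np.array(rmse_pm)
            mean_rmse = 0.5 * (rmse_al + rmse_pm)
            rows.append({
                "layers": n_layers, "width": width,
                "n_parameters": parameter_count(thresholds.n_bins, hidden, 2),
                "rmse_al_mean": rmse_al.mean(), "rmse_al_std": rmse_al.std(),
                "rmse_pmma_mean": rmse_pm.mean(), "rmse_pmma_std": rmse_pm.std(),
                "rmse_mean": mean_rmse.mean(), "rmse_mean_std": mean_rmse.std(),
                "n_seeds": n_seeds, **prov})
    df = pd.DataFrame(rows)
    _maybe_write(df, config, "mlp_architecture_study.csv")
    return df


def make_validation_set(grid: CalibrationGrid, spectrum, drf, thresholds,
                        n: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Dense n x n thickness lattice over the calibration ranges, excluding
    points that coincide with training nodes; returns (thicknesses, features)."""
    al = np.linspace(*grid.al_range, n)
    pm = np.linspace(*grid.pmma_range, n)
    aa, pp = np.meshgrid(al, pm, indexing="ij")
    t = np.column_stack([aa.ravel(), pp.ravel()])
    d = np.abs(t[:, None, :] - grid.thicknesses[None, :, :])
    on_node = np.any(np.all(d < 1e-9, axis=-1), axis=1)
    t = t[~on_node]
    f = features_for_thicknesses(t, spectrum, drf, thresholds)
    return t, f


def _maybe_write(df: pd.DataFrame, config: ExperimentConfig, name: str) -> None:
    if config.output_dir is not None:
        out = pathlib.Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / name, index=False)
        log.info("wrote %s", out / name)
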