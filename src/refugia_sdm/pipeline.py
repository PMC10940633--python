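"""End-to-end orchestration: seascape -> prep -> CV -> ensemble -> uncertainty
-> projection -> fishing risk, with a JSON manifest for reproducibility.

A single master seed drives every stochastic stage through named substreams
(one :class:`numpy.random.SeedSequence` child per stage), so individual
stages can be re-run in isolation without disturbing the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import (data_prep, ensemble as ens, fishing_risk, projection_refugia,
               synthetic_seascape, uncertainty)
from .ensemble import CVSettings
from .raster_core import GridSpec, write_raster
from .synthetic_seascape import PREDICTOR_NAMES, SurveyDesign, TruthParams

logger = logging.getLogger(__name__)

_STAGE_NAMES = ("simulate", "prep", "cv", "ensemble", "uncertainty",
                "project", "risk")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.code = f"stage_error:{stage}"


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline; defaults are the study settings."""

    # working grid (cell-center registration, degrees); the synthetic basin
    # spans ~1000 km a side so 250-km blocking yields a usable checkerboard
    lon_min: float = 10.0
    lat_min: float = 34.0
    cell_size: float = 0.15
    n_rows: int = 60
    n_cols: int = 60
    # synthetic seascape / survey
    truth: dict = field(default_factory=dict)       # TruthParams overrides
    n_survey_stations: int = 800
    n_presence_only: int = 40
    presence_only_regions: list = field(default_factory=lambda: [])
    # data preparation
    pseudo_absence_max_depth: float = 1000.0
    # cross-validation design
    block_size_km: float = 250.0
    n_folds: int = 5
    n_repeats: int = 30
    algorithms: tuple = ("gam", "rf")
    k_max: int = 4
    rf_trees: int = 500
    n_importance_permutations: int = 10
    compute_curves: bool = True
    curve_points: int = 100
    curve_background_max: int = 250
    # ensemble / uncertainty / projection / risk
    retention_fraction: float = 0.25
    buffer_km: float = 20.0
    occ_threshold: float = 0.5
    variogram_kind: str = "spherical"
    study_max_depth: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.algorithms = tuple(self.algorithms)
        self.presence_only_regions = [tuple(b) for b in self.presence_only_regions]
        if not self.presence_only_regions:
            # default: one presence-only box over the northern continental
            # slope, where both presences and <1000 m cells are plentiful
            lon_hi = self.lon_min + (self.n_cols - 1) * self.cell_size
            lat_hi = self.lat_min + (self.n_rows - 1) * self.cell_size
            self.presence_only_regions = [(
                self.lon_min + 0.10 * (lon_hi - self.lon_min),
                self.lat_min + 0.55 * (lat_hi - self.lat_min),
                self.lon_min + 0.50 * (lon_hi - self.lon_min),
                self.lat_min + 0.95 * (lat_hi - self.lat_min),
            )]

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.lon_min, self.lat_min, self.cell_size,
                        self.n_rows, self.n_cols)

    def truth_params(self) -> TruthParams:
        return TruthParams(**self.truth)

    def cv_settings(self) -> CVSettings:
        return CVSettings(
            k_max=self.k_max, rf_trees=self.rf_trees,
            n_importance_permutations=self.n_importance_permutations,
            compute_curves=self.compute_curves, curve_points=self.curve_points,
            curve_background_max=self.curve_background_max,
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["algorithms"] = list(self.algorithms)
        d["presence_only_regions"] = [list(b) for b in self.presence_only_regions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    idx = _STAGE_NAMES.index(stage)
    return int(np.random.SeedSequence((master, idx)).generate_state(1)[0] % (2 ** 31))


def collinearity_report(dataset: pd.DataFrame,
                        predictors: list[str] = list(PREDICTOR_NAMES),
                        flag_threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between predictors (advisory only)."""
    if len(dataset) < 3:
        raise ValueError("collinearity report needs >= 3 records")
    rows = []
    for i, a in enumerate(predictors):
        for b in predictors[i:]:
            xa = dataset[a].to_numpy(float)
            xb = dataset[b].to_numpy(float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                rho = np.nan
            elif a == b:
                rho = 1.0
            else:
                rho = float(spearmanr(xa, xb).statistic)
            rows.append({"predictor_a": a, "predictor_b": b, "spearman_rho": rho,
                         "flagged": bool(abs(rho) >= flag_threshold) if np.isfinite(rho) else True})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir=None,
                 write_artifacts: bool = True) -> dict:
    """Execute every stage in order and return the manifest dict.

    With ``write_artifacts`` the ensemble/uncertainty/change/risk layers are
    written as GeoTIFF and the tables as CSV under ``outdir``; the manifest
    itself is always returned and, when an outdir is given, written as
    ``manifest.json``.
    """
    t_start = time.time()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(),
                      "config_hash": config.config_hash(),
                      "stages": {}}
    predictors = list(PREDICTOR_NAMES)

    # --- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        params = config.truth_params()
        scape = synthetic_seascape.generate_seascape(
            config.grid, params, seed=_stage_seed(config.seed, stage))
        design = SurveyDesign(
            n_survey_stations=config.n_survey_stations,
            presence_only_regions=config.presence_only_regions,
            n_presence_only=config.n_presence_only,
            max_survey_depth=config.study_max_depth,
            seed=_stage_seed(config.seed, stage) + 1,
        )
        records = synthetic_seascape.sample_occurrences(
            scape["truth"], scape["present"]["bathymetry"], design)
        manifest["stages"][stage] = {
            "n_records": int(len(records)),
            "n_presences": int((records["detected"] == 1).sum()),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- prep --------------------------------------------------------------
    stage = "prep"
    try:
        with_pa = data_prep.add_pseudo_absences(
            records, config.presence_only_regions,
            scape["present"]["bathymetry"],
            seed=_stage_seed(config.seed, stage),
            max_depth=config.pseudo_absence_max_depth)
        aggregated = data_prep.aggregate_to_grid(
            with_pa, config.grid, seed=_stage_seed(config.seed, stage) + 1)
        dataset = data_prep.extract_predictors(aggregated, scape["present"])
        manifest["stages"][stage] = {
            "n_pseudo_absences": int(len(with_pa) - len(records)),
            "n_aggregated": int(len(aggregated)),
            "n_model_records": int(len(dataset)),
            "n_model_presences": int((dataset["detected"] == 1).sum()),
            "n_dropped_nodata": dataset.attrs.get("n_dropped_nodata", 0),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- cross-validation --------------------------------------------------
    stage = "cv"
    try:
        runs = ens.run_cross_validation(
            dataset, {"present": scape["present"], "future": scape["future"]},
            predictors, n_folds=config.n_folds, n_repeats=config.n_repeats,
            algorithms=config.algorithms, block_size_km=config.block_size_km,
            seed=_stage_seed(config.seed, stage), settings=config.cv_settings())
        metrics = ens.runs_metric_table(runs)
        manifest["stages"][stage] = {
            "n_runs": int(len(runs)),
            "n_expected": config.n_repeats * config.n_folds * len(config.algorithms),
            "mean_auc": float(metrics["auc"].mean()),
            "sd_auc": float(metrics["auc"].std(ddof=1)),
            "mean_tss": float(metrics["tss"].mean()),
            "mean_sensitivity": float(metrics["sensitivity"].mean()),
            "mean_specificity": float(metrics["specificity"].mean()),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- ensemble ----------------------------------------------------------
    stage = "ensemble"
    try:
        result = ens.build_ensemble(runs, dataset)
        manifest["stages"][stage] = {
            "n_retained": result.n_retained,
            "ensemble_threshold": float(result.ensemble_threshold),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- uncertainty -------------------------------------------------------
    stage = "uncertainty"
    try:
        retained = [r for r in runs if r.run_id in set(result.retained_ids)]
        calib = uncertainty.calibration_uncertainty(retained, "present")
        survey = records[records["source"] == "survey"]
        vgm = uncertainty.fit_variogram(
            survey["lon"], survey["lat"], survey["detected"].to_numpy(float),
            kind=config.variogram_kind)
        kriged = uncertainty.krige_occurrence(
            survey, vgm, config.grid, buffer_km=config.buffer_km)
        present_binary = projection_refugia.binarize_ensemble(
            result.suitability_present, result.ensemble_threshold)
        agreement = uncertainty.observation_agreement(
            present_binary, kriged, occ_threshold=config.occ_threshold)
        disagreement = None
        if set(config.algorithms) == {"gam", "rf"}:
            disagreement = uncertainty.algorithm_disagreement(
                retained, dataset, "present")
        manifest["stages"][stage] = {
            "variogram": {"kind": vgm.kind, "nugget": vgm.nugget,
                          "sill": vgm.sill, "range_km": vgm.range_km},
            "kriged_cells": int(kriged.n_valid),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- projection --------------------------------------------------------
    stage = "project"
    try:
        bathy = scape["present"]["bathymetry"]
        pres_b = projection_refugia.apply_depth_mask(
            present_binary, bathy, config.study_max_depth)
        fut_b = projection_refugia.apply_depth_mask(
            projection_refugia.binarize_ensemble(result.suitability_future,
                                                 result.ensemble_threshold),
            bathy, config.study_max_depth)
        change = projection_refugia.classify_change(pres_b, fut_b)
        summary = projection_refugia.habitat_change_summary(change)
        manifest["stages"][stage] = {
            k: summary[k] for k in ("loss_pct", "gain_pct", "refugia_pct",
                                    "present_suitable_km2", "future_suitable_km2")
        }
        manifest["stages"][stage]["areas_km2"] = summary["areas_km2"]
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- fishing risk ------------------------------------------------------
    stage = "risk"
    try:
        risk = fishing_risk.risk_levels(scape["fishing"])
        refugia_mask = change.class_mask("refugia").astype(float)
        refugia_layer = change.classes.with_values(
            refugia_mask, nodata=change.classes.nodata, name="refugia", units="0/1")
        observed = projection_refugia.binarize_ensemble(kriged, config.occ_threshold)
        tables = [
            fishing_risk.overlay_risk(risk, observed, scape["regions"], "observed"),
            fishing_risk.overlay_risk(risk, pres_b, scape["regions"], "suitable"),
            fishing_risk.overlay_risk(risk, refugia_layer, scape["regions"], "refugia"),
        ]
        overlay = pd.concat(tables, ignore_index=True)
        manifest["stages"][stage] = {
            "risk_edges_hours": list(risk.edges_hours),
            "overlay_total_km2": float(overlay.loc[overlay["region"] == "basin",
                                                   "area_km2"].sum()),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    manifest["elapsed_s"] = round(time.time() - t_start, 2)

    if out is not None and write_artifacts:
        write_raster(result.suitability_present, out / "suitability_present.tif")
        write_raster(result.suitability_future, out / "suitability_future.tif")
        write_raster(calib, out / "calibration_uncertainty.tif")
        write_raster(kriged, out / "kriged_occurrence.tif")
        write_raster(agreement, out / "observation_agreement.tif")
        if disagreement is not None:
            write_raster(disagreement, out / "algorithm_disagreement.tif")
        write_raster(change.classes, out / "habitat_change.tif")
        write_raster(risk.classes, out / "fishing_risk.tif")
        metrics.to_csv(out / "run_metrics.csv", index=False)
        dataset.to_csv(out / "model_dataset.csv", index=False)
        overlay.to_csv(out / "risk_overlay.csv", index=False)
        projection_refugia.change_summary_frame(change).to_csv(
            out / "change_areas.csv", index=False)
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return manifest
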