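"""Repeated spatial-block CV engine, model retention and binary-map ensemble.

The engine fits every (repeat, fold, algorithm) combination — with the
default settings, 30 repeats x 5 folds x {GAM, RF} = 300 models — evaluating
each on its spatially held-out fold.  The weakest quarter of models by
held-out AUC is discarded; the ensemble habitat-suitability surface is the
per-cell mean of the remaining models' binary (0/1) maps, and the ensemble
threshold re-optimizes TSS of that surface against the full aggregated
dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, sdm_models, spatial_cv
from .evaluation import ModelEvaluation, optimal_tss_threshold
from .raster_core import PredictorStack, RasterLayer, RasterError
from .sdm_models import FittedModel, ResponseCurve

logger = logging.getLogger(__name__)


class EnsembleError(ValueError):
    pass


@dataclass
class ModelRun:
    """One fitted learner with its evaluation and per-scenario binary maps."""

    run_id: int
    algorithm: str
    repeat_id: int
    fold_id: int
    evaluation: ModelEvaluation
    present_binary: RasterLayer
    future_binary: RasterLayer
    importance: pd.Series | None = None
    response_curves: dict[str, ResponseCurve] = field(default_factory=dict)
    model: FittedModel | None = None


@dataclass
class EnsembleResult:
    suitability_present: RasterLayer
    suitability_future: RasterLayer
    ensemble_threshold: float
    n_retained: int
    retained_ids: list[int]


@dataclass
class CVSettings:
    """Knobs of the CV engine that are not part of the study design.

    ``rf_trees`` defaults to the original tool's 500; smaller values trade
    forest vote granularity for speed.  Response curves and importances can
    be restricted or disabled for exploratory runs.
    """

    k_max: int = 4
    rf_trees: int = 500
    n_importance_permutations: int = 10
    compute_importance: bool = True
    compute_curves: bool = True
    curve_points: int = 100
    curve_background_max: int = 250
    curve_predictors: tuple[str, ...] | None = None  # None = all


def _binarize(prob_map: RasterLayer, threshold: float) -> RasterLayer:
    values = np.where(prob_map.values >= threshold, 1.0, 0.0)
    values[prob_map.nodata] = np.nan
    return prob_map.with_values(values, name=prob_map.name + "_binary",
                                units="0/1")


def run_cross_validation(dataset: pd.DataFrame,
                         stacks: dict[str, PredictorStack],
                         predictors: list[str],
                         n_folds: int = 5,
                         n_repeats: int = 30,
                         algorithms: tuple[str, ...] = ("gam", "rf"),
                         block_size_km: float = 250.0,
                         seed: int = 0,
                         settings: CVSettings | None = None) -> list[ModelRun]:
    """Fit and evaluate every (repeat, fold, algorithm) model run.

    Each model is fitted on the out-of-fold records, evaluated on the held-out
    fold (AUC, TSS, sensitivity, specificity and the TSS-optimal threshold of
    the held-out predictions), and its probability maps for both scenarios are
    binarized with that run's own threshold.  Runs whose held-out fold is
    single-class cannot be evaluated and are excluded with a logged reason.
    """
    if settings is None:
        settings = CVSettings()
    if "present" not in stacks or "future" not in stacks:
        raise EnsembleError("stacks must provide 'present' and 'future'")
    blocks = spatial_cv.build_blocks(dataset, block_size_km)
    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.generate_state(n_repeats)
    model_seeds = np.random.SeedSequence((seed, 1)).generate_state(
        n_repeats * n_folds * len(algorithms))
    runs: list[ModelRun] = []
    run_id = 0
    seed_idx = 0
    for rep in range(1, n_repeats + 1):
        fa = spatial_cv.assign_folds(blocks, n_folds=n_folds,
                                     seed=int(repeat_seeds[rep - 1]), repeat_id=rep)
        for fold in range(1, n_folds + 1):
            test_mask = fa.fold_of_record == fold
            train = dataset[~test_mask]
            test = dataset[test_mask]
            for algo in algorithms:
                sub_seed = int(model_seeds[seed_idx]) % (2 ** 31)
                seed_idx += 1
                try:
                    run = _one_run(run_id, algo, rep, fold, train, test, stacks,
                                   predictors, sub_seed, settings)
                except (sdm_models.ModelFitError, evaluation.EvaluationError) as exc:
                    logger.warning("run (repeat=%d fold=%d algo=%s) failed: %s",
                                   rep, fold, algo, exc)
                    continue
                runs.append(run)
                run_id += 1
    logger.info("cross-validation produced %d successful run(s)", len(runs))
    return runs


def _one_run(run_id, algo, rep, fold, train, test, stacks, predictors,
             sub_seed, settings: CVSettings) -> ModelRun:
    if algo == "gam":
        model = sdm_models.fit_gam(train, predictors, k_max=settings.k_max,
                                   repeat_id=rep, fold_id=fold)
    elif algo == "rf":
        model = sdm_models.fit_rf(train, predictors, n_trees=settings.rf_trees,
                                  seed=sub_seed, repeat_id=rep, fold_id=fold)
    else:
        raise EnsembleError(f"unknown algorithm {algo!r}")
    pred = model.predict(test)
    ev = evaluation.evaluate_predictions(test["detected"].to_numpy(), pred)
    present_prob = sdm_models.predict_map(model, stacks["present"])
    future_prob = sdm_models.predict_map(model, stacks["future"])
    run = ModelRun(
        run_id=run_id, algorithm=algo, repeat_id=rep, fold_id=fold,
        evaluation=ev,
        present_binary=_binarize(present_prob, ev.threshold),
        future_binary=_binarize(future_prob, ev.threshold),
        model=model,
    )
    if settings.compute_importance:
        run.importance = evaluation.permutation_importance(
            model, test, n_permutations=settings.n_importance_permutations,
            seed=sub_seed)
    if settings.compute_curves:
        background = train
        if len(background) > settings.curve_background_max:
            bg_rng = np.random.default_rng(sub_seed)
            background = background.sample(settings.curve_background_max,
                                           random_state=bg_rng.integers(2 ** 31))
        names = settings.curve_predictors or predictors
        for name in names:
            run.response_curves[name] = sdm_models.response_curve(
                model, name, background, n_points=settings.curve_points)
    return run


def retain_models(runs: list[ModelRun]) -> list[ModelRun]:
    """Discard the first quartile (count-based: the ``floor(n/4)`` lowest-AUC
    runs, ties broken by run id) so that e.g. 300 runs retain exactly 225."""
    if len(runs) < 4:
        raise EnsembleError("need at least 4 runs to apply quartile retention")
    n_drop = len(runs) // 4
    order = sorted(runs, key=lambda r: (r.evaluation.auc, r.run_id))
    dropped = {r.run_id for r in order[:n_drop]}
    return [r for r in runs if r.run_id not in dropped]


def ensemble_suitability(retained: list[ModelRun], scenario: str) -> RasterLayer:
    """Per-cell mean of the retained runs' binary maps for one scenario."""
    if not retained:
        raise EnsembleError("no retained runs")
    maps = [r.present_binary if scenario == "present" else r.future_binary
            for r in retained]
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid != grid:
            raise RasterError("retained binary maps are not on one grid")
    stackv = np.stack([m.masked() for m in maps])
    values = stackv.mean(axis=0)  # NaN wherever any retained map is nodata
    mask = ~np.isfinite(values)
    return RasterLayer(grid, values, mask, name=f"ensemble_{scenario}",
                       units="fraction of models")


def ensemble_threshold(suitability_present: RasterLayer,
                       dataset: pd.DataFrame) -> float:
    """TSS-optimal threshold of the ensemble surface against all records."""
    grid = suitability_present.grid
    row = dataset["row"].to_numpy(int) if "row" in dataset.columns else None
    if row is None:
        row, col = grid.cell_of(dataset["lon"].to_numpy(), dataset["lat"].to_numpy())
    else:
        col = dataset["col"].to_numpy(int)
    suit = suitability_present.values[row, col]
    valid = ~suitability_present.nodata[row, col]
    if not valid.all():
        logger.warning("%d record(s) on nodata ensemble cells ignored",
                       int((~valid).sum()))
    return optimal_tss_threshold(dataset["detected"].to_numpy()[valid], suit[valid])


def build_ensemble(runs: list[ModelRun], dataset: pd.DataFrame) -> EnsembleResult:
    """Retention + mean-of-binaries maps + ensemble threshold in one step."""
    retained = retain_models(runs)
    present = ensemble_suitability(retained, "present")
    future = ensemble_suitability(retained, "future")
    thr = ensemble_threshold(present, dataset)
    return EnsembleResult(
        suitability_present=present, suitability_future=future,
        ensemble_threshold=thr, n_retained=len(retained),
        retained_ids=[r.run_id for r in retained],
    )


def runs_metric_table(runs: list[ModelRun]) -> pd.DataFrame:
    """Tidy per-run metric table keyed by (repeat, fold, algorithm)."""
    rows = []
    for r in runs:
        rows.append({
            "run_id": r.run_id, "repeat": r.repeat_id, "fold": r.fold_id,
            "algorithm": r.algorithm, "auc": r.evaluation.auc,
            "tss": r.evaluation.tss, "sensitivity": r.evaluation.sensitivity,
            "specificity": r.evaluation.specificity,
            "threshold": r.evaluation.threshold,
        })
    return pd.DataFrame(rows)
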