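"""The two learners behind one interface: spline GAM and random forest.

Both learners consume a training table with a binary ``detected`` column and
one column per predictor, and expose ``predict(table) -> probability``.  The
GAM is a binomial GLM with a logit link and one B-spline smooth per
predictor, basis dimension capped at 4 (three spline columns per predictor
after the identifiability constraint, plus a global intercept — the classic
``k = 4`` regression-spline setup).  The random forest is a probability
forest (class-vote fraction) of CART trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from statsmodels.gam.smooth_basis import BSplines

from .raster_core import PredictorStack, RasterLayer


class ModelFitError(RuntimeError):
    pass


@dataclass
class ResponseCurve:
    """Partial-dependence curve of one predictor: mean predicted probability
    over the background table with the predictor overwritten by each x."""

    predictor: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("response-curve x grid must be strictly increasing")
        if np.any((self.y < 0) | (self.y > 1)):
            raise ValueError("response-curve values outside [0, 1]")

    @property
    def argmax_x(self) -> float:
        return float(self.x[int(np.argmax(self.y))])


@dataclass
class FittedModel:
    """One fitted learner plus the bookkeeping the CV engine needs."""

    algorithm: str                      # "gam" | "rf"
    predictor_names: list[str]
    repeat_id: int = 0
    fold_id: int = 0
    training_size: int = 0
    _state: Any = field(default=None, repr=False)

    def predict(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predicted probability of presence for each row."""
        X = _as_matrix(table, self.predictor_names)
        if self.algorithm == "gam":
            basis, res, lo, hi = self._state
            Xc = np.clip(X, lo, hi)  # clamp: spline basis is undefined off-range
            design = np.column_stack([np.ones(len(Xc)), basis.transform(Xc)])
            p = res.predict(design)
        elif self.algorithm == "rf":
            p = self._state.predict_proba(X)[:, 1]
        else:  # pragma: no cover - guarded at construction
            raise ModelFitError(f"unknown algorithm {self.algorithm!r}")
        return np.clip(np.asarray(p, float), 0.0, 1.0)


def _as_matrix(table, names: list[str]) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        missing = [n for n in names if n not in table.columns]
        if missing:
            raise ModelFitError(f"missing predictor column(s): {missing}")
        return table[names].to_numpy(float)
    X = np.asarray(table, float)
    if X.shape[1] != len(names):
        raise ModelFitError("matrix width does not match predictor_names")
    return X


def _check_training(table: pd.DataFrame, predictors: list[str]) -> tuple[np.ndarray, np.ndarray]:
    y = table["detected"].to_numpy(int)
    X = _as_matrix(table, predictors)
    if not np.isfinite(X).all():
        raise ModelFitError("missing predictor values in training table")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ModelFitError("training data needs at least 2 presences and 2 absences")
    return X, y


def fit_gam(train_table: pd.DataFrame, predictors: list[str], k_max: int = 4,
            repeat_id: int = 0, fold_id: int = 0) -> FittedModel:
    """Binomial logit GAM with basis dimension <= ``k_max`` per predictor."""
    X, y = _check_training(train_table, predictors)
    degree = min(3, k_max - 1)
    # statsmodels drops one column per smooth for identifiability, so df=k_max
    # yields k_max-1 free columns per predictor plus the shared intercept
    basis = BSplines(X, df=[k_max] * X.shape[1], degree=[degree] * X.shape[1],
                     variable_names=list(predictors))
    design = np.column_stack([np.ones(len(X)), basis.basis])
    try:
        res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:  # convergence / separation failures
        raise ModelFitError(f"GAM fit failed: {exc}") from exc
    if not res.converged:
        raise ModelFitError("GAM IRLS did not converge")
    lo, hi = X.min(axis=0), X.max(axis=0)
    return FittedModel("gam", list(predictors), repeat_id, fold_id, len(X),
                       _state=(basis, res, lo, hi))


def fit_rf(train_table: pd.DataFrame, predictors: list[str], n_trees: int = 500,
           seed: int = 0, repeat_id: int = 0, fold_id: int = 0) -> FittedModel:
    """Probability random forest of CART trees (sqrt-mtry, unlimited depth)."""
    X, y = _check_training(train_table, predictors)
    rf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                random_state=int(seed) % (2 ** 31), n_jobs=1)
    rf.fit(X, y)
    return FittedModel("rf", list(predictors), repeat_id, fold_id, len(X), _state=rf)


def predict_map(model: FittedModel, stack: PredictorStack) -> RasterLayer:
    """Per-cell probability of presence; nodata where any predictor is nodata."""
    missing = [n for n in model.predictor_names if n not in stack.layers]
    if missing:
        raise ModelFitError(f"stack is missing predictor layer(s): {missing}")
    grid = stack.grid
    mask = np.zeros(grid.shape, bool)
    for name in model.predictor_names:
        mask |= stack[name].nodata
    valid = ~mask
    X = np.column_stack([stack[n].values[valid] for n in model.predictor_names])
    values = np.full(grid.shape, np.nan)
    values[valid] = model.predict(X)
    return RasterLayer(grid, values, mask, name=f"suitability_{model.algorithm}",
                       units="probability")


def response_curve(model, predictor: str, background: pd.DataFrame,
                   n_points: int = 100) -> ResponseCurve:
    """Partial-dependence response of one predictor over a background table."""
    if predictor not in model.predictor_names:
        raise ModelFitError(f"{predictor!r} is not a model predictor")
    col = background[predictor].to_numpy(float)
    lo, hi = col.min(), col.max()
    if hi <= lo:
        raise ModelFitError(f"predictor {predictor!r} is constant in the background")
    xs = np.linspace(lo, hi, n_points)
    X = background[model.predictor_names].to_numpy(float)
    j = model.predictor_names.index(predictor)
    # evaluate all grid points in one batched prediction
    n = len(X)
    Xrep = np.repeat(X, len(xs), axis=0)
    Xrep[:, j] = np.tile(xs, n)
    p = model.predict(Xrep).reshape(n, len(xs))
    return ResponseCurve(predictor=predictor, x=xs, y=p.mean(axis=0))
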