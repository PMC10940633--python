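"""Performance metrics, TSS-optimal thresholding and permutation importance.

AUC follows the Mann-Whitney convention (ties count one half).  Binary
classification is closed on the presence side everywhere in the package:
a cell or record is called *present* iff its score is ``>= threshold``.
The TSS-optimal threshold scans the observed score values and returns the
smallest candidate attaining the maximum TSS, which favors sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class EvaluationError(ValueError):
    pass


@dataclass
class ModelEvaluation:
    auc: float
    tss: float
    sensitivity: float
    specificity: float
    threshold: float

    def __post_init__(self) -> None:
        if abs(self.tss - (self.sensitivity + self.specificity - 1.0)) > 1e-12:
            raise EvaluationError("tss must equal sensitivity + specificity - 1")


def _check_classes(obs: np.ndarray) -> np.ndarray:
    obs = np.asarray(obs, int)
    if obs.min(initial=1) < 0 or obs.max(initial=0) > 1:
        raise EvaluationError("observations must be 0/1")
    if len(np.unique(obs)) < 2:
        raise EvaluationError("both classes must be present")
    return obs


def roc_auc(obs, pred) -> float:
    """P(random presence outranks random absence), ties counted half."""
    obs = _check_classes(obs)
    pred = np.asarray(pred, float)
    if len(obs) != len(pred):
        raise EvaluationError("obs and pred lengths differ")
    ranks = rankdata(pred)
    n1 = int(obs.sum())
    n0 = len(obs) - n1
    u = ranks[obs == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def confusion_metrics(obs, pred, threshold: float) -> tuple[float, float, float]:
    """(sensitivity, specificity, tss) when calling presence iff pred >= t."""
    obs = _check_classes(obs)
    pred = np.asarray(pred, float)
    call = pred >= threshold
    tp = int(np.sum(call & (obs == 1)))
    fn = int(np.sum(~call & (obs == 1)))
    tn = int(np.sum(~call & (obs == 0)))
    fp = int(np.sum(call & (obs == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens, spec, sens + spec - 1.0


def optimal_tss_threshold(obs, pred) -> float:
    """Smallest candidate threshold maximizing TSS.

    Candidates are the sorted unique predicted values plus {0, 1}.
    """
    obs = _check_classes(obs)
    pred = np.asarray(pred, float)
    candidates = np.unique(np.concatenate([pred, [0.0, 1.0]]))
    n1 = int(obs.sum())
    n0 = len(obs) - n1
    # vectorized scan: counts of presences/absences at score >= t
    order = np.argsort(pred, kind="mergesort")
    sp = pred[order]
    so = obs[order]
    # for each candidate, index of first score >= t
    first = np.searchsorted(sp, candidates, side="left")
    cum_pres = np.concatenate([np.cumsum(so[::-1])[::-1], [0]])
    tp = cum_pres[first]
    n_ge = len(sp) - first
    fp = n_ge - tp
    sens = tp / n1
    spec = (n0 - fp) / n0
    tss = sens + spec - 1.0
    best = tss.max()
    return float(candidates[np.flatnonzero(tss >= best - 1e-15)[0]])


def evaluate_predictions(obs, pred) -> ModelEvaluation:
    """Full evaluation at the TSS-optimal threshold."""
    thr = optimal_tss_threshold(obs, pred)
    sens, spec, tss = confusion_metrics(obs, pred, thr)
    return ModelEvaluation(auc=roc_auc(obs, pred), tss=tss, sensitivity=sens,
                           specificity=spec, threshold=thr)


def permutation_importance(model, eval_table: pd.DataFrame,
                           n_permutations: int = 10, seed: int = 0) -> pd.Series:
    """Mean AUC loss when each predictor column is shuffled in turn.

    Negative losses (permutation accidentally helping) are reported as-is.
    """
    if n_permutations < 1:
        raise EvaluationError("n_permutations must be >= 1")
    obs = _check_classes(eval_table["detected"].to_numpy())
    base_auc = roc_auc(obs, model.predict(eval_table))
    rng = np.random.default_rng(seed)
    X = eval_table[model.predictor_names].to_numpy(float)
    losses = {}
    for j, name in enumerate(model.predictor_names):
        drop = 0.0
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drop += base_auc - roc_auc(obs, model.predict(Xp))
        losses[name] = drop / n_permutations
    out = pd.Series(losses, name="auc_loss")
    out.attrs["n_permutations"] = n_permutations
    out.attrs["base_auc"] = base_auc
    return out
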