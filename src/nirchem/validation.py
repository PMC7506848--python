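"""Model validation: RMSECV/RMSEP, R2, classification metrics, grid search.

RMSECV pools every held-out prediction of a k-fold loop into a single
root-mean-square error; RMSEP is the same formula on an independent
prediction set. R2 defaults to the standard coefficient of determination
``1 - SS_res / SS_tot``; an alternative convention ``paper_eq14`` exposes
the plain ratio ``SS_res / SS_ex`` (residual over explained sums of
squares) for comparison with sources that print it that way.

Grid search is exhaustive and deterministic: minimum RMSECV for regression,
maximum pooled CV accuracy for classification, with ties resolved in favor
of the first grid point in iteration order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import clone
from sklearn.metrics import precision_score, recall_score
from sklearn.pipeline import Pipeline

from .exceptions import DegenerateInputError

__all__ = [
    "EvaluationReport",
    "rmse",
    "rmse_cv",
    "cross_val_predict_folds",
    "r_squared",
    "classification_metrics",
    "grid_search",
]


@dataclass
class EvaluationReport:
    """Evaluation summary for one fitted scheme.

    Regression schemes fill the rmse/r2 fields; classification schemes fill
    accuracy/precision/recall/f1 (accuracies as fractions in [0, 1]; use
    :meth:`to_dict` with ``percent=True`` for the x100 presentation).
    """

    scheme: str
    n_features_in: int
    rmsecv: float | None = None
    rmsep: float | None = None
    r2_calibration: float | None = None
    r2_prediction: float | None = None
    accuracy_calibration: float | None = None
    accuracy_prediction: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    best_params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self, percent: bool = False) -> dict:
        out = asdict(self)
        if percent:
            for key in ("accuracy_calibration", "accuracy_prediction"):
                if out[key] is not None:
                    out[key] = round(100.0 * out[key], 2)
        return out


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def _check_folds(folds, n: int):
    folds = [(np.asarray(tr, dtype=int), np.asarray(va, dtype=int))
             for tr, va in folds]
    for tr, va in folds:
        if va.size == n or tr.size == 0:
            raise ValueError("a fold holds out every sample; nothing to train on")
        if np.intersect1d(tr, va).size:
            raise ValueError("train and validation indices overlap")
    return folds


def cross_val_predict_folds(X, y, estimator, folds) -> np.ndarray:
    """Held-out predictions, each sample predicted by the model trained
    without its fold. Samples never held out get NaN."""
    X = np.asarray(X)
    y = np.asarray(y)
    folds = _check_folds(folds, X.shape[0])
    out = np.full(y.shape, np.nan, dtype=float if y.dtype.kind in "fiu" else object)
    for tr, va in folds:
        model = clone(estimator).fit(X[tr], y[tr])
        out[va] = model.predict(X[va])
    return out


def rmse_cv(X, y, estimator, folds) -> float:
    """Pooled cross-validated RMSE over all held-out predictions."""
    yhat = cross_val_predict_folds(X, y, estimator, folds)
    held = ~np.isnan(yhat)
    return rmse(np.asarray(y, dtype=float)[held], yhat[held])


def r_squared(y_true, y_pred, convention: str = "standard") -> float:
    """Coefficient of determination between measured and predicted values.

    ``standard``: 1 - sum((y - yhat)^2) / sum((y - ybar)^2).
    ``paper_eq14``: sum((yhat - y)^2) / sum((yhat - ybar)^2), the raw
    residual/explained ratio some sources print.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y_true) == 0:
        raise DegenerateInputError("R2 undefined for constant measurements")
    ybar = y_true.mean()
    ss_res = float(np.sum((y_pred - y_true) ** 2))
    if convention == "standard":
        return 1.0 - ss_res / float(np.sum((y_true - ybar) ** 2))
    if convention == "paper_eq14":
        return ss_res / float(np.sum((y_pred - ybar) ** 2))
    raise ValueError(f"unknown convention {convention!r}")


def classification_metrics(y_true, y_pred) -> dict:
    """Macro-averaged precision/recall, the F1 of those macro values, and
    overall accuracy (fraction correct)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty inputs")
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    precision = float(precision_score(y_true, y_pred, average="macro",
                                      zero_division=0))
    recall = float(recall_score(y_true, y_pred, average="macro",
                                zero_division=0))
    f1 = 0.0 if precision + recall == 0 else (
        2.0 * precision * recall / (precision + recall)
    )
    accuracy = float(np.mean(y_true == y_pred))
    return {"precision": precision, "recall": recall, "f1": f1,
            "accuracy": accuracy}


def _split_pipeline_for_grid(estimator, param_names):
    """Split a Pipeline into a (cacheable prefix, grid-dependent suffix).

    Stages before the first stage named in the grid never change across
    grid points, so they are fitted once per fold. For a plain estimator
    the prefix is empty.
    """
    if not isinstance(estimator, Pipeline):
        return None, estimator
    touched = {name.split("__", 1)[0] for name in param_names}
    unknown = touched - {name for name, _ in estimator.steps}
    if unknown:
        raise ValueError(f"grid references unknown stages {sorted(unknown)}")
    first = min(i for i, (name, _) in enumerate(estimator.steps)
                if name in touched)
    prefix = Pipeline(estimator.steps[:first]) if first > 0 else None
    return prefix, Pipeline(estimator.steps[first:])


def grid_search(estimator, param_grid: dict, X, y, folds,
                scoring: str = "rmsecv"):
    """Exhaustive cross-validated scan over a parameter grid.

    Parameters use sklearn ``set_params`` keys (``stage__param`` for
    pipelines). ``scoring`` is ``rmsecv`` (minimized) or ``accuracy``
    (pooled CV accuracy, maximized). Returns
    ``(best_params, best_score, trace)`` where ``trace`` lists
    ``(params, score)`` in grid order. Deterministic; ties keep the
    earliest grid point.
    """
    if not param_grid:
        raise ValueError("parameter grid must be non-empty")
    if scoring not in ("rmsecv", "accuracy"):
        raise ValueError("scoring must be 'rmsecv' or 'accuracy'")
    X = np.asarray(X)
    y = np.asarray(y)
    folds = _check_folds(folds, X.shape[0])
    keys = list(param_grid)
    combos = [dict(zip(keys, values))
              for values in itertools.product(*(param_grid[k] for k in keys))]
    prefix, suffix = _split_pipeline_for_grid(estimator, keys)

    held = np.zeros(X.shape[0], dtype=bool)
    for _, va in folds:
        held[va] = True
    predictions = [np.empty(y.shape, dtype=object) for _ in combos]
    for tr, va in folds:
        if prefix is not None:
            fitted_prefix = clone(prefix).fit(X[tr], y[tr])
            Xtr, Xva = fitted_prefix.transform(X[tr]), fitted_prefix.transform(X[va])
        else:
            Xtr, Xva = X[tr], X[va]
        for c, params in enumerate(combos):
            model = clone(suffix).set_params(**params)
            model.fit(Xtr, y[tr])
            predictions[c][va] = model.predict(Xva)
    trace = []
    best_idx, best_score = 0, None
    for c, params in enumerate(combos):
        yhat = predictions[c][held]
        if scoring == "rmsecv":
            score = rmse(np.asarray(y, dtype=float)[held],
                         np.asarray(yhat, dtype=float))
            better = best_score is None or score < best_score - 1e-12
        else:
            score = float(np.mean(np.asarray(yhat) == y[held]))
            better = best_score is None or score > best_score + 1e-12
        trace.append((params, score))
        if better:
            best_idx, best_score = c, score
    return combos[best_idx], best_score, trace
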