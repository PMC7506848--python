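"""Named modelling schemes composing preprocessing, selection and PLS.

Each scheme is an sklearn Pipeline built from the package's transformers.
Classification schemes (origin identification): PLS, SNV-PLS, SNV-PCA-PLS,
PCA-PLS. Regression schemes (lipid content): PLS, UVE-PLS, MCUVE-PLS,
WT-PLS, WT-MCUVE-PLS, PCR, PCA-PLS, SPA-PLS.

Every run follows the same protocol: a fixed-size random calibration /
prediction split, five-fold cross-validated grid search on the calibration
set only (all data-dependent stages are refitted inside each training
fold, so no information from held-out samples leaks into selection), a
final refit on the full calibration set, and scoring on the untouched
prediction set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.feature_selection import VarianceThreshold
from sklearn.pipeline import Pipeline

from .dataset import SpectraSet, SplitPlan, make_folds, split_dataset
from .exceptions import LeakageError, SchemeError
from .feature_selection import MCUVESelector, SPASelector, UVESelector
from .pls import PCRRegressor, PLSDAClassifier, PLSRegressor
from .preprocess import SNVScaler
from .validation import (EvaluationReport, classification_metrics,
                         grid_search, r_squared, rmse)
from .wavelet import PAPER_FILTERS, THRESHOLD_STRATEGIES, WaveletCompressor, \
    compress_spectra

__all__ = [
    "SchemeSpec",
    "CLASSIFICATION_SCHEMES",
    "REGRESSION_SCHEMES",
    "build_scheme",
    "run_classification",
    "run_regression",
    "compare_regression",
    "compression_benchmark",
]

CLASSIFICATION_SCHEMES = ("PLS", "SNV-PLS", "SNV-PCA-PLS", "PCA-PLS")
REGRESSION_SCHEMES = ("PLS", "UVE-PLS", "MCUVE-PLS", "WT-PLS",
                      "WT-MCUVE-PLS", "PCR", "PCA-PLS", "SPA-PLS")


def _normalize(name: str) -> str:
    return name.replace("–", "-").replace("—", "-").strip().upper()


@dataclass
class SchemeSpec:
    """A named scheme with stage-parameter overrides and a seed."""

    name: str
    task: str  # "classification" | "regression"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.name = _normalize(self.name)
        allowed = (CLASSIFICATION_SCHEMES if self.task == "classification"
                   else REGRESSION_SCHEMES if self.task == "regression"
                   else None)
        if allowed is None:
            raise SchemeError(f"unknown task {self.task!r}")
        if self.name not in allowed:
            raise SchemeError(
                f"{self.name!r} is not a {self.task} scheme; "
                f"expected one of {allowed}"
            )


def build_scheme(spec: SchemeSpec) -> tuple[Pipeline, dict]:
    """Instantiate the pipeline and default parameter grid for a scheme.

    Stage order is fixed per scheme (preprocess -> transform -> select ->
    model); ``spec.params`` overrides stage parameters via sklearn
    ``stage__param`` keys, and an override named like a grid key replaces
    that grid axis with the single given value.
    """
    seed = spec.seed
    name, task = spec.name, spec.task
    d_grid = list(range(1, 13))

    if task == "classification":
        clf = PLSDAClassifier()
        if name == "PLS":
            pipe = Pipeline([("plsda", clf)])
            grid = {"plsda__n_components": list(range(1, 11))}
        elif name == "SNV-PLS":
            pipe = Pipeline([("snv", SNVScaler()), ("plsda", clf)])
            grid = {"plsda__n_components": list(range(1, 11))}
        elif name == "SNV-PCA-PLS":
            pipe = Pipeline([
                ("snv", SNVScaler()),
                ("pca", PCA(n_components=2, svd_solver="full")),
                ("plsda", clf),
            ])
            grid = {"plsda__n_components": [1, 2]}
        else:  # PCA-PLS
            pipe = Pipeline([
                ("pca", PCA(n_components=2, svd_solver="full")),
                ("plsda", clf),
            ])
            grid = {"plsda__n_components": [1, 2]}
    else:
        reg = PLSRegressor()
        if name == "PLS":
            pipe = Pipeline([("pls", reg)])
            grid = {"pls__n_components": d_grid}
        elif name == "UVE-PLS":
            pipe = Pipeline([
                ("uve", UVESelector(random_state=seed)),
                ("pls", reg),
            ])
            grid = {"pls__n_components": d_grid}
        elif name == "MCUVE-PLS":
            pipe = Pipeline([
                ("mcuve", MCUVESelector(k=70, random_state=seed)),
                ("pls", reg),
            ])
            grid = {"pls__n_components": d_grid}
        elif name == "WT-PLS":
            pipe = Pipeline([
                ("snv", SNVScaler()),
                ("wt", WaveletCompressor(output="coefficients")),
                ("nonzero", VarianceThreshold(threshold=0.0)),
                ("pls", reg),
            ])
            grid = {"pls__n_components": d_grid}
        elif name == "WT-MCUVE-PLS":
            pipe = Pipeline([
                ("snv", SNVScaler()),
                ("wt", WaveletCompressor(output="coefficients")),
                ("mcuve", MCUVESelector(k=70, random_state=seed)),
                ("pls", reg),
            ])
            grid = {"pls__n_components": d_grid}
        elif name == "PCR":
            pipe = Pipeline([("pcr", PCRRegressor())])
            grid = {"pcr__n_components": list(range(1, 21))}
        elif name == "PCA-PLS":
            pipe = Pipeline([
                ("pca", PCA(n_components=10, svd_solver="full")),
                ("pls", reg),
            ])
            grid = {"pls__n_components": list(range(1, 11))}
        else:  # SPA-PLS
            pipe = Pipeline([
                ("spa", SPASelector(k_range=range(5, 51, 5),
                                    random_state=seed)),
                ("pls", reg),
            ])
            grid = {"pls__n_components": d_grid}

    overrides = dict(spec.params)
    for key in list(overrides):
        if key in grid:
            grid[key] = [overrides.pop(key)]
    if overrides:
        pipe.set_params(**overrides)
    return pipe, grid


def _prepare_split(data: SpectraSet, seed: int, n_calibration: int,
                   n_prediction: int, n_folds: int,
                   plan: SplitPlan | None) -> SplitPlan:
    if plan is None:
        plan = split_dataset(data, n_calibration, n_prediction, seed=seed)
        plan = make_folds(plan, k=n_folds, seed=seed + 1)
    if np.intersect1d(plan.calibration_indices, plan.prediction_indices).size:
        raise LeakageError("calibration and prediction sets overlap")
    if plan.fold_assignment is None:
        plan = make_folds(plan, k=n_folds, seed=plan.seed + 1)
    return plan


def _relative_folds(plan: SplitPlan):
    """Fold index pairs relative to the calibration submatrix."""
    pos = {int(g): i for i, g in enumerate(plan.calibration_indices)}
    rel = []
    for tr, va in plan.iter_folds():
        rel.append((np.array([pos[int(i)] for i in tr]),
                    np.array([pos[int(i)] for i in va])))
    return rel


def _n_features_into_model(pipe: Pipeline, X_cal: np.ndarray) -> int:
    """Number of feature columns entering the final modelling stage."""
    if len(pipe.steps) == 1:
        return X_cal.shape[1]
    return int(pipe[:-1].transform(X_cal).shape[1])


def run_classification(
    data: SpectraSet,
    scheme: SchemeSpec | str,
    seed: int | None = None,
    n_calibration: int = 80,
    n_prediction: int = 40,
    n_folds: int = 5,
    plan: SplitPlan | None = None,
) -> EvaluationReport:
    """Run an origin-identification scheme end to end.

    80/40 split (by default), five-fold CV grid search maximizing pooled
    CV accuracy, final refit, scoring of both sets. Precision/recall/F1
    are macro averages on the calibration set of the refit model.
    """
    if isinstance(scheme, str):
        scheme = SchemeSpec(name=scheme, task="classification",
                            seed=0 if seed is None else seed)
    elif seed is not None:
        scheme = SchemeSpec(scheme.name, scheme.task, dict(scheme.params), seed)
    if scheme.task != "classification":
        raise SchemeError("run_classification needs a classification scheme")
    if data.origin is None:
        raise ValueError("classification needs origin labels")
    plan = _prepare_split(data, scheme.seed, n_calibration, n_prediction,
                          n_folds, plan)
    X, y = data.absorbance, data.origin
    cal, pred = plan.calibration_indices, plan.prediction_indices
    pipe, grid = build_scheme(scheme)
    best, _, _ = grid_search(pipe, grid, X[cal], y[cal],
                             _relative_folds(plan), scoring="accuracy")
    pipe.set_params(**best)
    pipe.fit(X[cal], y[cal])
    yhat_cal = pipe.predict(X[cal])
    yhat_pred = pipe.predict(X[pred])
    cal_metrics = classification_metrics(y[cal], yhat_cal)
    return EvaluationReport(
        scheme=scheme.name,
        n_features_in=_n_features_into_model(pipe, X[cal]),
        accuracy_calibration=cal_metrics["accuracy"],
        accuracy_prediction=float(np.mean(yhat_pred == y[pred])),
        precision=cal_metrics["precision"],
        recall=cal_metrics["recall"],
        f1=cal_metrics["f1"],
        best_params=best,
        seed=scheme.seed,
    )


def run_regression(
    data: SpectraSet,
    scheme: SchemeSpec | str,
    seed: int | None = None,
    n_calibration: int = 80,
    n_prediction: int = 40,
    n_folds: int = 5,
    plan: SplitPlan | None = None,
) -> EvaluationReport:
    """Run a lipid-content regression scheme end to end.

    Grid search minimizes five-fold RMSECV on the calibration set; RMSEP
    and prediction R2 come from the untouched prediction set.
    """
    if isinstance(scheme, str):
        scheme = SchemeSpec(name=scheme, task="regression",
                            seed=0 if seed is None else seed)
    elif seed is not None:
        scheme = SchemeSpec(scheme.name, scheme.task, dict(scheme.params), seed)
    if scheme.task != "regression":
        raise SchemeError("run_regression needs a regression scheme")
    if data.lipid is None:
        raise ValueError("regression needs lipid reference values")
    plan = _prepare_split(data, scheme.seed, n_calibration, n_prediction,
                          n_folds, plan)
    X, y = data.absorbance, data.lipid
    cal, pred = plan.calibration_indices, plan.prediction_indices
    pipe, grid = build_scheme(scheme)
    best, rmsecv, _ = grid_search(pipe, grid, X[cal], y[cal],
                                  _relative_folds(plan), scoring="rmsecv")
    pipe.set_params(**best)
    pipe.fit(X[cal], y[cal])
    yhat_cal = pipe.predict(X[cal])
    yhat_pred = pipe.predict(X[pred])
    return EvaluationReport(
        scheme=scheme.name,
        n_features_in=_n_features_into_model(pipe, X[cal]),
        rmsecv=rmsecv,
        rmsep=rmse(y[pred], yhat_pred),
        r2_calibration=r_squared(y[cal], yhat_cal),
        r2_prediction=r_squared(y[pred], yhat_pred),
        best_params=best,
        seed=scheme.seed,
    )


def compare_regression(
    data: SpectraSet,
    schemes=REGRESSION_SCHEMES,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Run several regression schemes on one shared split; tabular output
    with columns model, n_features, RMSECV, R2_cal, RMSEP, R2_pre."""
    plan = _prepare_split(data, seed, kwargs.pop("n_calibration", 80),
                          kwargs.pop("n_prediction", 40),
                          kwargs.pop("n_folds", 5), kwargs.pop("plan", None))
    rows = []
    for name in schemes:
        report = run_regression(
            data, SchemeSpec(name=name, task="regression", seed=seed),
            plan=plan, **kwargs,
        )
        rows.append({
            "model": report.scheme,
            "n_features": report.n_features_in,
            "RMSECV": report.rmsecv,
            "R2_cal": report.r2_calibration,
            "RMSEP": report.rmsep,
            "R2_pre": report.r2_prediction,
        })
    return pd.DataFrame(rows)


def compression_benchmark(
    data: SpectraSet,
    filters=PAPER_FILTERS,
    strategies=THRESHOLD_STRATEGIES,
    levels: int = 3,
    apply_snv: bool = True,
) -> pd.DataFrame:
    """Grid of wavelet filters x threshold strategies with averaged
    compression rate (%) and PRD (%) per combination."""
    from .preprocess import snv as _snv

    source = _snv(data) if apply_snv else data
    rows = []
    for filt in filters:
        for strategy in strategies:
            _, report, _ = compress_spectra(
                source, filter_name=filt, levels=levels, strategy=strategy,
            )
            rows.append({
                "wavelet": filt,
                "strategy": strategy,
                "compression_rate": report.compression_rate,
                "prd": report.prd,
            })
    return pd.DataFrame(rows)
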