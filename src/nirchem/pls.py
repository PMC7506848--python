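"""Partial least-squares models: NIPALS regression, PLS-DA, PCR baseline.

The NIPALS algorithm extracts latent components one at a time: for each
component a unit X-weight vector ``w`` maximizing covariance with the
response is found, X-scores ``t = X w`` are computed, loadings ``p`` and
``q`` regress X and Y on ``t``, and both blocks are deflated. Prediction
uses the composite regression vector ``coef = W (P'W)^-1 Q'`` so that new
samples need only the centered spectrum.

PLS-DA wraps the same machinery around a one-hot response matrix (class k
encoded as the k-th unit vector) with an argmax decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

from .exceptions import DegenerateInputError

__all__ = ["PLSRegressor", "PLSDAClassifier", "PCRRegressor", "ClassEncoding",
           "fit_pls", "predict_pls", "fit_plsda", "fit_pcr"]

_EPS = np.finfo(float).eps


def _nipals(Xc: np.ndarray, Yc: np.ndarray, n_components: int,
            max_iter: int, tol: float):
    """Run NIPALS on centered blocks; returns (W, T, P, Q, U, b, E, F)."""
    n, p = Xc.shape
    m = Yc.shape[1]
    W = np.empty((p, n_components))
    T = np.empty((n, n_components))
    P = np.empty((p, n_components))
    Q = np.empty((m, n_components))
    U = np.empty((n, n_components))
    b = np.empty(n_components)
    Xr, Yr = Xc.copy(), Yc.copy()
    for a in range(n_components):
        u = Yr[:, int(np.argmax(Yr.var(axis=0)))]
        if np.linalg.norm(u) < _EPS * n:
            raise DegenerateInputError(
                f"response fully deflated after {a} components"
            )
        t = np.zeros(n)
        for _ in range(max_iter):
            w = Xr.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w < _EPS * n:
                raise DegenerateInputError(
                    f"zero-variance X block at component {a + 1}"
                )
            w /= norm_w
            t_new = Xr @ w
            tt = float(t_new @ t_new)
            if tt < _EPS * n:
                raise DegenerateInputError(
                    f"degenerate scores at component {a + 1}"
                )
            q = Yr.T @ t_new / tt
            if m == 1:
                t = t_new
                break
            u_new = Yr @ q / float(q @ q)
            if np.linalg.norm(t_new - t) <= tol * np.linalg.norm(t_new):
                t = t_new
                break
            t, u = t_new, u_new
        tt = float(t @ t)
        p_load = Xr.T @ t / tt
        q = Yr.T @ t / tt
        b[a] = float(u @ t) / tt
        W[:, a], T[:, a], P[:, a], Q[:, a], U[:, a] = w, t, p_load, q, u
        Xr = Xr - np.outer(t, p_load)
        Yr = Yr - np.outer(t, q)
    return W, T, P, Q, U, b, Xr, Yr


class PLSRegressor(RegressorMixin, BaseEstimator):
    """PLS regression fitted by NIPALS with mean-centering.

    Parameters
    ----------
    n_components : int
        Number of latent components d, 1 <= d <= min(n - 1, p).
    scale : bool
        Also autoscale X columns to unit variance (default off: SNV /
        wavelet pretreatment precedes the model in the intended pipelines).
    max_iter, tol : NIPALS inner-loop controls.

    Attributes (after fit)
    ----------------------
    x_mean_, y_mean_ : centering vectors.
    x_weights_ W (p x d), x_scores_ T (n x d), x_loadings_ P (p x d),
    y_loadings_ Q (m x d), y_scores_ U (n x d): per-component blocks.
    inner_coefficients_ : diagonal of the d-dimensional inner relation
        between U and T.
    coef_ : (p x m) composite regression vector used for prediction.
    x_residual_, y_residual_ : deflation residuals E and F.
    """

    def __init__(self, n_components: int = 2, scale: bool = False,
                 max_iter: int = 500, tol: float = 1e-9):
        self.n_components = n_components
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, Y):
        X, Y = check_X_y(X, Y, multi_output=True, y_numeric=True)
        Y2 = Y.reshape(-1, 1) if Y.ndim == 1 else Y
        self._y_1d = Y.ndim == 1
        n, p = X.shape
        d = self.n_components
        if not isinstance(d, (int, np.integer)) or d < 1:
            raise ValueError("n_components must be a positive integer")
        if d > min(n - 1, p):
            raise ValueError(
                f"n_components={d} exceeds min(n - 1, p) = {min(n - 1, p)}"
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y2.mean(axis=0)
        Xc = X - self.x_mean_
        if self.scale:
            sd = Xc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            self.x_std_ = sd
            Xc = Xc / sd
        else:
            self.x_std_ = np.ones(p)
        Yc = Y2 - self.y_mean_
        W, T, P, Q, U, b, E, F = _nipals(Xc, Yc, d, self.max_iter, self.tol)
        self.x_weights_, self.x_scores_ = W, T
        self.x_loadings_, self.y_loadings_ = P, Q
        self.y_scores_, self.inner_coefficients_ = U, b
        self.x_residual_, self.y_residual_ = E, F
        # rotation mapping centered X directly to scores: T = Xc R
        self.x_rotations_ = W @ np.linalg.inv(P.T @ W)
        self.coef_ = self.x_rotations_ @ Q.T
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.n_features_in_}"
            )
        Yhat = ((X - self.x_mean_) / self.x_std_) @ self.coef_ + self.y_mean_
        return Yhat.ravel() if self._y_1d else Yhat

    def transform(self, X):
        """Project spectra onto the latent components (scores)."""
        check_is_fitted(self)
        X = check_array(X)
        return ((X - self.x_mean_) / self.x_std_) @ self.x_rotations_


@dataclass
class ClassEncoding:
    """Ordered class labels and their one-hot response matrix."""

    class_labels: np.ndarray
    response_matrix: np.ndarray

    def decode(self, responses: np.ndarray) -> np.ndarray:
        """Argmax decision rule; ties go to the lowest class index."""
        idx = np.argmax(np.atleast_2d(responses), axis=1)
        return self.class_labels[idx]


def _one_hot(labels: np.ndarray) -> ClassEncoding:
    labels = np.asarray(labels)
    classes = np.array(list(dict.fromkeys(labels.tolist())), dtype=object)
    if classes.size < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    index = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((labels.size, classes.size))
    for row, lab in enumerate(labels.tolist()):
        Y[row, index[lab]] = 1.0
    return ClassEncoding(class_labels=classes, response_matrix=Y)


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS discriminant analysis: PLS on a one-hot response + argmax rule.

    Class order is fixed by first appearance in the label vector; argmax
    ties resolve to the lowest class index.
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X = check_array(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        self.encoding_ = _one_hot(y)
        self.classes_ = self.encoding_.class_labels
        self.pls_ = PLSRegressor(
            n_components=self.n_components, scale=self.scale
        ).fit(X, self.encoding_.response_matrix)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        return self.pls_.predict(X)

    def predict(self, X):
        return self.encoding_.decode(self.decision_function(X))


class PCRRegressor(RegressorMixin, BaseEstimator):
    """Principal-component regression: OLS of y on the first PCA scores."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        d = self.n_components
        if not isinstance(d, (int, np.integer)) or d < 1:
            raise ValueError("n_components must be a positive integer")
        if d > min(X.shape[0] - 1, X.shape[1]):
            raise ValueError("n_components too large for the data")
        self.pca_ = PCA(n_components=d, svd_solver="full").fit(X)
        scores = self.pca_.transform(X)
        self.y_mean_ = float(np.mean(y))
        beta, *_ = np.linalg.lstsq(scores, y - self.y_mean_, rcond=None)
        self.score_coef_ = beta
        self.coef_ = self.pca_.components_.T @ beta
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return self.pca_.transform(X) @ self.score_coef_ + self.y_mean_


# ---------------------------------------------------------------------------
# thin functional wrappers

def fit_pls(X, Y, n_components: int) -> PLSRegressor:
    return PLSRegressor(n_components=n_components).fit(X, Y)


def predict_pls(model: PLSRegressor, X_new):
    return model.predict(X_new)


def fit_plsda(X, labels, n_components: int) -> PLSDAClassifier:
    return PLSDAClassifier(n_components=n_components).fit(X, labels)


def fit_pcr(X, y, n_components: int) -> PCRRegressor:
    return PCRRegressor(n_components=n_components).fit(X, y)
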