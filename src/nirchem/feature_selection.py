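"""Variable selection and projection: PCA, UVE, MCUVE and SPA.

MCUVE (Monte-Carlo uninformative variable elimination) rates every input
variable by the stability of its PLS regression coefficient across random
sample subsets: ``s_j = mean(beta_j) / std(beta_j)``. Variables whose
coefficient flips sign or fluctuates across resamples get |s| near zero and
are eliminated; the top-k most stable variables feed the final model.

Classic UVE appends artificial near-zero noise variables, computes the same
stability under leave-one-out resampling, and keeps the real variables that
beat every noise variable. SPA (successive projections algorithm) instead
greedily chains minimally collinear columns by orthogonal projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

from .pls import PLSRegressor

__all__ = [
    "PCAProjection",
    "StabilityProfile",
    "fit_pca",
    "mcuve_stability",
    "select_top_k",
    "uve_select",
    "spa_select",
    "MCUVESelector",
    "UVESelector",
    "SPASelector",
]


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAProjection:
    """Orthonormal principal directions with explained variances."""

    components: np.ndarray  # (k, p), rows unit-norm and orthogonal
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    center: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.center) @ self.components.T


def fit_pca(X: np.ndarray, n_components: int) -> PCAProjection:
    """Variance-maximizing orthonormal projection (full SVD solver)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n - 1, p) = {min(n - 1, p)}"
        )
    model = PCA(n_components=n_components, svd_solver="full").fit(X)
    return PCAProjection(
        components=model.components_,
        explained_variance=model.explained_variance_,
        explained_variance_ratio=model.explained_variance_ratio_,
        center=model.mean_,
    )


# ---------------------------------------------------------------------------
# MCUVE

@dataclass
class StabilityProfile:
    """Per-variable MCUVE stability scores and their ranking.

    ``stability[j] = mean_r(beta_jr) / std_r(beta_jr)`` over Monte-Carlo
    runs r; ``ranking`` sorts variables by |stability| descending with ties
    broken by ascending index. A variable whose coefficient is identical in
    every run (std 0, mean nonzero) gets a signed-infinity sentinel; a dead
    variable (std 0 and mean 0, e.g. an always-zeroed wavelet coefficient)
    gets stability 0 so it can never be selected.
    """

    stability: np.ndarray
    ranking: np.ndarray
    n_mc_runs: int
    subset_fraction: float
    n_latent: int
    seed: int

    def to_frame(self, variable_names=None) -> pd.DataFrame:
        p = self.stability.size
        return pd.DataFrame(
            {
                "variable": np.arange(p) if variable_names is None
                else np.asarray(variable_names),
                "stability": self.stability,
                "rank": np.argsort(self.ranking).astype(int) + 1,
            }
        )


def _rank_by_magnitude(s: np.ndarray) -> np.ndarray:
    # stable sort on (-|s|, index): ties resolve to the lower index
    return np.lexsort((np.arange(s.size), -np.abs(s)))


def _choose_n_latent(X: np.ndarray, y: np.ndarray, seed: int,
                     max_components: int = 10, n_folds: int = 5) -> int:
    """Pick the PLS depth once by k-fold RMSECV on the full data."""
    from .validation import rmse_cv  # local import: avoids a cycle

    n = X.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [
        (np.setdiff1d(order, order[k::n_folds]), order[k::n_folds])
        for k in range(n_folds)
    ]
    upper = min(max_components, min(n - len(folds[0][1]) - 1, X.shape[1]))
    best_d, best_rmse = 1, np.inf
    for d in range(1, upper + 1):
        score = rmse_cv(X, y, PLSRegressor(n_components=d), folds)
        if score < best_rmse - 1e-12:
            best_d, best_rmse = d, score
    return best_d


def _stability(betas: np.ndarray) -> np.ndarray:
    mean = betas.mean(axis=0)
    std = betas.std(axis=0, ddof=1)
    s = np.zeros(mean.size)
    ok = std > 0
    s[ok] = mean[ok] / std[ok]
    frozen = (~ok) & (mean != 0)
    s[frozen] = np.sign(mean[frozen]) * np.inf
    return s


def mcuve_stability(
    X: np.ndarray,
    y: np.ndarray,
    n_mc_runs: int = 500,
    subset_fraction: float = 0.8,
    n_latent: int | None = None,
    seed: int = 0,
) -> StabilityProfile:
    """Monte-Carlo UVE stability of every input variable.

    Each run fits a PLS model with ``n_latent`` components on a random
    ``subset_fraction`` of the samples (without replacement) and records the
    regression coefficient of every variable; stability is the ratio of the
    mean to the standard deviation of those coefficients across runs.
    ``n_latent=None`` chooses the depth once by 5-fold RMSECV on the full
    data. Deterministic given ``seed``.
    """
    X, y = check_X_y(X, y, y_numeric=True)
    if n_mc_runs < 2:
        raise ValueError("n_mc_runs must be at least 2")
    if not 0.0 < subset_fraction < 1.0:
        raise ValueError("subset_fraction must lie strictly between 0 and 1")
    n, p = X.shape
    if n_latent is None:
        n_latent = _choose_n_latent(X, y, seed)
    m = max(int(round(subset_fraction * n)), n_latent + 2)
    if m >= n:
        raise ValueError("subset too large for the available samples")
    rng = np.random.default_rng(seed)
    betas = np.empty((n_mc_runs, p))
    for r in range(n_mc_runs):
        idx = rng.choice(n, size=m, replace=False)
        model = PLSRegressor(n_components=n_latent).fit(X[idx], y[idx])
        betas[r] = model.coef_.ravel()
    s = _stability(betas)
    return StabilityProfile(
        stability=s,
        ranking=_rank_by_magnitude(s),
        n_mc_runs=n_mc_runs,
        subset_fraction=subset_fraction,
        n_latent=n_latent,
        seed=seed,
    )


def select_top_k(profile: StabilityProfile, k: int) -> np.ndarray:
    """Indices (ascending) of the k variables with largest |stability|."""
    p = profile.stability.size
    if not 1 <= k <= p:
        raise ValueError(f"k={k} outside [1, {p}]")
    return np.sort(profile.ranking[:k])


def uve_select(
    X: np.ndarray,
    y: np.ndarray,
    n_latent: int | None = None,
    noise_scale: float = 1e-10,
    seed: int = 0,
) -> np.ndarray:
    """Classic UVE: retain variables more stable than any noise variable.

    Appends p artificial uniform-noise columns scaled by
    ``noise_scale * max|X|`` (numerically negligible, statistically null),
    computes leave-one-out coefficient stabilities, and keeps real variables
    whose |s| exceeds the largest |s| among the noise columns.
    """
    X, y = check_X_y(X, y, y_numeric=True)
    if noise_scale <= 0:
        raise ValueError("noise_scale must be positive")
    n, p = X.shape
    if n_latent is None:
        n_latent = _choose_n_latent(X, y, seed)
    rng = np.random.default_rng(seed)
    noise = rng.uniform(size=(n, p)) * noise_scale * np.max(np.abs(X))
    Xa = np.hstack([X, noise])
    betas = np.empty((n, 2 * p))
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[:] = True
        keep[i] = False
        model = PLSRegressor(n_components=n_latent).fit(Xa[keep], y[keep])
        betas[i] = model.coef_.ravel()
    s = _stability(betas)
    cutoff = np.max(np.abs(s[p:]))
    return np.flatnonzero(np.abs(s[:p]) > cutoff)


# ---------------------------------------------------------------------------
# SPA

def _spa_chain(X: np.ndarray, start: int, k_max: int) -> np.ndarray:
    """Forward chain of minimally collinear columns by projection.

    At each step every remaining column is replaced by its projection onto
    the orthogonal complement of the selected set; the column with the
    largest residual norm is added next.
    """
    n, p = X.shape
    proj = X.copy()
    chain = [start]
    for _ in range(k_max - 1):
        t = proj[:, chain[-1]].copy()
        norm2 = float(t @ t)
        if norm2 <= 0:
            break
        proj = proj - np.outer(t, (t @ proj) / norm2)
        norms = np.einsum("ij,ij->j", proj, proj)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-12 * n:
            break
        chain.append(nxt)
    return np.asarray(chain, dtype=int)


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    k_range=range(1, 21),
    n_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Successive projections algorithm with RMSECV model-size choice.

    Chains are grown from every candidate start column; each (start, k)
    subset is scored by k-fold RMSECV of an ordinary least-squares fit and
    the global minimizer is returned (ascending index order).
    """
    X, y = check_X_y(X, y, y_numeric=True)
    k_range = [int(k) for k in k_range]
    if len(k_range) == 0:
        raise ValueError("k_range must be non-empty")
    n, p = X.shape
    if min(k_range) < 1 or max(k_range) > p:
        raise ValueError(f"k_range must lie within [1, {p}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [(np.setdiff1d(order, order[f::n_folds]), order[f::n_folds])
             for f in range(n_folds)]
    k_max = max(k_range)
    best = (np.inf, None)
    for start in range(p):
        chain = _spa_chain(X, start, k_max)
        for k in k_range:
            if k > chain.size:
                continue
            cols = chain[:k]
            press = 0.0
            for tr, va in folds:
                A = np.column_stack([np.ones(tr.size), X[np.ix_(tr, cols)]])
                beta, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
                Av = np.column_stack([np.ones(va.size), X[np.ix_(va, cols)]])
                press += float(np.sum((y[va] - Av @ beta) ** 2))
            rmsecv = np.sqrt(press / n)
            if rmsecv < best[0] - 1e-12:
                best = (rmsecv, np.sort(cols))
    return best[1]


# ---------------------------------------------------------------------------
# scikit-learn selector front-ends

class MCUVESelector(SelectorMixin, BaseEstimator):
    """Select the k most MCUVE-stable variables (sklearn transformer)."""

    def __init__(self, k: int = 70, n_mc_runs: int = 500,
                 subset_fraction: float = 0.8, n_latent: int | None = None,
                 random_state: int = 0):
        self.k = k
        self.n_mc_runs = n_mc_runs
        self.subset_fraction = subset_fraction
        self.n_latent = n_latent
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.profile_ = mcuve_stability(
            X, y,
            n_mc_runs=self.n_mc_runs,
            subset_fraction=self.subset_fraction,
            n_latent=self.n_latent,
            seed=self.random_state,
        )
        k = min(self.k, X.shape[1])
        self.selected_ = select_top_k(self.profile_, k)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask


class UVESelector(SelectorMixin, BaseEstimator):
    """Classic UVE selection against artificial noise variables."""

    def __init__(self, n_latent: int | None = None, noise_scale: float = 1e-10,
                 random_state: int = 0, min_keep: int = 1):
        self.n_latent = n_latent
        self.noise_scale = noise_scale
        self.random_state = random_state
        self.min_keep = min_keep

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.selected_ = uve_select(
            X, y, n_latent=self.n_latent, noise_scale=self.noise_scale,
            seed=self.random_state,
        )
        if self.selected_.size < self.min_keep:
            # fall back to the most stable variables so the pipeline can fit
            profile = mcuve_stability(
                X, y, n_mc_runs=50, n_latent=self.n_latent,
                seed=self.random_state,
            )
            self.selected_ = select_top_k(profile, self.min_keep)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask


class SPASelector(SelectorMixin, BaseEstimator):
    """Successive-projections variable selection (sklearn transformer)."""

    def __init__(self, k_range=range(5, 51, 5), n_folds: int = 5,
                 random_state: int = 0):
        self.k_range = k_range
        self.n_folds = n_folds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.selected_ = spa_select(
            X, y, k_range=self.k_range, n_folds=self.n_folds,
            seed=self.random_state,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask
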