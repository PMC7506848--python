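"""Row-wise spectral pretreatment (SNV) and reference-chemistry arithmetic.

SNV (standard normal variate) removes multiplicative scatter and path-length
effects by centering and scaling each spectrum to zero mean and unit sample
standard deviation. The gravimetric crude-lipid computation converts Soxhlet
extraction weighings into a lipid content in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .dataset import SpectraSet
from .exceptions import DegenerateInputError

__all__ = ["snv", "SNVScaler", "CrudeLipidWeights", "crude_lipid_content"]


def _snv_matrix(X: np.ndarray, sample_ids=None) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise DegenerateInputError("SNV needs at least 2 bands per spectrum")
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        who = sample_ids[bad[0]] if sample_ids is not None else f"row {bad[0]}"
        raise DegenerateInputError(f"constant spectrum (zero variance): {who}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def snv(spectra):
    """Standard normal variate transform.

    Accepts a :class:`SpectraSet` (returns a new one) or a 2-D array
    (returns the transformed array). Each row ends up with mean 0 and
    sample (n-1) standard deviation 1.
    """
    if isinstance(spectra, SpectraSet):
        return spectra.with_absorbance(
            _snv_matrix(spectra.absorbance, spectra.sample_ids)
        )
    return _snv_matrix(spectra)


class SNVScaler(TransformerMixin, BaseEstimator):
    """Stateless per-spectrum SNV transformer (scikit-learn compatible).

    SNV is a row-wise operation: nothing is learned from the calibration
    set, so using it inside cross-validated pipelines cannot leak
    information across samples.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return _snv_matrix(X)


@dataclass(frozen=True)
class CrudeLipidWeights:
    """Soxhlet weighings in grams.

    bottle_bag : weighing bottle + filter-paper bag             (a)
    bottle_bag_sample : bottle + bag + dried sample             (b)
    bottle_bag_residue : bottle + bag + dry residue after
        extraction                                              (c)
    """

    bottle_bag: float
    bottle_bag_sample: float
    bottle_bag_residue: float

    def __post_init__(self) -> None:
        a, b, c = self.bottle_bag, self.bottle_bag_sample, self.bottle_bag_residue
        if b <= a:
            raise ValueError("sample weight must be positive (b > a)")
        if not (a <= c <= b):
            raise ValueError("residue weight must satisfy a <= c <= b")


def crude_lipid_content(weights: CrudeLipidWeights) -> float:
    """Crude lipid content in percent: 100 * (b - c) / (b - a)."""
    a = weights.bottle_bag
    b = weights.bottle_bag_sample
    c = weights.bottle_bag_residue
    return 100.0 * (b - c) / (b - a)
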