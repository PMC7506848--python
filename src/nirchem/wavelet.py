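"""Multilevel DWT with threshold compression of NIR spectra.

The discrete wavelet transform (via PyWavelets) splits each spectrum into an
approximation vector and per-level detail vectors. Under the additive
i.i.d. Gaussian noise model, noise energy concentrates in small detail
coefficients, so zeroing details below a threshold simultaneously denoises
and compresses the signal. Four threshold strategies are provided:

``donoho``
    Universal threshold lambda = sigma * sqrt(2 ln N) with the *hard* rule
    (keep-or-kill); best at preserving retained coefficients.
``soft``
    Same universal threshold with the *soft* rule (shrink survivors by
    lambda); biases retained coefficients toward zero.
``sure_shrink``
    Per-level soft threshold minimizing Stein's unbiased risk estimate over
    the candidate set {0} + {|d_jk|}.
``birge_massart``
    Level-dependent keep-count rule: with M the approximation length and
    sparsity parameter alpha, detail level j (j = 1 coarsest) retains its
    n_j = M / (2 + j)**alpha largest-magnitude coefficients (hard rule).

Distortion is scored by PRD, the percent root-mean-square difference
``100 * sqrt(sum((x - x_rec)^2) / sum(x^2))``, and compression by the
percentage of all coefficients that are exactly zero after thresholding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .dataset import SpectraSet
from .exceptions import StructureError

__all__ = [
    "WaveletDecomposition",
    "ThresholdSpec",
    "CompressionReport",
    "PAPER_FILTERS",
    "THRESHOLD_STRATEGIES",
    "dwt_multilevel",
    "idwt_multilevel",
    "estimate_noise_sigma",
    "compute_threshold",
    "apply_threshold",
    "prd",
    "compress_spectra",
    "WaveletCompressor",
]

PAPER_FILTERS = ("db9", "bior4.4", "sym8", "coif4")
THRESHOLD_STRATEGIES = ("birge_massart", "sure_shrink", "donoho", "soft")

_MAD_TO_SIGMA = 0.6745  # Phi^-1(0.75): MAD of a N(0, sigma) sample / sigma


@dataclass
class WaveletDecomposition:
    """Multilevel DWT coefficients with reconstruction bookkeeping.

    ``details`` is ordered finest first: ``details[0]`` is level 1 (highest
    frequency), ``details[-1]`` the coarsest level ``levels``.
    """

    filter_name: str
    levels: int
    approx: np.ndarray
    details: list[np.ndarray]
    extension_mode: str
    original_length: int

    @property
    def n_coefficients(self) -> int:
        return self.approx.size + sum(d.size for d in self.details)

    def coefficient_vector(self) -> np.ndarray:
        """Flat vector [approx, coarsest detail, ..., finest detail]."""
        return np.concatenate([self.approx, *reversed(self.details)])

    def copy(self) -> "WaveletDecomposition":
        return WaveletDecomposition(
            filter_name=self.filter_name,
            levels=self.levels,
            approx=self.approx.copy(),
            details=[d.copy() for d in self.details],
            extension_mode=self.extension_mode,
            original_length=self.original_length,
        )


@dataclass
class ThresholdSpec:
    """Per-level thresholds plus the shrinkage rule to apply.

    ``per_level_thresholds`` aligns with ``WaveletDecomposition.details``
    (finest first). Approximation coefficients are never thresholded.
    """

    strategy: str
    per_level_thresholds: np.ndarray
    shrink_rule: str  # "hard" | "soft"
    noise_sigma: float

    def __post_init__(self) -> None:
        self.per_level_thresholds = np.asarray(self.per_level_thresholds, dtype=float)
        if np.any(self.per_level_thresholds < 0):
            raise ValueError("thresholds must be nonnegative")
        if self.shrink_rule not in ("hard", "soft"):
            raise ValueError(f"unknown shrink rule {self.shrink_rule!r}")


@dataclass
class CompressionReport:
    """Compression rate (% coefficients zeroed) and PRD distortion (%)."""

    compression_rate: float
    prd: float | None = None


def _coeff_shapes(n: int, filter_name: str, levels: int, mode: str) -> list[int]:
    """Coefficient lengths [approx, coarsest..finest] for a length-n signal."""
    shapes = []
    length = n
    dec_len = pywt.Wavelet(filter_name).dec_len
    for _ in range(levels):
        length = pywt.dwt_coeff_len(length, dec_len, mode)
        shapes.append(length)
    return [shapes[-1]] + shapes[::-1]


def dwt_multilevel(
    signal: np.ndarray,
    filter_name: str = "bior4.4",
    levels: int = 3,
    extension_mode: str = "symmetric",
) -> WaveletDecomposition:
    """Multilevel discrete wavelet transform of a single spectrum."""
    signal = np.asarray(signal, dtype=float).ravel()
    n = signal.size
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if n < 2 or levels > int(math.floor(math.log2(n))):
        raise ValueError(f"{levels} levels too deep for signal of length {n}")
    coeffs = pywt.wavedec(signal, filter_name, mode=extension_mode, level=levels)
    return WaveletDecomposition(
        filter_name=filter_name,
        levels=levels,
        approx=coeffs[0],
        details=list(reversed(coeffs[1:])),
        extension_mode=extension_mode,
        original_length=n,
    )


def idwt_multilevel(decomp: WaveletDecomposition) -> np.ndarray:
    """Inverse multilevel DWT, restoring a signal of ``original_length``."""
    expected = _coeff_shapes(
        decomp.original_length, decomp.filter_name, decomp.levels,
        decomp.extension_mode,
    )
    got = [decomp.approx.size] + [d.size for d in reversed(decomp.details)]
    if len(decomp.details) != decomp.levels or got != expected:
        raise StructureError(
            f"coefficient shapes {got} inconsistent with bookkeeping {expected}"
        )
    coeffs = [decomp.approx, *reversed(decomp.details)]
    rec = pywt.waverec(coeffs, decomp.filter_name, mode=decomp.extension_mode)
    return rec[: decomp.original_length]


def estimate_noise_sigma(decomp: WaveletDecomposition) -> float:
    """Robust noise level from the finest detail level: MAD / 0.6745."""
    finest = decomp.details[0]
    if finest.size == 0:
        raise StructureError("finest detail level is empty")
    return float(np.median(np.abs(finest)) / _MAD_TO_SIGMA)


def _sure_threshold(detail: np.ndarray, sigma: float) -> float:
    """Soft threshold minimizing Stein's unbiased risk estimate.

    Risk (in sigma^2 units) of soft thresholding y_i = d_i/sigma at t:
    ``n - 2 * #{|y_i| <= t} + sum_i min(y_i^2, t^2)``, minimized over the
    candidate thresholds {0} + {|y_i|}.
    """
    if sigma == 0 or detail.size == 0:
        return 0.0
    y = np.sort(np.abs(detail) / sigma)
    n = y.size
    candidates = np.concatenate(([0.0], y))
    cumsq = np.concatenate(([0.0], np.cumsum(y**2)))
    below = np.searchsorted(y, candidates, side="right")  # #{y_i <= t}
    risk = n - 2.0 * below + cumsq[below] + (n - below) * candidates**2
    return float(sigma * candidates[np.argmin(risk)])


def _birge_massart_threshold(detail: np.ndarray, keep: int) -> float:
    """Hard threshold retaining exactly ``keep`` largest-magnitude coeffs
    (assuming no magnitude ties)."""
    if keep >= detail.size:
        return 0.0
    mags = np.sort(np.abs(detail))[::-1]
    if keep <= 0:
        return float(mags[0]) if detail.size else 0.0
    return float(mags[keep])  # hard rule zeroes |d| <= lambda


def compute_threshold(
    decomp: WaveletDecomposition,
    strategy: str,
    bm_alpha: float = 1.5,
    noise_sigma: float | None = None,
) -> ThresholdSpec:
    """Compute per-level thresholds for one of the four strategies.

    ``noise_sigma`` overrides the MAD estimate from the finest detail level
    (used by the universal and SURE thresholds).
    """
    if strategy not in THRESHOLD_STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {THRESHOLD_STRATEGIES}"
        )
    sigma = estimate_noise_sigma(decomp) if noise_sigma is None else float(noise_sigma)
    levels = decomp.levels

    if strategy in ("donoho", "soft"):
        lam = sigma * math.sqrt(2.0 * math.log(decomp.original_length))
        thresholds = np.full(levels, lam)
        rule = "hard" if strategy == "donoho" else "soft"
    elif strategy == "sure_shrink":
        thresholds = np.array(
            [_sure_threshold(d, sigma) for d in decomp.details]
        )
        rule = "soft"
    else:  # birge_massart
        m = decomp.approx.size
        thresholds = np.empty(levels)
        # j = 1 at the coarsest detail level for this rule
        for j in range(1, levels + 1):
            keep = int(round(m / (2.0 + j) ** bm_alpha))
            detail = decomp.details[levels - j]
            thresholds[levels - j] = _birge_massart_threshold(detail, keep)
        rule = "hard"
    return ThresholdSpec(
        strategy=strategy,
        per_level_thresholds=thresholds,
        shrink_rule=rule,
        noise_sigma=sigma,
    )


def apply_threshold(
    decomp: WaveletDecomposition, spec: ThresholdSpec
) -> tuple[WaveletDecomposition, CompressionReport]:
    """Threshold detail coefficients; approximation is left untouched.

    Hard rule: d -> 0 if |d| <= lambda else d.
    Soft rule: d -> sign(d) * max(|d| - lambda, 0).
    The report's ``compression_rate`` is the percentage of all coefficients
    (details + approximation) that are exactly zero afterwards; ``prd`` is
    left unset (it needs the reconstruction).
    """
    if spec.per_level_thresholds.size != decomp.levels:
        raise StructureError(
            f"{spec.per_level_thresholds.size} thresholds for "
            f"{decomp.levels} detail levels"
        )
    out = decomp.copy()
    zeros = 0
    for i, lam in enumerate(spec.per_level_thresholds):
        d = out.details[i]
        if spec.shrink_rule == "hard":
            d = np.where(np.abs(d) <= lam, 0.0, d)
        else:
            d = np.sign(d) * np.maximum(np.abs(d) - lam, 0.0)
        out.details[i] = d
        zeros += int(np.sum(d == 0.0))
    rate = 100.0 * zeros / out.n_coefficients
    return out, CompressionReport(compression_rate=rate)


def prd(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Percent root-mean-square difference between a signal and its
    reconstruction: ``100 * sqrt(sum((x - x_rec)^2) / sum(x^2))``."""
    x = np.asarray(original, dtype=float).ravel()
    r = np.asarray(reconstructed, dtype=float).ravel()
    if x.size != r.size:
        raise ValueError("signals must have equal length")
    denom = float(np.sum(x**2))
    if denom == 0.0:
        raise ZeroDivisionError("PRD undefined for an all-zero original signal")
    return 100.0 * math.sqrt(float(np.sum((x - r) ** 2)) / denom)


def compress_spectra(
    data: SpectraSet | np.ndarray,
    filter_name: str = "bior4.4",
    levels: int = 3,
    strategy: str = "donoho",
    extension_mode: str = "symmetric",
    bm_alpha: float = 1.5,
) -> tuple[SpectraSet | np.ndarray, CompressionReport, list[WaveletDecomposition]]:
    """Per-sample decompose -> threshold -> reconstruct over a dataset.

    Returns the reconstructed spectra, a report averaging compression rate
    and PRD across samples, and the thresholded decompositions (whose
    coefficient vectors feed downstream feature selection).
    """
    X = data.absorbance if isinstance(data, SpectraSet) else np.atleast_2d(data)
    recon = np.empty_like(X)
    rates, prds, decomps = [], [], []
    for i in range(X.shape[0]):
        decomp = dwt_multilevel(X[i], filter_name, levels, extension_mode)
        spec = compute_threshold(decomp, strategy, bm_alpha=bm_alpha)
        thresholded, partial = apply_threshold(decomp, spec)
        recon[i] = idwt_multilevel(thresholded)
        rates.append(partial.compression_rate)
        prds.append(prd(X[i], recon[i]))
        decomps.append(thresholded)
    report = CompressionReport(
        compression_rate=float(np.mean(rates)), prd=float(np.mean(prds))
    )
    if isinstance(data, SpectraSet):
        return data.with_absorbance(recon), report, decomps
    return recon, report, decomps


class WaveletCompressor(TransformerMixin, BaseEstimator):
    """Wavelet threshold compression as a scikit-learn transformer.

    Stateless and row-wise (thresholds are estimated per spectrum), so it
    cannot leak information across cross-validation folds.

    Parameters
    ----------
    wavelet : str
        Mother wavelet ('db9', 'bior4.4', 'sym8', 'coif4', ...).
    levels : int
        Decomposition depth (default 3).
    strategy : str
        One of ``THRESHOLD_STRATEGIES``.
    extension_mode : str
        Boundary rule ('symmetric' default; 'periodization' for strict
        energy bookkeeping with orthogonal filters).
    bm_alpha : float
        Sparsity parameter of the Birge-Massart rule.
    output : {'spectrum', 'coefficients'}
        Return the reconstructed spectra, or the thresholded coefficient
        vectors (for coefficient-domain feature selection).
    """

    def __init__(
        self,
        wavelet: str = "bior4.4",
        levels: int = 3,
        strategy: str = "donoho",
        extension_mode: str = "symmetric",
        bm_alpha: float = 1.5,
        output: str = "spectrum",
    ):
        self.wavelet = wavelet
        self.levels = levels
        self.strategy = strategy
        self.extension_mode = extension_mode
        self.bm_alpha = bm_alpha
        self.output = output

    def fit(self, X, y=None):
        if self.output not in ("spectrum", "coefficients"):
            raise ValueError("output must be 'spectrum' or 'coefficients'")
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        recon, _, decomps = compress_spectra(
            X,
            filter_name=self.wavelet,
            levels=self.levels,
            strategy=self.strategy,
            extension_mode=self.extension_mode,
            bm_alpha=self.bm_alpha,
        )
        if self.output == "spectrum":
            return recon
        return np.vstack([d.coefficient_vector() for d in decomps])
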