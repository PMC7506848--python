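"""Synthetic NIR spectra with known ground truth.

The generator emulates powdered-seed NIR measurements over 900-1700 nm:
each spectrum is a sum of smooth Gaussian absorption bands whose amplitudes
depend linearly on the sample's lipid content (the C-H overtone bands near
1210 and 1390 nm carry the lipid signal) plus small class-specific band
offsets that separate the three growing regions, all degraded by
multiplicative scatter, a random sloped baseline, and white noise:

    x_i(lambda) = m_i * sum_b A_b(lipid_i, class_i) * G(lambda; c_b, w_b)
                  + s_i * (lambda - lambda_min) / range + eps_i(lambda)

with m_i ~ N(1, scatter_sd), s_i ~ N(0, baseline_slope_sd) and eps white
Gaussian. Lipid contents are drawn per class from truncated normals whose
means/SDs/ranges match gravimetric reference statistics for the three
regions, so descriptive tables of the synthetic reference data resemble the
real ones. Every dataset ships with a ground-truth record (lipid, class,
informative band indices) so selection methods can be scored for hit rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SpectraSet, SplitPlan

__all__ = ["SyntheticConfig", "generate_dataset", "reference_statistics"]

# per-class reference lipid statistics: mean, SD, min, max (percent)
DEFAULT_LIPID_STATS = {
    "Changbai": (60.90, 0.76, 59.70, 62.30),
    "Yichun": (63.01, 0.27, 62.60, 63.40),
    "Heihe": (61.17, 0.52, 60.30, 62.20),
}


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic NIR generator.

    Defaults give 3 balanced classes x 40 samples on a 511-band grid over
    900-1700 nm with lipid contents inside 59.7-63.4%.
    """

    n_per_class: int = 40
    class_names: tuple = ("Changbai", "Yichun", "Heihe")
    n_bands: int = 511
    wavelength_range: tuple = (900.0, 1700.0)
    band_centers: tuple = (930.0, 1040.0, 1210.0, 1390.0, 1450.0, 1650.0)
    band_widths: tuple = (25.0, 45.0, 35.0, 40.0, 50.0, 40.0)
    base_amplitudes: tuple = (0.25, 0.45, 0.70, 0.55, 0.80, 0.40)
    # absorbance change per percent lipid, per band (C-H overtones carry it)
    lipid_coefficients: tuple = (0.0, 0.0, 0.012, 0.009, 0.0, 0.0)
    # additive band-amplitude perturbation per class
    class_offsets: dict = field(default_factory=lambda: {
        "Changbai": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        "Yichun": (0.07, 0.0, 0.0, 0.0, -0.05, 0.0),
        "Heihe": (0.0, 0.07, 0.0, 0.0, 0.0, -0.05),
    })
    lipid_stats: dict = field(default_factory=lambda: dict(DEFAULT_LIPID_STATS))
    lipid_range: tuple = (59.7, 63.4)
    lipid_reference: float = 61.5  # amplitude anchor (mid-range lipid, %)
    scatter_sd: float = 0.05
    baseline_slope_sd: float = 0.02
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_bands < 8:
            raise ValueError("invalid sample or band count")
        if self.wavelength_range[0] >= self.wavelength_range[1]:
            raise ValueError("invalid wavelength range")
        if self.lipid_range[0] >= self.lipid_range[1]:
            raise ValueError("invalid lipid range")
        sizes = {len(self.band_centers), len(self.band_widths),
                 len(self.base_amplitudes), len(self.lipid_coefficients)}
        if len(sizes) != 1:
            raise ValueError("band parameter tuples must have equal length")
        for name in self.class_names:
            if name not in self.lipid_stats or name not in self.class_offsets:
                raise ValueError(f"missing per-class parameters for {name!r}")
        if min(self.scatter_sd, self.baseline_slope_sd, self.noise_sd) < 0:
            raise ValueError("noise scales must be nonnegative")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return dist.ppf(rng.uniform(size=size))


def _band_profiles(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = cfg.wavelength_range
    wavelengths = np.linspace(lo, hi, cfg.n_bands)
    centers = np.asarray(cfg.band_centers)
    widths = np.asarray(cfg.band_widths)
    profiles = np.exp(
        -0.5 * ((wavelengths[:, None] - centers[None, :]) / widths[None, :]) ** 2
    )
    return wavelengths, profiles  # (p,), (p, n_bands_components)


def generate_dataset(cfg: SyntheticConfig | None = None
                     ) -> tuple[SpectraSet, dict]:
    """Generate a synthetic dataset plus its ground-truth record.

    Returns ``(SpectraSet, truth)`` where ``truth`` carries the per-sample
    lipid contents and classes, the informative band indices (wavelength
    grid positions where the lipid-sensitivity profile exceeds half its
    maximum), and the config seed. Deterministic given ``cfg.seed``.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    wavelengths, profiles = _band_profiles(cfg)
    n = cfg.n_per_class * len(cfg.class_names)
    p = cfg.n_bands

    lipid = np.empty(n)
    origin = np.empty(n, dtype=object)
    ids = np.empty(n, dtype=object)
    row = 0
    for name in cfg.class_names:
        mean, sd, lo, hi = cfg.lipid_stats[name]
        lo = max(lo, cfg.lipid_range[0])
        hi = min(hi, cfg.lipid_range[1])
        vals = _truncated_normal(rng, mean, sd, lo, hi, cfg.n_per_class)
        for k in range(cfg.n_per_class):
            lipid[row] = vals[k]
            origin[row] = name
            ids[row] = f"{name[0]}{row + 1}"
            row += 1

    base = np.asarray(cfg.base_amplitudes)
    coef = np.asarray(cfg.lipid_coefficients)
    X = np.empty((n, p))
    lo_wl, hi_wl = cfg.wavelength_range
    ramp = (wavelengths - lo_wl) / (hi_wl - lo_wl)
    scatter = rng.normal(1.0, cfg.scatter_sd, size=n) if cfg.scatter_sd else np.ones(n)
    slopes = (rng.normal(0.0, cfg.baseline_slope_sd, size=n)
              if cfg.baseline_slope_sd else np.zeros(n))
    for i in range(n):
        amps = (base + coef * (lipid[i] - cfg.lipid_reference)
                + np.asarray(cfg.class_offsets[origin[i]]))
        clean = profiles @ amps
        X[i] = scatter[i] * clean + slopes[i] * ramp
    if cfg.noise_sd:
        X += rng.normal(0.0, cfg.noise_sd, size=X.shape)

    sensitivity = np.abs(profiles @ coef)
    informative = (np.flatnonzero(sensitivity > 0.5 * sensitivity.max())
                   if sensitivity.max() > 0 else np.array([], dtype=int))
    data = SpectraSet(
        wavelengths=wavelengths,
        absorbance=X,
        sample_ids=ids,
        origin=origin,
        lipid=lipid,
    )
    truth = {
        "lipid": lipid.copy(),
        "origin": origin.copy(),
        "informative_bands": informative,
        "lipid_sensitivity": sensitivity,
        "seed": cfg.seed,
    }
    return data, truth


def reference_statistics(data: SpectraSet,
                         plan: SplitPlan | None = None) -> pd.DataFrame:
    """Descriptive table of the reference lipid contents.

    One row per origin group (when labels exist), optional calibration /
    prediction rows (when a split plan is given), and a Total row. Columns:
    Mean, Min, Max, SD (sample SD) and CV = SD / Mean * 100.
    """
    if data.lipid is None:
        raise ValueError("reference statistics need lipid values")

    def describe(values: np.ndarray) -> dict:
        values = np.asarray(values, dtype=float)
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        mean = float(values.mean())
        return {
            "n": int(values.size),
            "Mean": mean,
            "Min": float(values.min()),
            "Max": float(values.max()),
            "SD": sd,
            "CV": 100.0 * sd / mean,
        }

    rows = {}
    if data.origin is not None:
        for name in dict.fromkeys(data.origin.tolist()):
            rows[str(name)] = describe(data.lipid[data.origin == name])
    if plan is not None:
        rows["Calibration set"] = describe(data.lipid[plan.calibration_indices])
        rows["Prediction set"] = describe(data.lipid[plan.prediction_indices])
    rows["Total"] = describe(data.lipid)
    return pd.DataFrame(rows).T
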