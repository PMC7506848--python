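import math

import numpy as np
import pytest
import pywt

from nirchem import (ThresholdSpec, WaveletCompressor, apply_threshold,
                     compress_spectra, compute_threshold, dwt_multilevel,
                     estimate_noise_sigma, idwt_multilevel, prd, snv)
from nirchem.exceptions import StructureError
from nirchem.wavelet import PAPER_FILTERS, _sure_threshold

# ---------------------------------------------------------------------------
# independent single-level DWT oracle (periodized circular convolution):
# a[k] = sum_m h[m] x[(2k + L/2 - m) mod N]  for even N, filter length L


def _oracle_dwt_level(x, filter_name):
    w = pywt.Wavelet(filter_name)
    N = x.size
    out = []
    for filt in (np.asarray(w.dec_lo), np.asarray(w.dec_hi)):
        L = filt.size
        y = np.array([
            sum(filt[m] * x[(2 * k + L // 2 - m) % N] for m in range(L))
            for k in range(N // 2)
        ])
        out.append(y)
    return out  # [approx, detail]


def _oracle_dwt_multilevel(x, filter_name, levels):
    details = []
    approx = x
    for _ in range(levels):
        approx, d = _oracle_dwt_level(approx, filter_name)
        details.append(d)
    return approx, details  # details finest first


class TestDWT:
    def test_constant_signal_has_zero_details(self):
        decomp = dwt_multilevel(np.ones(4), "haar", levels=1)
        np.testing.assert_allclose(decomp.details[0], 0, atol=1e-14)

    @pytest.mark.parametrize("filter_name", ["db9", "sym8", "coif4"])
    def test_matches_convolution_matrix_oracle(self, rng, filter_name):
        x = rng.normal(size=16)
        decomp = dwt_multilevel(x, filter_name, levels=3,
                                extension_mode="periodization")
        oracle_a, oracle_d = _oracle_dwt_multilevel(x, filter_name, 3)
        np.testing.assert_allclose(decomp.approx, oracle_a, atol=1e-10)
        for got, want in zip(decomp.details, oracle_d):
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_transform_is_linear(self, rng):
        x, y = rng.normal(size=(2, 64))
        dx = dwt_multilevel(x, "db9", 3)
        dy = dwt_multilevel(y, "db9", 3)
        dxy = dwt_multilevel(x + y, "db9", 3)
        np.testing.assert_allclose(dxy.approx, dx.approx + dy.approx,
                                   atol=1e-10)
        for s, a, b in zip(dxy.details, dx.details, dy.details):
            np.testing.assert_allclose(s, a + b, atol=1e-10)

    def test_excessive_depth_rejected(self):
        with pytest.raises(ValueError):
            dwt_multilevel(np.ones(4), "haar", levels=3)

    @pytest.mark.parametrize("filter_name", PAPER_FILTERS)
    @pytest.mark.parametrize("levels", [1, 2, 3])
    @pytest.mark.parametrize("length", [100, 511, 512, 1000])
    def test_perfect_reconstruction(self, rng, filter_name, levels, length):
        x = rng.normal(size=length)
        rec = idwt_multilevel(dwt_multilevel(x, filter_name, levels))
        np.testing.assert_allclose(rec, x, atol=1e-8)

    @pytest.mark.parametrize("filter_name", ["db9", "sym8", "coif4"])
    def test_energy_conservation_orthogonal_periodized(self, rng, filter_name):
        x = rng.normal(size=512)
        decomp = dwt_multilevel(x, filter_name, 3,
                                extension_mode="periodization")
        energy = np.sum(decomp.approx**2) + sum(
            np.sum(d**2) for d in decomp.details)
        assert energy == pytest.approx(np.sum(x**2), abs=1e-8)

    def test_zeroing_details_of_constant_signal_changes_nothing(self):
        x = np.full(64, 3.0)
        decomp = dwt_multilevel(x, "db9", 2)
        for i in range(len(decomp.details)):
            decomp.details[i] = np.zeros_like(decomp.details[i])
        np.testing.assert_allclose(idwt_multilevel(decomp), x, atol=1e-10)

    def test_corrupted_shapes_are_a_structure_error(self, rng):
        decomp = dwt_multilevel(rng.normal(size=100), "db9", 2)
        decomp.details[0] = decomp.details[0][:-3]
        with pytest.raises(StructureError):
            idwt_multilevel(decomp)


class TestNoiseSigma:
    def test_mad_formula(self, rng):
        decomp = dwt_multilevel(rng.normal(size=64), "haar", 1)
        decomp.details[0] = np.array([-1.0, 1.0, -1.0, 1.0])
        decomp.levels = 1
        assert estimate_noise_sigma(decomp) == pytest.approx(1 / 0.6745)

    def test_zero_details_give_zero_sigma(self):
        decomp = dwt_multilevel(np.ones(16), "haar", 1)
        assert estimate_noise_sigma(decomp) == 0.0

    def test_single_coefficient(self, rng):
        decomp = dwt_multilevel(rng.normal(size=16), "haar", 1)
        decomp.details[0] = np.array([-3.0])
        assert estimate_noise_sigma(decomp) == pytest.approx(3 / 0.6745)


class TestThresholds:
    def test_universal_threshold_closed_form(self, rng):
        # sigma = 1, N = e^2  ->  lambda = sqrt(2 ln e^2) = 2
        x = rng.normal(size=8)
        decomp = dwt_multilevel(x, "haar", 1)
        decomp.original_length = int(round(math.e**2))
        spec = compute_threshold(decomp, "donoho", noise_sigma=1.0)
        assert spec.per_level_thresholds[0] == pytest.approx(
            math.sqrt(2 * math.log(decomp.original_length)))
        assert spec.shrink_rule == "hard"
        soft_spec = compute_threshold(decomp, "soft", noise_sigma=1.0)
        np.testing.assert_allclose(soft_spec.per_level_thresholds,
                                   spec.per_level_thresholds)
        assert soft_spec.shrink_rule == "soft"

    def test_sure_matches_brute_force_risk_scan(self, rng):
        d = rng.normal(size=16) * 2.0
        sigma = 1.3

        def sure_risk(t):
            y = np.abs(d) / sigma
            return (y.size - 2 * np.sum(y <= t)
                    + np.sum(np.minimum(y**2, t**2)))

        candidates = np.concatenate([[0.0], np.abs(d) / sigma])
        best = candidates[np.argmin([sure_risk(t) for t in candidates])]
        assert _sure_threshold(d, sigma) == pytest.approx(sigma * best)

    def test_birge_massart_keep_counts(self, rng):
        decomp = dwt_multilevel(rng.normal(size=256), "haar", 3)
        alpha = 1.5
        spec = compute_threshold(decomp, "birge_massart", bm_alpha=alpha)
        thresholded, _ = apply_threshold(decomp, spec)
        m = decomp.approx.size
        # j = 1 at the coarsest detail level
        for j in range(1, 4):
            keep = int(round(m / (2.0 + j) ** alpha))
            level = thresholded.details[3 - j]
            expect = min(keep, level.size)
            assert np.sum(level != 0) == expect
            # retained coefficients are exactly the largest-magnitude ones
            original = decomp.details[3 - j]
            top = set(np.argsort(np.abs(original))[::-1][:expect].tolist())
            assert set(np.flatnonzero(level != 0).tolist()) == top

    def test_unknown_strategy_rejected(self, rng):
        decomp = dwt_multilevel(rng.normal(size=64), "haar", 2)
        with pytest.raises(ValueError):
            compute_threshold(decomp, "magic")


class TestApplyThreshold:
    @pytest.mark.parametrize("rule,value,lam,expected", [
        ("soft", 3.0, 1.0, 2.0),
        ("soft", -0.5, 1.0, 0.0),
        ("hard", 3.0, 1.0, 3.0),
        ("hard", 0.5, 1.0, 0.0),
    ])
    def test_shrinkage_rules(self, rng, rule, value, lam, expected):
        decomp = dwt_multilevel(rng.normal(size=16), "haar", 1)
        decomp.details[0] = np.array([value])
        decomp.details[0] = np.asarray(decomp.details[0], dtype=float)
        spec = ThresholdSpec(strategy="donoho",
                             per_level_thresholds=[lam],
                             shrink_rule=rule, noise_sigma=1.0)
        out, _ = apply_threshold(decomp, spec)
        assert out.details[0][0] == pytest.approx(expected)

    def test_zero_threshold_is_identity(self, rng):
        x = rng.normal(size=128)
        decomp = dwt_multilevel(x, "db9", 3)
        spec = ThresholdSpec(strategy="donoho",
                             per_level_thresholds=[0.0, 0.0, 0.0],
                             shrink_rule="hard", noise_sigma=0.0)
        out, report = apply_threshold(decomp, spec)
        assert report.compression_rate == 0.0
        assert prd(x, idwt_multilevel(out)) < 1e-8

    def test_approximation_is_never_touched(self, rng):
        decomp = dwt_multilevel(rng.normal(size=128), "db9", 3)
        spec = ThresholdSpec(strategy="donoho",
                             per_level_thresholds=[np.inf] * 3,
                             shrink_rule="hard", noise_sigma=1.0)
        out, _ = apply_threshold(decomp, spec)
        np.testing.assert_array_equal(out.approx, decomp.approx)
        assert all(np.all(d == 0) for d in out.details)


class TestPRD:
    def test_identical_signals(self):
        assert prd([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_zero_reconstruction_gives_100(self, rng):
        x = rng.normal(size=10)
        assert prd(x, np.zeros(10)) == pytest.approx(100.0)

    def test_scaled_residual(self):
        x = np.array([3.0, 4.0])
        assert prd(x, 0.9 * x) == pytest.approx(10.0)

    def test_scale_invariance(self, rng):
        x = rng.normal(size=30)
        r = x + rng.normal(size=30) * 0.01
        assert prd(7.3 * x, 7.3 * r) == pytest.approx(prd(x, r))

    def test_all_zero_original_rejected(self):
        with pytest.raises(ZeroDivisionError):
            prd(np.zeros(5), np.ones(5))


class TestCompressSpectra:
    def test_smooth_spectra_compress_well_with_low_distortion(
            self, default_dataset):
        """Smooth NIR-like spectra have sparse details: the universal
        threshold removes most coefficients at sub-percent distortion."""
        data, _ = default_dataset
        _, report, _ = compress_spectra(snv(data), "bior4.4", 3, "donoho")
        assert report.prd < 1.0
        assert report.compression_rate > 50.0

    def test_noiseless_spectra_reconstruct_almost_exactly(
            self, clean_dataset):
        data, _ = clean_dataset
        _, report, _ = compress_spectra(snv(data), "bior4.4", 3, "donoho")
        assert report.prd < 0.01

    def test_soft_is_at_least_as_distorting_as_hard_universal(
            self, default_dataset):
        data, _ = default_dataset
        source = snv(data)
        _, donoho, _ = compress_spectra(source, "bior4.4", 3, "donoho")
        _, soft, _ = compress_spectra(source, "bior4.4", 3, "soft")
        assert soft.prd >= donoho.prd

    def test_monotonicity_in_threshold(self, default_dataset):
        """Larger lambda can only zero more coefficients and distort more
        (provable for an orthogonal filter under periodization)."""
        data, _ = default_dataset
        x = snv(data).absorbance[0]
        decomp = dwt_multilevel(x, "sym8", 3, extension_mode="periodization")
        base = compute_threshold(decomp, "donoho")
        rates, prds = [], []
        for scale in [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]:
            spec = ThresholdSpec(
                strategy="donoho",
                per_level_thresholds=base.per_level_thresholds * scale,
                shrink_rule="hard", noise_sigma=base.noise_sigma)
            out, report = apply_threshold(decomp, spec)
            rates.append(report.compression_rate)
            prds.append(prd(x, idwt_multilevel(out)))
        assert all(a <= b + 1e-12 for a, b in zip(rates, rates[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(prds, prds[1:]))

    def test_transformer_coefficient_output_shape_is_consistent(
            self, default_dataset):
        data, _ = default_dataset
        wc = WaveletCompressor(output="coefficients").fit(data.absorbance)
        C = wc.transform(data.absorbance[:5])
        decomp = dwt_multilevel(data.absorbance[0], "bior4.4", 3)
        assert C.shape == (5, decomp.n_coefficients)
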