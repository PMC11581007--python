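"""Tests of the tuning/performance descriptors (SSI, TSI, MPS, tiling...)."""

import numpy as np
import pytest

from tunespace.metrics import (ResponseField, TuningCurve, classify_spike_width,
                               modulation_power_spectrum,
                               noise_corrected_prediction_correlation,
                               signal_correlation, subspace_similarity_index,
                               tiling_overlap, tuning_curve,
                               tuning_symmetry_index)


def fourier_filter_set(n=4, shape=(32, 25)):
    """Orthogonal, zero-mean 2-D Fourier basis elements (flattened-orthonormal)."""
    F, U = shape
    f = np.arange(F)[:, None]
    u = np.arange(U)[None, :]
    filters = []
    for kf, ku, fn in [(1, 0, np.cos), (2, 0, np.cos), (0, 1, np.cos), (1, 1, np.sin)]:
        g = fn(2 * np.pi * (kf * f / F + ku * u / U))
        g = g - g.mean()
        filters.append(g / np.linalg.norm(g))
    return np.stack(filters[:n])


class TestSSI:
    def test_self_similarity_is_one(self):
        filters = fourier_filter_set()
        assert subspace_similarity_index(filters, filters, 4) == pytest.approx(1.0,
                                                                               abs=1e-10)

    def test_disjoint_support_gives_zero(self):
        # zero-mean dipole filters living on disjoint channel blocks
        a = np.zeros((2, 8, 6))
        b = np.zeros((2, 8, 6))
        a[0, 0, 0], a[0, 1, 0] = 1.0, -1.0
        a[1, 2, 3], a[1, 3, 3] = 1.0, -1.0
        b[0, 4, 1], b[0, 5, 1] = 1.0, -1.0
        b[1, 6, 2], b[1, 7, 2] = 1.0, -1.0
        assert subspace_similarity_index(a, b) == pytest.approx(0.0, abs=1e-10)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((3, 8, 6))
        b = rng.standard_normal((3, 8, 6))
        assert subspace_similarity_index(a, -b) == pytest.approx(
            subspace_similarity_index(a, b), abs=1e-12)

    def test_symmetry_when_counts_match(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((4, 8, 6))
        b = rng.standard_normal((4, 8, 6))
        assert subspace_similarity_index(a, b) == pytest.approx(
            subspace_similarity_index(b, a), abs=1e-12)

    def test_normalizes_by_smaller_filter_count(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((2, 8, 6))
        ssi = subspace_similarity_index(a, a[:1], n_filters=4)
        # one matching filter out of min(2,1)=1
        assert ssi >= 1.0


def curve_from(f, n_bins=20):
    x = np.linspace(-1, 1, n_bins)
    return TuningCurve(x_centers=x, y=f(x))


class TestTSI:
    def test_monotone_curve_is_zero(self):
        assert tuning_symmetry_index(curve_from(lambda x: x)) == pytest.approx(0.0,
                                                                               abs=1e-12)

    def test_downward_parabola_is_minus_one(self):
        assert tuning_symmetry_index(curve_from(lambda x: -x ** 2)) == pytest.approx(
            -1.0, abs=1e-12)

    def test_upward_parabola_is_plus_one(self):
        assert tuning_symmetry_index(curve_from(lambda x: x ** 2)) == pytest.approx(
            1.0, abs=1e-12)

    def test_invariant_to_offset_and_positive_scaling(self):
        base = curve_from(lambda x: x ** 2 - 0.2 * x)
        t0 = tuning_symmetry_index(base)
        shifted = TuningCurve(base.x_centers, 3.5 * base.y + 11.0)
        assert tuning_symmetry_index(shifted) == pytest.approx(t0, abs=1e-12)

    def test_negation_flips_parabola_symmetry(self):
        up = tuning_symmetry_index(curve_from(lambda x: x ** 2))
        down = tuning_symmetry_index(curve_from(lambda x: -x ** 2))
        assert up == pytest.approx(-down, abs=1e-12)

    def test_flat_curve_flagged_missing(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(tuning_symmetry_index(curve_from(lambda x: 0 * x)))

    def test_too_few_bins_raises(self):
        c = TuningCurve(np.array([-1.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            tuning_symmetry_index(c)


class TestTuningCurveBinning:
    def test_recovers_known_function_of_projection(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20000)
        rate = x ** 2
        curve = tuning_curve(x, rate, n_bins=20)
        # binned means should track the parabola up to binning width
        assert np.corrcoef(curve.y, curve.x_centers ** 2)[0, 1] > 0.99

    def test_has_requested_bin_count(self):
        rng = np.random.default_rng(4)
        curve = tuning_curve(rng.standard_normal(1000), rng.standard_normal(1000))
        assert curve.x_centers.shape == (20,) and curve.y.shape == (20,)


class TestPredictionCorrelation:
    def test_noiseless_raster_reduces_to_pearson(self):
        rng = np.random.default_rng(5)
        signal = rng.standard_normal(500)
        pred = signal + 0.5 * rng.standard_normal(500)
        raster = np.tile(signal, (4, 1))
        expected = np.corrcoef(pred, signal)[0, 1]
        got = noise_corrected_prediction_correlation(pred, raster)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_recovers_unity_for_true_signal_with_noise(self):
        rng = np.random.default_rng(6)
        signal = rng.standard_normal(3000)
        raster = signal[None, :] + 0.8 * rng.standard_normal((20, 3000))
        got = noise_corrected_prediction_correlation(signal, raster)
        assert got == pytest.approx(1.0, abs=0.05)

    def test_independent_prediction_near_zero(self):
        rng = np.random.default_rng(7)
        signal = rng.standard_normal(1000)
        raster = signal[None, :] + 0.3 * rng.standard_normal((10, 1000))
        pred = rng.standard_normal(1000)
        assert abs(noise_corrected_prediction_correlation(pred, raster)) <= 0.1

    def test_zero_variance_prediction_warns_and_returns_zero(self):
        raster = np.random.default_rng(8).standard_normal((3, 100))
        with pytest.warns(RuntimeWarning):
            assert noise_corrected_prediction_correlation(np.ones(100), raster) == 0.0

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            noise_corrected_prediction_correlation(np.zeros(10), np.zeros((1, 10)))


class TestSignalCorrelation:
    def test_identical_and_negated(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal(200)
        assert signal_correlation(a, a) == pytest.approx(1.0, abs=1e-12)
        assert signal_correlation(a, -a) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(10)
        a, b = rng.standard_normal((2, 300))
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        expected = np.mean(za * zb)
        assert signal_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_flagged(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(signal_correlation(np.ones(10), np.arange(10.0)))


class TestModulationPowerSpectrum:
    def test_pure_ripple_peaks_at_its_modulation_bin(self):
        F, U = 32, 25
        frame_rate = 100.0
        kf, ku = 3, 5  # integer cycles across each axis
        f = np.arange(F)[:, None]
        u = np.arange(U)[None, :]
        filt = np.cos(2 * np.pi * (kf * f / F + ku * u / U))
        power, wt, wf = modulation_power_spectrum(filt, frame_rate=frame_rate,
                                                  channels_per_octave=6.0)
        i_f, i_t = np.unravel_index(np.argmax(power), power.shape)
        assert abs(abs(wt[i_t]) - ku * frame_rate / U) < 1e-9
        assert abs(abs(wf[i_f]) - kf * 6.0 / F) < 1e-9

    def test_parseval_total_power(self):
        rng = np.random.default_rng(11)
        filt = rng.standard_normal((16, 10))
        power, _, _ = modulation_power_spectrum(filt)
        assert power.sum() / filt.size == pytest.approx(np.sum(filt ** 2), rel=1e-10)

    def test_conjugate_symmetry_for_real_filters(self):
        # P(k) == P(-k): power symmetric under joint sign flip of both axes
        rng = np.random.default_rng(12)
        filt = rng.standard_normal((8, 6))
        raw = np.abs(np.fft.fft2(filt)) ** 2
        kf = np.arange(raw.shape[0])[:, None]
        kt = np.arange(raw.shape[1])[None, :]
        assert np.allclose(raw, raw[(-kf) % raw.shape[0], (-kt) % raw.shape[1]],
                           atol=1e-9)


class TestTilingOverlap:
    def test_single_field_max_overlap_one(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 3:6] = True
        res = tiling_overlap([ResponseField(mask)], n_shuffles=10, seed=0)
        assert res["max_overlap"] == 1
        assert res["fraction_max_overlap"] == 1.0

    def test_identical_fields_overlap_fully(self):
        mask = np.zeros((8, 8), bool)
        mask[1:3, 1:3] = True
        res = tiling_overlap([ResponseField(mask)] * 5, n_shuffles=5, seed=1)
        assert res["max_overlap"] == 5

    def test_disjoint_fields_max_overlap_one(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[:2, :2], b[4:, 4:] = True, True
        res = tiling_overlap([ResponseField(a), ResponseField(b)], n_shuffles=5,
                             seed=2)
        assert res["max_overlap"] == 1

    def test_shuffle_preserves_field_areas_and_is_reproducible(self):
        rng = np.random.default_rng(13)
        masks = [ResponseField(rng.random((12, 12)) > 0.7) for _ in range(6)]
        res1 = tiling_overlap(masks, n_shuffles=20, seed=42)
        res2 = tiling_overlap(masks, n_shuffles=20, seed=42)
        assert np.array_equal(res1["shuffled_max_overlap"], res2["shuffled_max_overlap"])
        total_area = sum(m.area for m in masks)
        # toroidal translation preserves area, so the summed overlap map is conserved
        assert res1["overlap_map"].sum() == total_area
        assert np.all(res1["shuffled_max_overlap"] <= len(masks))

    def test_empty_field_list_raises(self):
        with pytest.raises(ValueError):
            tiling_overlap([])


class TestSpikeWidth:
    @pytest.mark.parametrize("width,threshold,expected", [
        (0.2, 0.35, "narrow"),
        (0.5, 0.35, "regular"),
        (0.35, 0.35, "regular"),   # tie resolves to regular
        (0.36, 0.375, "narrow"),
    ])
    def test_classification(self, width, threshold, expected):
        assert classify_spike_width(width, threshold) == expected

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            classify_spike_width(0.0, 0.35)
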