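"""Morlet CWT and importance-weighted wavelet feature contracts."""

import numpy as np
import pytest

from sleepvol.bands import ALPHA, DELTA, THETA, SPINDLE, BandDefinition
from sleepvol import wavelets as wv

FS = 100.0


def loop_energy(coeffs, b):
    total = 0.0
    for w, bi in zip(np.ravel(coeffs), np.ravel(b)):
        total += abs(w) ** 2 * bi
    return total


def loop_entropy(coeffs, b):
    w = np.abs(np.ravel(coeffs)) ** 2
    p = w / w.sum()
    total = 0.0
    for pi, bi in zip(p, np.ravel(b)):
        if pi > 0 and bi > 0:
            total -= pi * np.log(pi * bi)
    return total


class TestCwt:
    def test_zero_signal_gives_zero_coefficients(self):
        res = wv.morlet_cwt(np.zeros(500), [0.1, 0.2], sample_rate=FS)
        np.testing.assert_allclose(res.coefficients, 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=400), rng.normal(size=400)
        scales = wv.scales_for_band(ALPHA, 5, sample_rate=FS)
        wxy = wv.morlet_cwt(x + y, scales, sample_rate=FS).coefficients
        wx = wv.morlet_cwt(x, scales, sample_rate=FS).coefficients
        wy = wv.morlet_cwt(y, scales, sample_rate=FS).coefficients
        np.testing.assert_allclose(wxy, wx + wy, atol=1e-10)

    def test_sine_peaks_at_matching_scale(self):
        f0 = 10.0
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * f0 * t)
        scales = wv.scales_for_band(BandDefinition("wide", 5.0, 20.0), 30,
                                    sample_rate=FS)
        res = wv.morlet_cwt(x, scales, sample_rate=FS)
        power = np.abs(res.coefficients[:, 500:-500]).mean(axis=1)
        peak_freq = res.frequencies[np.argmax(power)]
        freqs = res.frequencies
        step = np.max(np.abs(np.diff(freqs)))
        assert abs(peak_freq - f0) <= step + 1e-9

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            wv.morlet_cwt(np.ones(100), [], sample_rate=FS)

    def test_agrees_with_pywavelets_ridge(self):
        """Independent route: pywt's complex-Morlet CWT finds the same
        spectral ridge for a pure tone."""
        pywt = pytest.importorskip("pywt")
        f0 = 6.0
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * f0 * t)
        scales = wv.scales_for_band(BandDefinition("w", 2.0, 15.0), 25,
                                    sample_rate=FS)
        ours = wv.morlet_cwt(x, scales, sample_rate=FS)
        ours_peak = ours.frequencies[
            np.argmax(np.abs(ours.coefficients[:, 300:-300]).mean(axis=1))]
        # pywt scales are in samples; cmorB-C has center frequency C
        pywt_scales = pywt.frequency2scale("cmor1.5-1.0",
                                           ours.frequencies / FS)
        coeffs, freqs = pywt.cwt(x, pywt_scales, "cmor1.5-1.0",
                                 sampling_period=1 / FS)
        pywt_peak = freqs[
            np.argmax(np.abs(coeffs[:, 300:-300]).mean(axis=1))]
        assert abs(ours_peak - pywt_peak) < 0.5


class TestScales:
    def test_endpoints_map_back_to_band_edges(self):
        scales = wv.scales_for_band(THETA, 12, sample_rate=FS)
        freqs = wv.scale_to_frequency(scales)
        assert abs(freqs[0] - THETA.low) / THETA.low < 0.01
        assert abs(freqs[-1] - THETA.high) / THETA.high < 0.01

    def test_single_bin_sits_at_geometric_center(self):
        scales = wv.scales_for_band(THETA, 1, sample_rate=FS)
        assert len(scales) == 1
        f = wv.scale_to_frequency(scales)[0]
        np.testing.assert_allclose(f, np.sqrt(THETA.low * THETA.high))

    def test_scales_decrease_with_frequency(self):
        scales = wv.scales_for_band(DELTA, 8, sample_rate=FS)
        assert np.all(np.diff(scales) < 0)


class TestFeatureFormulas:
    def test_energy_examples(self):
        assert wv.wavelet_energy([1.0, 2.0j], np.zeros(2)) == 0.0
        assert wv.wavelet_energy([1.0, 2.0j]) == pytest.approx(5.0)

    def test_energy_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(4, 7)) + 1j * rng.normal(size=(4, 7))
        b = rng.random((4, 7))
        np.testing.assert_allclose(wv.wavelet_energy(c, b),
                                   loop_energy(c, b))

    def test_energy_weight_validation(self):
        with pytest.raises(ValueError):
            wv.wavelet_energy([1.0, 2.0], [0.5])
        with pytest.raises(ValueError):
            wv.wavelet_energy([1.0], [1.5])

    def test_mean_examples(self):
        assert wv.wavelet_mean([1.0, 2.0, 3.0]) == pytest.approx(2.0)
        assert wv.wavelet_mean([1.0, 2.0, 3.0], np.zeros(3)) == 0.0
        with pytest.raises(ValueError):
            wv.wavelet_mean([])

    def test_mean_complex_variant(self):
        c = np.array([1 + 1j, -1 + 1j])
        assert wv.wavelet_mean(c, magnitude=False) == pytest.approx(1j)
        assert wv.wavelet_mean(c) == pytest.approx(np.sqrt(2))

    def test_entropy_uniform_is_log_n(self):
        c = np.full(16, 3.0 + 4.0j)
        assert wv.wavelet_entropy(c) == pytest.approx(np.log(16))

    def test_entropy_single_coefficient_is_zero(self):
        assert wv.wavelet_entropy([0.0, 5.0, 0.0]) == pytest.approx(0.0)

    def test_entropy_matches_loop_oracle_with_exclusions(self):
        rng = np.random.default_rng(2)
        c = rng.normal(size=20) + 1j * rng.normal(size=20)
        b = rng.random(20)
        b[[3, 7]] = 0.0  # excluded terms
        np.testing.assert_allclose(wv.wavelet_entropy(c, b),
                                   loop_entropy(c, b))

    def test_entropy_all_zero_raises(self):
        with pytest.raises(ValueError):
            wv.wavelet_entropy(np.zeros(5))

    def test_entropy_scale_invariance(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=30) + 1j * rng.normal(size=30)
        np.testing.assert_allclose(wv.wavelet_entropy(c),
                                   wv.wavelet_entropy(1000.0 * c))

    def test_energy_is_homogeneous_of_degree_two(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=600)
        scales = wv.scales_for_band(ALPHA, 6, sample_rate=FS)
        e1 = wv.wavelet_energy(
            wv.morlet_cwt(x, scales, sample_rate=FS).coefficients)
        e3 = wv.wavelet_energy(
            wv.morlet_cwt(3.0 * x, scales, sample_rate=FS).coefficients)
        np.testing.assert_allclose(e3, 9.0 * e1, rtol=1e-10)

    def test_entropy_maximal_iff_uniform(self):
        # any perturbation away from uniform magnitudes lowers the entropy
        n = 6
        uniform = np.ones(n, dtype=complex)
        h_max = wv.wavelet_entropy(uniform)
        assert h_max == pytest.approx(np.log(n))
        rng = np.random.default_rng(5)
        for _ in range(25):
            perturbed = uniform * (1 + 0.3 * rng.random(n))
            if np.ptp(np.abs(perturbed)) > 1e-12:
                assert wv.wavelet_entropy(perturbed) < h_max


class TestShannonEntropy:
    def test_uniform_over_k_bins(self):
        vals = np.repeat(np.arange(5), 40)
        assert wv.shannon_entropy(vals, bins=5) == pytest.approx(np.log(5))

    def test_constant_input_is_degenerate_zero(self):
        assert wv.shannon_entropy(np.full(50, 2.5)) == 0.0

    def test_matches_independent_binned_oracle(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=500)
        bins = 10
        edges = np.unique(np.quantile(vals, np.linspace(0, 1, bins + 1)))
        counts, _ = np.histogram(vals, bins=edges)
        p = counts / counts.sum()
        p = p[p > 0]
        expected = -np.sum(p * np.log(p))
        assert wv.shannon_entropy(vals, bins=bins) == pytest.approx(
            expected, rel=1e-6)

    def test_log_base_conversion(self):
        vals = np.repeat(np.arange(4), 25)
        assert wv.shannon_entropy(vals, bins=4, base=2) == pytest.approx(2.0)


class TestEpochwiseFeatures:
    def test_matches_per_epoch_cwt_reduction(self):
        rng = np.random.default_rng(7)
        epochs = rng.normal(size=(3, 400))
        scales = wv.scales_for_band(ALPHA, 4, sample_rate=FS)
        feats = wv.epochwise_features(epochs, scales, 6.0, FS)
        for i in range(3):
            res = wv.morlet_cwt(epochs[i], scales, 6.0, FS)
            assert feats["energy"][i] == pytest.approx(
                wv.wavelet_energy(res.coefficients))
            assert feats["mean"][i] == pytest.approx(
                wv.wavelet_mean(res.coefficients))
            assert feats["entropy"][i] == pytest.approx(
                wv.wavelet_entropy(res.coefficients))


@pytest.fixture(scope="module")
def small_feature_set(tiny_cohort):
    from sleepvol.tensorize import find_stage_bouts
    recs = [r for r in tiny_cohort if r.subject_id == "S000"]
    windows = []
    for rec in recs:
        windows.extend(find_stage_bouts(rec.hypnogram, rec.subject_id,
                                        rec.condition, rec.sample_rate))
    return wv.compute_feature_set(windows, recs,
                                  [DELTA, THETA, ALPHA, SPINDLE],
                                  n_scales=8)


class TestFeatureSet:
    def test_single_window_gives_degenerate_summaries(self, tiny_cohort):
        from sleepvol.tensorize import find_stage_bouts
        rec = tiny_cohort[0]
        windows = find_stage_bouts(rec.hypnogram, rec.subject_id,
                                   rec.condition, rec.sample_rate)[:1]
        fset = wv.compute_feature_set(windows, [rec], [DELTA], n_scales=4)
        assert (fset.summaries[["SEEN", "SEM", "SEE"]] == 0.0).all().all()

    def test_no_windows_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            wv.compute_feature_set([], [tiny_cohort[0]], [DELTA])

    def test_entropy_summary_dominates_majority_of_cells(
            self, small_feature_set):
        """Across band/modality cells, the Shannon entropy of the wavelet
        entropy distribution (SEEN) is mostly the largest of the three
        feature summaries."""
        s = small_feature_set.summaries
        wins = ((s["SEEN"] >= s["SEM"]) & (s["SEEN"] >= s["SEE"])).mean()
        assert wins > 0.5

    def test_ranking_covers_all_cells_and_is_sorted(self, small_feature_set):
        r = small_feature_set.ranking
        assert len(r) == 3 * len(small_feature_set.summaries)
        assert (np.diff(r["shannon_entropy"].to_numpy()) <= 1e-12).all()
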