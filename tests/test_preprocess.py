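"""Filtering, PSD, envelope and ICA conditioning contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from sleepvol.bands import DELTA, BandDefinition
from sleepvol import preprocess as pp

FS = 100.0


def sine(freq, seconds=60.0, fs=FS, amp=1.0):
    t = np.arange(0, seconds, 1.0 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


def interior(x, fraction=0.25):
    n = len(x)
    return x[int(n * fraction):int(n * (1 - fraction))]


class TestFirDesign:
    def test_passband_gain_within_ripple(self):
        taps = pp.design_bandpass_fir(0.5, 4.0, FS)
        w, h = sps.freqz(taps, worN=16384, fs=FS)
        center = np.abs(h[np.argmin(np.abs(w - 2.25))])
        assert abs(center - 1.0) < 10 ** (1.0 / 20) - 1 + 0.01

    def test_stopband_attenuation(self):
        taps = pp.design_bandpass_fir(0.5, 4.0, FS)
        w, h = sps.freqz(taps, worN=16384, fs=FS)
        stop = np.abs(h[w >= 4.5])
        assert np.all(stop <= 10 ** (-40 / 20) * 1.1)

    def test_linear_phase_symmetry(self):
        taps = pp.design_bandpass_fir(4.0, 8.0, FS)
        np.testing.assert_allclose(taps, taps[::-1], atol=1e-12)

    def test_unmeetable_spec_raises_design_error(self):
        # a 0.025 Hz transition at 100 Hz sampling needs more taps than the
        # admissible maximum
        with pytest.raises(pp.FilterDesignError):
            pp.design_bandpass_fir(0.05, 0.1, FS)


class TestBandpass:
    def test_out_of_band_sine_suppressed(self):
        x = sine(10.0)
        y = pp.bandpass(x, DELTA, FS)
        assert interior(y).std() < 0.01 * interior(x).std()

    def test_in_band_sine_preserved_within_one_db(self):
        x = sine(2.0)
        y = pp.bandpass(x, DELTA, FS)
        assert abs(interior(y).std() / interior(x).std() - 1.0) < 0.12

    def test_zero_in_zero_out_and_length(self):
        x = np.zeros(6000)
        y = pp.bandpass(x, DELTA, FS)
        assert y.shape == x.shape
        np.testing.assert_allclose(y, 0.0)

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError):
            pp.bandpass(np.ones(50), DELTA, FS)

    def test_zero_phase_no_lag_on_in_band_sine(self):
        x = sine(2.0)
        y = pp.bandpass(x, DELTA, FS)
        xc = np.correlate(interior(y), interior(x), mode="full")
        lag = np.argmax(xc) - (len(interior(x)) - 1)
        assert lag == 0


class TestWelch:
    def test_sine_band_power_is_half_amplitude_squared(self):
        psd = pp.welch_psd(sine(5.0), FS)
        bp = pp.band_power(psd, BandDefinition("x", 4.5, 5.5))
        assert abs(bp - 0.5) < 0.025

    def test_white_noise_total_power_matches_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2.0, 100_000)
        psd = pp.welch_psd(x, FS)
        total = np.trapezoid(psd.power, psd.frequencies)
        assert abs(total - np.var(x)) < 0.1 * np.var(x)

    def test_constant_signal_power_concentrates_at_dc(self):
        # all power sits in the DC bin up to the Hamming-taper mainlobe
        psd = pp.welch_psd(np.full(3000, 3.0), FS)
        assert np.argmax(psd.power) == 0
        assert np.all(psd.power[3:] < 1e-10 * psd.power[0])

    def test_short_signal_raises(self):
        with pytest.raises(ValueError):
            pp.welch_psd(np.ones(100), FS)

    @settings(deadline=None, max_examples=8, derandomize=True)
    @given(window=st.sampled_from([4.0, 8.0, 11.0]),
           overlap=st.sampled_from([0.25, 0.5, 0.75]))
    def test_parseval_for_any_window_configuration(self, window, overlap):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1.5, 50_000)
        psd = pp.welch_psd(x, FS, window_seconds=window,
                           overlap_fraction=overlap)
        total = np.trapezoid(psd.power, psd.frequencies)
        assert abs(total - np.var(x)) < 0.1 * np.var(x)


class TestBandPower:
    def test_full_grid_integral_equals_total_power(self):
        psd = pp.welch_psd(np.random.default_rng(1).normal(size=20000), FS)
        full = BandDefinition("full", psd.frequencies[0],
                              psd.frequencies[-1])
        np.testing.assert_allclose(
            pp.band_power(psd, full),
            np.trapezoid(psd.power, psd.frequencies))

    def test_disjoint_bands_sum_to_union(self):
        psd = pp.welch_psd(np.random.default_rng(2).normal(size=20000), FS)
        a = pp.band_power(psd, BandDefinition("a", 1.0, 7.3))
        b = pp.band_power(psd, BandDefinition("b", 7.3, 19.0))
        u = pp.band_power(psd, BandDefinition("u", 1.0, 19.0))
        np.testing.assert_allclose(a + b, u, rtol=1e-10)

    def test_band_outside_grid_raises(self):
        psd = pp.welch_psd(np.zeros(3000) + 1.0, FS)
        with pytest.raises(ValueError):
            pp.band_power(psd, BandDefinition("x", 1.0, 60.0))


class TestHighpass:
    def test_respiration_attenuated(self):
        x = sine(0.25, seconds=120.0)
        y = pp.highpass_physio(x, FS)
        assert interior(y).std() < 0.1 * interior(x).std()  # >= 20 dB

    def test_fast_activity_preserved(self):
        x = sine(10.0)
        y = pp.highpass_physio(x, FS)
        assert abs(interior(y).std() / interior(x).std() - 1.0) < 0.12

    def test_zero_signal(self):
        np.testing.assert_allclose(
            pp.highpass_physio(np.zeros(8000), FS), 0.0)


class TestEnvelopes:
    def test_emg_envelope_plateau_equals_amplitude(self):
        x = sine(30.0, amp=2.0)
        env = interior(pp.emg_envelope(x, FS))
        assert abs(env.mean() - 2.0) < 0.2
        assert env.std() / env.mean() < 0.05

    def test_emg_envelope_zero(self):
        np.testing.assert_allclose(pp.emg_envelope(np.zeros(6000), FS), 0.0)

    def test_emg_envelope_tracks_amplitude_step(self):
        x = sine(30.0)
        x[len(x) // 2:] *= 2.0
        env = pp.emg_envelope(x, FS)
        lo = env[1000:2500].mean()
        hi = env[4000:5500].mean()
        assert abs(hi / lo - 2.0) < 0.2

    def test_eog_condition_plateau_and_step(self):
        x = sine(2.0, seconds=200.0)
        env = interior(pp.eog_condition(x, FS))
        assert abs(env.mean() - 1.0) < 0.1
        x[len(x) // 2:] *= 2.0
        env = pp.eog_condition(x, FS)
        n = len(env)
        ratio = env[int(0.6 * n):int(0.7 * n)].mean() / \
            env[int(0.3 * n):int(0.4 * n)].mean()
        assert abs(ratio - 2.0) < 0.2

    def test_eog_condition_zero(self):
        np.testing.assert_allclose(
            pp.eog_condition(np.zeros(30000), FS), 0.0, atol=1e-12)


class TestRms:
    def test_constant_signal(self):
        np.testing.assert_allclose(pp.rms(np.full(500, -3.0), FS), 3.0)

    def test_sine_long_window(self):
        x = sine(10.0, seconds=20.0)
        r = interior(pp.rms(x, FS, window_ms=2000))
        assert np.all(np.abs(r - 1 / np.sqrt(2)) < 0.02 / np.sqrt(2))

    def test_zero(self):
        np.testing.assert_allclose(pp.rms(np.zeros(500), FS), 0.0)

    def test_length_preserved(self):
        assert len(pp.rms(np.ones(777), FS, window_ms=90)) == 777


class TestDiagnostics:
    def test_rest_stub_passes_through_with_warning(self):
        x = np.random.default_rng(9).normal(size=(2, 500))
        with pytest.warns(UserWarning, match="pass-through"):
            out = pp.rest_rereference(x, FS)
        np.testing.assert_array_equal(out, x)

    def test_psd_csv_round_trip_and_loglog_export(self, tmp_path):
        psd = pp.welch_psd(sine(5.0), FS)
        path = tmp_path / "psd.csv"
        pp.psd_to_csv(psd, path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        np.testing.assert_allclose(data[:, 0], psd.frequencies, rtol=1e-9)
        np.testing.assert_allclose(data[:, 1], psd.power, rtol=1e-9)
        lf, lp = pp.loglog_spectrum(psd)
        assert len(lf) == len(lp) > 0
        assert np.all(np.isfinite(lf)) and np.all(np.isfinite(lp))


class TestOcularArtifactRemoval:
    def _sources(self, n=20000, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / FS
        brain = np.sin(2 * np.pi * 9.0 * t) + 0.5 * rng.normal(size=n)
        eog = sps.sosfiltfilt(
            sps.butter(4, [1.2, 4.0], "bandpass", fs=FS, output="sos"),
            rng.normal(size=n)) * 3.0
        return brain, eog

    def test_eog_contamination_removed(self):
        brain, eog = self._sources()
        eeg = np.vstack([brain + 0.8 * eog, 0.7 * brain + 0.9 * eog])
        cleaned, report = pp.remove_ocular_artifacts(eeg, eog, FS)
        assert report.status == "ok"
        assert len(report.removed_components) >= 1
        for row in cleaned:
            r = np.corrcoef(row, eog)[0, 1]
            assert abs(r) < 0.2

    def test_zero_eog_removes_nothing(self):
        brain, _ = self._sources()
        eeg = np.vstack([brain, brain * 0.5])
        cleaned, report = pp.remove_ocular_artifacts(
            eeg, np.zeros_like(brain), FS)
        assert report.status == "no-eog"
        assert report.removed_components == []
        np.testing.assert_array_equal(cleaned, eeg)

    def test_orthogonal_sources_unchanged(self):
        brain, eog = self._sources(seed=5)
        eeg = np.vstack([brain, np.roll(brain, 37)])
        cleaned, report = pp.remove_ocular_artifacts(eeg, eog, FS)
        if report.status == "ok":
            rel = np.linalg.norm(cleaned - eeg) / np.linalg.norm(eeg)
            assert rel < 0.05
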