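"""Generator contracts: Markov hypnograms, GARCH injection, cohort design."""

import numpy as np
import pytest

from sleepvol import preprocess
from sleepvol.bands import DELTA
from sleepvol.synthgen import (STAGES, CohortSpec, GarchParams, Hypnogram,
                               default_transition_matrix, generate_cohort,
                               generate_hypnogram, generate_recording,
                               simulate_garch_series)
from sleepvol.volatility import Garch11

from conftest import zeroed_signal_config


def _spec(**kw):
    defaults = dict(n_subjects=1, duration_hours=0.5, seed=0)
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestHypnogram:
    def test_absorbing_wake_state_yields_all_wake(self):
        tm = np.eye(len(STAGES))
        hyp = generate_hypnogram(_spec(), "18-29", "placebo", seed=1,
                                 transition_matrix=tm, m_prob=0.0)
        assert set(hyp.stages) == {"W"}

    def test_zero_duration_gives_empty_sequence(self):
        hyp = generate_hypnogram(_spec(duration_hours=0.0), "18-29",
                                 "placebo", seed=1)
        assert len(hyp) == 0

    def test_unknown_group_or_condition_rejected(self):
        with pytest.raises(ValueError):
            generate_hypnogram(_spec(), "90-99", "placebo", seed=1)
        with pytest.raises(ValueError):
            generate_hypnogram(_spec(), "18-29", "vitamin", seed=1)

    def test_transition_rows_sum_to_one(self):
        for gi in range(3):
            for cond in ("placebo", "drug"):
                tm = default_transition_matrix(gi, cond)
                np.testing.assert_allclose(tm.sum(axis=1), 1.0)

    def test_empirical_proportions_match_stationary_distribution(self):
        """10^6 simulated epochs reproduce the eigen-decomposition
        stationary distribution within +/-0.01 per stage."""
        tm = default_transition_matrix(0, "placebo")
        # oracle: left eigenvector of the transition matrix at eigenvalue 1
        vals, vecs = np.linalg.eig(tm.T)
        k = np.argmin(np.abs(vals - 1.0))
        pi = np.real(vecs[:, k])
        pi = pi / pi.sum()

        n = 10 ** 6
        spec = _spec(duration_hours=n * 30.0 / 3600.0)
        hyp = generate_hypnogram(spec, "18-29", "placebo", seed=42,
                                 m_prob=0.0)
        stages = np.asarray(hyp.stages, dtype=object)
        for i, st in enumerate(STAGES):
            assert abs((stages == st).mean() - pi[i]) < 0.01


class TestGarchSimulation:
    def test_degenerate_case_has_constant_variance(self):
        g = GarchParams(alpha0=0.3, alpha1=0.0, beta1=0.0, mu=0.0)
        _, sigma2 = simulate_garch_series(g, 500, seed=0)
        np.testing.assert_allclose(sigma2, 0.3)

    def test_sample_variance_matches_unconditional_variance(self):
        g = GarchParams(alpha0=0.1, alpha1=0.1, beta1=0.8)
        y, _ = simulate_garch_series(g, 100_000, seed=1)
        assert abs(np.var(y) - 1.0) < 0.05

    def test_seed_determinism(self):
        g = GarchParams(alpha0=0.1, alpha1=0.1, beta1=0.8)
        y1, s1 = simulate_garch_series(g, 1000, seed=9)
        y2, s2 = simulate_garch_series(g, 1000, seed=9)
        np.testing.assert_array_equal(y1, y2)
        np.testing.assert_array_equal(s1, s2)

    def test_nonstationary_parameters_rejected(self):
        with pytest.raises(ValueError):
            GarchParams(alpha0=0.1, alpha1=0.5, beta1=0.5)


class TestRecording:
    def test_zero_config_gives_zero_channels(self, flat_hypnogram):
        hyp = flat_hypnogram(["W", "S2", "S3", "R"] * 5)
        rec = generate_recording(hyp, subject_id="S", age=20,
                                 age_group="18-29", sex="F",
                                 condition="placebo", night=1, seed=0,
                                 config=zeroed_signal_config())
        for sig in rec.channels.values():
            np.testing.assert_allclose(sig, 0.0)

    def test_channel_length_conservation(self, hour_recording):
        n = int(1.0 * 3600 * 100)
        for sig in hour_recording.channels.values():
            assert len(sig) == n

    def test_deep_sleep_delta_power_exceeds_wake(self, hour_recording):
        rec = hour_recording
        stages = np.asarray(rec.hypnogram.stages, dtype=object)
        x = rec.channels["EEG Fpz-Cz"]
        ep = rec.epoch_samples

        def delta_power(stage):
            idx = np.where(stages == stage)[0]
            seg = np.concatenate([x[i * ep:(i + 1) * ep] for i in idx])
            psd = preprocess.welch_psd(seg, rec.sample_rate)
            return preprocess.band_power(psd, DELTA)

        assert delta_power("S3") > delta_power("W")

    def test_rem_eye_movements_exceed_deep_sleep(self, hour_recording):
        rec = hour_recording
        stages = np.asarray(rec.hypnogram.stages, dtype=object)
        eog = rec.channels["EOG horizontal"]
        ep = rec.epoch_samples

        def stage_rms(stage):
            idx = np.where(stages == stage)[0]
            seg = np.concatenate([eog[i * ep:(i + 1) * ep] for i in idx])
            return float(np.sqrt(np.mean(seg ** 2)))

        assert stage_rms("R") > stage_rms("S3")

    def test_emg_tone_decreases_with_sleep_depth(self, hour_recording):
        rec = hour_recording
        stages = np.asarray(rec.hypnogram.stages, dtype=object)
        emg = rec.channels["EMG submental"]
        ep = rec.epoch_samples
        tone = {}
        for stage in ("W", "S2", "R"):
            idx = np.where(stages == stage)[0]
            seg = np.concatenate([emg[i * ep:(i + 1) * ep] for i in idx])
            tone[stage] = float(np.sqrt(np.mean(seg ** 2)))
        assert tone["W"] > tone["S2"] > tone["R"]

    def test_empty_hypnogram_rejected(self, flat_hypnogram):
        with pytest.raises(ValueError):
            generate_recording(flat_hypnogram([]), subject_id="S", age=20,
                               age_group="18-29", sex="F",
                               condition="placebo", night=1, seed=0)

    def test_dominant_band_follows_stage_configuration(self, hour_recording):
        """Stage-gain tables put each stage's configured dominant band on
        top; spindle activity peaks in S2 relative to other stages."""
        from sleepvol.synthgen import SignalConfig
        from sleepvol.bands import SPINDLE
        cfg = SignalConfig()
        for stage, bands in (("S3", {"delta", "swa"}), ("S2", {"spindle"}),
                             ("W", {"alpha"})):
            rel = {b: cfg.stage_weights[b][stage]
                   / max(cfg.stage_weights[b].values())
                   for b in cfg.stage_weights}
            assert max(rel, key=rel.get) in bands
        rec = hour_recording
        stages = np.asarray(rec.hypnogram.stages, dtype=object)
        x = rec.channels["EEG Fpz-Cz"]
        ep = rec.epoch_samples

        def spindle_power(stage):
            idx = np.where(stages == stage)[0]
            seg = np.concatenate([x[i * ep:(i + 1) * ep] for i in idx])
            return preprocess.band_power(
                preprocess.welch_psd(seg, rec.sample_rate), SPINDLE)

        assert spindle_power("S2") > spindle_power("W")


class TestCohort:
    def test_count_conservation(self):
        spec = CohortSpec(n_subjects=22, duration_hours=0.05, seed=1)
        recs = generate_cohort(spec)
        assert len(recs) == 44
        conditions = [r.condition for r in recs]
        assert conditions.count("drug") == 22
        assert conditions.count("placebo") == 22

    def test_age_group_sizes_match_study_design(self):
        spec = CohortSpec(n_subjects=22, duration_hours=0.05, seed=1)
        recs = generate_cohort(spec)
        subjects = {r.subject_id: r.age_group for r in recs}
        sizes = [list(subjects.values()).count(g)
                 for g in ("18-29", "30-49", "50-66")]
        assert sizes == [8, 7, 7]

    def test_single_subject_has_both_nights(self):
        spec = CohortSpec(n_subjects=1, duration_hours=0.05, seed=2)
        recs = generate_cohort(spec)
        assert sorted(r.night for r in recs) == [1, 2]
        assert sorted(r.condition for r in recs) == ["drug", "placebo"]

    def test_seed_determinism_bit_identical(self):
        spec = CohortSpec(n_subjects=2, duration_hours=0.05, seed=5)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for ra, rb in zip(a, b):
            assert list(ra.hypnogram.stages) == list(rb.hypnogram.stages)
            for ch in ra.channels:
                np.testing.assert_array_equal(ra.channels[ch],
                                              rb.channels[ch])

    def test_ages_fall_in_group_ranges(self):
        spec = CohortSpec(n_subjects=6, duration_hours=0.05, seed=3)
        for rec in generate_cohort(spec):
            label, lo, hi = next(g for g in spec.age_groups
                                 if g[0] == rec.age_group)
            assert lo <= rec.age <= hi


class TestVolatilityInjection:
    def test_garch_parameters_recoverable_from_epoch_amplitudes(self):
        """Fitting GARCH(1,1) to the generated epoch-amplitude series
        recovers the injected alpha1/beta1 within +/-0.1 at 5000 epochs."""
        truth = GarchParams(alpha0=0.02, alpha1=0.25, beta1=0.65, mu=1.0)
        cfg = zeroed_signal_config(
            band_amplitudes={**{k: 0.0 for k in
                                zeroed_signal_config().band_amplitudes},
                             "gamma": 5.0},
            garch_truth=truth)
        n_epochs = 5000
        hyp = Hypnogram(np.array(["W"] * n_epochs, dtype=object),
                        epoch_seconds=5.0)
        rec = generate_recording(hyp, subject_id="S", age=20,
                                 age_group="18-29", sex="F",
                                 condition="placebo", night=1, seed=17,
                                 config=cfg)
        x = rec.channels["EEG Fpz-Cz"]
        ep = rec.epoch_samples
        amp = np.sqrt(np.mean(x[:n_epochs * ep].reshape(n_epochs, ep) ** 2,
                              axis=1))
        fit = Garch11().fit(amp)
        assert abs(fit.alpha1_ - truth.alpha1) < 0.1
        assert abs(fit.beta1_ - truth.beta1) < 0.1
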