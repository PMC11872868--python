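"""Shared fixtures: small synthetic cohorts and recordings."""

from __future__ import annotations

import numpy as np
import pytest

from sleepvol.synthgen import (CohortSpec, Hypnogram, SignalConfig,
                               generate_cohort, generate_hypnogram,
                               generate_recording)


def zeroed_signal_config(**overrides) -> SignalConfig:
    """A generator config with every amplitude and noise source at zero."""
    cfg = SignalConfig(
        band_amplitudes={k: 0.0 for k in SignalConfig().band_amplitudes},
        background_uv=0.0, sensor_noise_uv=0.0, cardiorespiratory_uv=0.0,
        emg_tone_uv={k: 0.0 for k in SignalConfig().emg_tone_uv},
        eog_base_uv=0.0, coupling_strength=0.0)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@pytest.fixture(scope="session")
def hour_recording():
    """One hour of placebo polysomnography for a young subject."""
    spec = CohortSpec(n_subjects=1, duration_hours=1.0, seed=3)
    hyp = generate_hypnogram(spec, "18-29", "placebo", seed=5)
    return generate_recording(hyp, subject_id="S000", age=25,
                              age_group="18-29", sex="F",
                              condition="placebo", night=1, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two subjects x two nights at 30 minutes, full default structure."""
    spec = CohortSpec(n_subjects=2, duration_hours=0.5, seed=7)
    return generate_cohort(spec)


@pytest.fixture
def flat_hypnogram():
    def make(stages, epoch_seconds=30.0):
        return Hypnogram(np.array(stages, dtype=object), epoch_seconds)
    return make
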