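"""Synthetic multimodal sleep-telemetry cohorts with known statistical structure.

Generates two-night polysomnography (EEG Fpz-Cz, EEG Pz-Oz, horizontal EOG,
submental EMG at 100 Hz, plus a 30-s-epoch R&K hypnogram) for a cohort of
subjects split into three age groups, with one placebo and one drug night
per subject.  The generator builds in, with controllable parameters:

* stage-dependent spectral content (delta/SWA dominance in stages 3-4,
  spindle-band activity in stage 2, mixed theta in REM, alpha in wake);
* EMG tone decreasing with sleep depth and lowest in REM;
* larger slow EOG activity during REM (eye movements);
* age-group effects: multiplicative decline of delta, SWA and spindle
  amplitudes with age;
* condition effects: the drug night halves the ARCH coefficient of the
  injected amplitude-volatility process (reduced volatility);
* GARCH(1,1)-structured epoch-amplitude volatility with known parameters,
  so downstream estimation can be validated by parameter recovery;
* a lagged frontal-to-occipital coupling of the delta component during
  stage 3, so directed-influence estimation has a planted ground truth.

Everything is deterministic given the root seed: randomness flows from one
``numpy.random.SeedSequence`` split per subject, per night, per channel.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "STAGES",
    "MOVEMENT",
    "ALL_LABELS",
    "GarchParams",
    "CohortSpec",
    "Hypnogram",
    "Recording",
    "SignalConfig",
    "default_transition_matrix",
    "generate_hypnogram",
    "simulate_garch_series",
    "generate_recording",
    "generate_cohort",
    "load_signal_config",
    "dump_signal_config",
]

STAGES = ("W", "S1", "S2", "S3", "S4", "R")
MOVEMENT = "M"
ALL_LABELS = STAGES + (MOVEMENT,)

DEFAULT_AGE_GROUPS = (("18-29", 18, 29), ("30-49", 30, 49), ("50-66", 50, 66))
CONDITIONS = ("placebo", "drug")

EEG_FPZ = "EEG Fpz-Cz"
EEG_PZ = "EEG Pz-Oz"
EOG_CH = "EOG horizontal"
EMG_CH = "EMG submental"
CHANNEL_NAMES = (EEG_FPZ, EEG_PZ, EOG_CH, EMG_CH)


@dataclass(frozen=True)
class GarchParams:
    """GARCH(1,1) parameters: sigma2_t = alpha0 + alpha1*eps2_{t-1} + beta1*sigma2_{t-1}."""

    alpha0: float
    alpha1: float
    beta1: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha0 <= 0:
            raise ValueError(f"alpha0 must be > 0, got {self.alpha0}")
        if self.alpha1 < 0 or self.beta1 < 0:
            raise ValueError("alpha1 and beta1 must be >= 0")
        if self.alpha1 + self.beta1 >= 1:
            raise ValueError(
                f"covariance stationarity requires alpha1 + beta1 < 1, got "
                f"{self.alpha1 + self.beta1}")

    @property
    def unconditional_variance(self) -> float:
        return self.alpha0 / (1.0 - self.alpha1 - self.beta1)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level design: sizes, age groups, conditions, timing, seed."""

    n_subjects: int = 22
    age_groups: tuple = DEFAULT_AGE_GROUPS
    conditions: tuple = CONDITIONS
    duration_hours: float = 8.0
    sample_rate: float = 100.0
    epoch_seconds: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        total_s = self.duration_hours * 3600.0
        if abs(total_s / self.epoch_seconds - round(total_s / self.epoch_seconds)) > 1e-9:
            raise ValueError(
                "duration_hours * 3600 must be divisible by epoch_seconds")

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_hours * 3600.0 / self.epoch_seconds))

    @property
    def group_labels(self) -> tuple:
        return tuple(g[0] for g in self.age_groups)

    def group_sizes(self) -> list[int]:
        """Split subjects as evenly as possible; earlier groups take the remainder.

        22 subjects over three groups gives 8/7/7.
        """
        k = len(self.age_groups)
        base, rem = divmod(self.n_subjects, k)
        return [base + (1 if i < rem else 0) for i in range(k)]


@dataclass
class Hypnogram:
    """Sequence of per-epoch R&K stage labels."""

    stages: np.ndarray
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        bad = set(self.stages) - set(ALL_LABELS)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.stages)


@dataclass
class Recording:
    """One subject-night of multimodal signals plus metadata."""

    subject_id: str
    age: int
    age_group: str
    sex: str
    condition: str
    night: int
    channels: dict
    sample_rate: float
    hypnogram: Hypnogram
    truth: GarchParams | None = None

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def epoch_samples(self) -> int:
        return int(round(self.hypnogram.epoch_seconds * self.sample_rate))

    @property
    def duration_hours(self) -> float:
        return self.n_samples / self.sample_rate / 3600.0


# ---------------------------------------------------------------------------
# Hypnogram model: first-order Markov chain at 30-s epoch resolution
# ---------------------------------------------------------------------------

# Base transition matrix over (W, S1, S2, S3, S4, R); rows are normalized at
# use.  Values chosen for realistic bout lengths at 30-s epochs.
_BASE_TRANSITIONS = np.array([
    # W      S1     S2     S3     S4     R
    [0.900, 0.070, 0.015, 0.000, 0.000, 0.015],  # W
    [0.050, 0.790, 0.145, 0.000, 0.000, 0.015],  # S1
    [0.010, 0.030, 0.895, 0.045, 0.005, 0.015],  # S2
    [0.005, 0.000, 0.060, 0.880, 0.050, 0.005],  # S3
    [0.005, 0.000, 0.020, 0.075, 0.890, 0.010],  # S4
    [0.020, 0.020, 0.030, 0.000, 0.000, 0.930],  # R
])

# Age modulation: older groups intrude wake more and reach deep sleep less.
_AGE_WAKE_BOOST = {0: 1.0, 1: 1.6, 2: 2.4}
_AGE_DEEP_FACTOR = {0: 1.0, 1: 0.75, 2: 0.5}
# Drug nights leave consolidated NREM (S2/S3) less often.
_DRUG_EXIT_FACTOR = 0.7


def default_transition_matrix(age_group_index: int = 0,
                              condition: str = "placebo") -> np.ndarray:
    """Stage-transition matrix modulated by age group and condition.

    Rows follow :data:`STAGES` order and sum to 1.
    """
    if age_group_index not in _AGE_WAKE_BOOST:
        raise ValueError(f"unknown age group index {age_group_index}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    m = _BASE_TRANSITIONS.copy()
    w = STAGES.index("W")
    boost = _AGE_WAKE_BOOST[age_group_index]
    deep = _AGE_DEEP_FACTOR[age_group_index]
    for i in range(len(STAGES)):
        if i != w:
            m[i, w] *= boost
    for j in (STAGES.index("S3"), STAGES.index("S4")):
        for i in range(len(STAGES)):
            if i != j:
                m[i, j] *= deep
    if condition == "drug":
        for i in (STAGES.index("S2"), STAGES.index("S3")):
            for j in range(len(STAGES)):
                if j != i:
                    m[i, j] *= _DRUG_EXIT_FACTOR
    return m / m.sum(axis=1, keepdims=True)


def generate_hypnogram(spec: CohortSpec, age_group: str, condition: str,
                       seed, transition_matrix: np.ndarray | None = None,
                       start_stage: str = "W",
                       m_prob: float = 0.002) -> Hypnogram:
    """Simulate a first-order Markov hypnogram.

    Movement ("M") epochs overlay the chain with probability ``m_prob`` per
    epoch: the underlying stage process is unaffected, but the epoch is
    labelled M (and excluded from downstream windows).
    """
    labels = spec.group_labels
    if age_group not in labels:
        raise ValueError(f"unknown age group {age_group!r}; expected {labels}")
    if condition not in spec.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if transition_matrix is None:
        transition_matrix = default_transition_matrix(
            labels.index(age_group), condition)
    tm = np.asarray(transition_matrix, dtype=float)
    if tm.shape != (len(STAGES), len(STAGES)) or np.any(tm < 0):
        raise ValueError("transition matrix must be nonnegative 6x6")
    if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must sum to 1")

    n = spec.n_epochs
    rng = np.random.default_rng(seed)
    if n == 0:
        return Hypnogram(np.array([], dtype=object), spec.epoch_seconds)
    cum = [list(np.cumsum(row)) for row in tm]
    u = rng.random(n)
    um = rng.random(n)
    state = STAGES.index(start_stage)
    out = []
    for t in range(n):
        out.append(MOVEMENT if um[t] < m_prob else STAGES[state])
        state = bisect_right(cum[state], u[t])
        if state >= len(STAGES):  # numerical guard on the last cumsum entry
            state = len(STAGES) - 1
    return Hypnogram(np.array(out, dtype=object), spec.epoch_seconds)


# ---------------------------------------------------------------------------
# GARCH(1,1) simulation
# ---------------------------------------------------------------------------

def simulate_garch_series(garch: GarchParams, n: int, seed
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``(y_t, sigma2_t)`` from a GARCH(1,1) process.

    ``y_t = mu + sigma_t z_t`` with i.i.d. standard-normal ``z_t`` and
    ``sigma2_t = alpha0 + alpha1*eps2_{t-1} + beta1*sigma2_{t-1}``;
    ``sigma2_1`` starts at the unconditional variance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    sigma2 = np.empty(n)
    sigma2[0] = garch.unconditional_variance
    a0, a1, b1 = garch.alpha0, garch.alpha1, garch.beta1
    for t in range(1, n):
        # eps_{t-1} = sigma_{t-1} * z_{t-1}
        sigma2[t] = a0 + (a1 * z[t - 1] ** 2 + b1) * sigma2[t - 1]
    y = garch.mu + np.sqrt(sigma2) * z
    return y, sigma2


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _default_stage_weights() -> dict:
    return {
        "delta":   {"W": 0.5, "S1": 1.0, "S2": 1.5, "S3": 3.0, "S4": 3.5, "R": 0.7},
        "swa":     {"W": 0.3, "S1": 0.8, "S2": 1.2, "S3": 3.0, "S4": 3.5, "R": 0.5},
        "theta":   {"W": 0.6, "S1": 1.6, "S2": 1.1, "S3": 0.8, "S4": 0.7, "R": 1.8},
        "alpha":   {"W": 2.2, "S1": 1.0, "S2": 0.7, "S3": 0.4, "S4": 0.3, "R": 0.8},
        "beta":    {"W": 1.5, "S1": 0.9, "S2": 0.6, "S3": 0.3, "S4": 0.3, "R": 1.0},
        "gamma":   {"W": 1.2, "S1": 0.8, "S2": 0.6, "S3": 0.4, "S4": 0.4, "R": 1.0},
        "spindle": {"W": 0.3, "S1": 0.5, "S2": 2.5, "S3": 0.8, "S4": 0.5, "R": 0.3},
    }


@dataclass
class SignalConfig:
    """All tunable knobs of the signal generator.

    Amplitudes are µV RMS of the corresponding component at stage weight 1.
    ``band_edges`` are the synthesis bands (gamma capped at 45 Hz, below the
    50 Hz Nyquist limit of 100 Hz sampling).
    """

    band_edges: dict = field(default_factory=lambda: {
        "delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
        "beta": (14.0, 30.0), "gamma": (30.0, 45.0), "swa": (0.5, 2.0),
        "spindle": (12.0, 16.0)})
    band_amplitudes: dict = field(default_factory=lambda: {
        "delta": 7.0, "theta": 5.0, "alpha": 5.0, "beta": 3.0,
        "gamma": 1.2, "swa": 5.0, "spindle": 4.0})
    stage_weights: dict = field(default_factory=_default_stage_weights)
    #: multiplicative age-group gain on delta/SWA/spindle amplitudes
    age_gains: dict = field(default_factory=lambda: {
        "delta": (1.0, 0.8, 0.6), "swa": (1.0, 0.8, 0.6),
        "spindle": (1.0, 0.8, 0.6)})
    background_uv: float = 8.0        # 1/f EEG background, amplitude-stable
    sensor_noise_uv: float = 1.0      # white noise on every channel
    cardiorespiratory_uv: float = 2.0  # 0.25 Hz contaminant (high-pass target)
    cardiorespiratory_hz: float = 0.25
    emg_band: tuple = (20.0, 49.0)
    emg_tone_uv: dict = field(default_factory=lambda: {
        "W": 10.0, "S1": 7.0, "S2": 5.0, "S3": 3.5, "S4": 3.0, "R": 1.5,
        "M": 25.0})
    eog_band: tuple = (0.3, 3.0)
    eog_base_uv: float = 15.0
    eog_stage_weights: dict = field(default_factory=lambda: {
        "W": 1.2, "S1": 0.8, "S2": 0.5, "S3": 0.3, "S4": 0.3, "R": 2.5,
        "M": 1.5})
    #: GARCH truth for the epoch-amplitude volatility process (placebo)
    garch_truth: GarchParams = field(default_factory=lambda: GarchParams(
        alpha0=0.02, alpha1=0.25, beta1=0.65, mu=1.0))
    #: the drug night multiplies alpha1 by this factor (reduced volatility)
    drug_alpha1_factor: float = 0.5
    #: lagged frontal->occipital delta coupling during stage 3
    coupling_strength: float = 1.5
    coupling_lag_seconds: float = 0.25
    coupling_stage: str = "S3"
    coupling_band: str = "delta"

    def garch_for_condition(self, condition: str) -> GarchParams:
        if condition == "drug":
            return replace(self.garch_truth,
                           alpha1=self.garch_truth.alpha1 * self.drug_alpha1_factor)
        return self.garch_truth

    def age_gain(self, band: str, group_index: int) -> float:
        gains = self.age_gains.get(band)
        if gains is None:
            return 1.0
        return gains[min(group_index, len(gains) - 1)]

    def to_dict(self) -> dict:
        d = {
            "band_edges": {k: list(v) for k, v in self.band_edges.items()},
            "band_amplitudes": dict(self.band_amplitudes),
            "stage_weights": {k: dict(v) for k, v in self.stage_weights.items()},
            "age_gains": {k: list(v) for k, v in self.age_gains.items()},
            "background_uv": self.background_uv,
            "sensor_noise_uv": self.sensor_noise_uv,
            "cardiorespiratory_uv": self.cardiorespiratory_uv,
            "cardiorespiratory_hz": self.cardiorespiratory_hz,
            "emg_band": list(self.emg_band),
            "emg_tone_uv": dict(self.emg_tone_uv),
            "eog_band": list(self.eog_band),
            "eog_base_uv": self.eog_base_uv,
            "eog_stage_weights": dict(self.eog_stage_weights),
            "garch_truth": {"alpha0": self.garch_truth.alpha0,
                            "alpha1": self.garch_truth.alpha1,
                            "beta1": self.garch_truth.beta1,
                            "mu": self.garch_truth.mu},
            "drug_alpha1_factor": self.drug_alpha1_factor,
            "coupling_strength": self.coupling_strength,
            "coupling_lag_seconds": self.coupling_lag_seconds,
            "coupling_stage": self.coupling_stage,
            "coupling_band": self.coupling_band,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SignalConfig":
        d = dict(d)
        if "garch_truth" in d:
            d["garch_truth"] = GarchParams(**d["garch_truth"])
        for key in ("band_edges", "age_gains"):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        for key in ("emg_band", "eog_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def load_signal_config(path) -> SignalConfig:
    with open(path) as fh:
        return SignalConfig.from_dict(yaml.safe_load(fh) or {})


def dump_signal_config(config: SignalConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def _band_noise_from_spectrum(spectrum: np.ndarray, freqs: np.ndarray,
                              low: float, high: float, n: int) -> np.ndarray:
    """Band-limited unit-RMS noise from a shared white spectrum.

    Disjoint bands carved from the same white spectrum are mutually
    independent (non-overlapping Fourier coefficients).
    """
    mask = (freqs >= low) & (freqs <= high)
    if not np.any(mask):
        return np.zeros(n)
    x = np.fft.irfft(np.where(mask, spectrum, 0.0), n=n)
    s = x.std()
    return x / s if s > 0 else x


def _one_over_f_noise(spectrum: np.ndarray, freqs: np.ndarray, n: int,
                      f_floor: float = 0.5) -> np.ndarray:
    shaped = spectrum / np.sqrt(np.maximum(freqs, f_floor))
    shaped[0] = 0.0
    x = np.fft.irfft(shaped, n=n)
    s = x.std()
    return x / s if s > 0 else x


def _expand_epochs(per_epoch: np.ndarray, epoch_samples: int) -> np.ndarray:
    return np.repeat(per_epoch, epoch_samples)


def generate_recording(hypnogram: Hypnogram, *, subject_id: str, age: int,
                       age_group: str, sex: str, condition: str, night: int,
                       garch: GarchParams | None = None, seed=0,
                       config: SignalConfig | None = None,
                       sample_rate: float = 100.0,
                       age_group_index: int = 0) -> Recording:
    """Synthesize one subject-night of EEG/EOG/EMG from a hypnogram.

    Per epoch, EEG is a sum of stage-weighted band-limited noise oscillators
    plus an amplitude-stable 1/f background and a slow cardiorespiratory
    sinusoid; the oscillator bundle of each channel is multiplied by a
    GARCH(1,1) epoch-amplitude process (observation series with mean level
    ``mu``, clipped below at 0.05).  EMG is 20-49 Hz noise with
    stage-dependent tone; EOG is slow activity largest during REM.  The
    occipital channel receives a lagged copy of the frontal delta component
    during the coupling stage.
    """
    if len(hypnogram) == 0:
        raise ValueError("hypnogram must be non-empty")
    config = config or SignalConfig()
    top = max(hi for _, hi in config.band_edges.values())
    if sample_rate <= 2 * top:
        raise ValueError(
            f"sample rate {sample_rate} Hz cannot represent the {top} Hz "
            "synthesis band (need sample_rate > 2 x highest component)")
    garch = garch or config.garch_for_condition(condition)

    stages_arr = np.asarray(hypnogram.stages, dtype=object)
    n_epochs = len(stages_arr)
    epoch_samples = int(round(hypnogram.epoch_seconds * sample_rate))
    n = n_epochs * epoch_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)

    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    ch_seeds = root.spawn(len(CHANNEL_NAMES) + 1)
    garch_seeds = np.random.SeedSequence(
        entropy=root.entropy, spawn_key=root.spawn_key + (1000,)).spawn(
        len(CHANNEL_NAMES))

    # EEG stage weights: movement epochs borrow the wake profile.
    def weight_for(band: str, st: str) -> float:
        return config.stage_weights[band].get(
            "W" if st == MOVEMENT else st, 0.0)

    # slow contaminant shared across EEG channels (cardiac/respiratory)
    t = np.arange(n) / sample_rate
    contaminant = (config.cardiorespiratory_uv
                   * np.sin(2 * np.pi * config.cardiorespiratory_hz * t))

    channels: dict[str, np.ndarray] = {}
    delta_component: np.ndarray | None = None
    for idx, name in enumerate((EEG_FPZ, EEG_PZ)):
        rng = np.random.default_rng(ch_seeds[idx])
        osc_spec = (rng.standard_normal(len(freqs))
                    + 1j * rng.standard_normal(len(freqs)))
        bg_spec = (rng.standard_normal(len(freqs))
                   + 1j * rng.standard_normal(len(freqs)))
        y_amp, _ = simulate_garch_series(garch, n_epochs, garch_seeds[idx])
        mult = _expand_epochs(np.maximum(y_amp, 0.05), epoch_samples)
        sig = np.zeros(n)
        for band, (lo, hi) in config.band_edges.items():
            carrier = _band_noise_from_spectrum(osc_spec, freqs, lo, hi, n)
            w = np.array([weight_for(band, st) for st in stages_arr])
            amp = (config.band_amplitudes[band]
                   * config.age_gain(band, age_group_index)
                   * _expand_epochs(w, epoch_samples))
            comp = carrier * amp * mult
            if name == EEG_FPZ and band == config.coupling_band:
                delta_component = comp
            sig += comp
        if (name == EEG_PZ and config.coupling_strength > 0
                and delta_component is not None):
            lag = int(round(config.coupling_lag_seconds * sample_rate))
            shifted = np.concatenate([np.zeros(lag),
                                      delta_component[:n - lag]])
            mask = _expand_epochs(
                (stages_arr == config.coupling_stage).astype(float),
                epoch_samples)
            sig += config.coupling_strength * shifted * mask
        # the 1/f background is neural too: it shares the epoch-amplitude
        # volatility process, so the whole epoch waveform scales with m
        sig += (config.background_uv * _one_over_f_noise(bg_spec, freqs, n)
                * mult)
        sig += contaminant
        sig += config.sensor_noise_uv * rng.standard_normal(n)
        channels[name] = sig

    # EOG: slow band noise, stage weighted (REM largest)
    rng = np.random.default_rng(ch_seeds[2])
    spec_eog = (rng.standard_normal(len(freqs))
                + 1j * rng.standard_normal(len(freqs)))
    carrier = _band_noise_from_spectrum(spec_eog, freqs,
                                        config.eog_band[0],
                                        config.eog_band[1], n)
    w = np.array([config.eog_stage_weights.get(st, 0.0) for st in stages_arr])
    y_amp, _ = simulate_garch_series(garch, n_epochs, garch_seeds[2])
    mult = _expand_epochs(np.maximum(y_amp, 0.05), epoch_samples)
    eog = (config.eog_base_uv * carrier * _expand_epochs(w, epoch_samples)
           * mult)
    eog += config.sensor_noise_uv * rng.standard_normal(n)
    channels[EOG_CH] = eog

    # EMG: broadband muscle-band noise with stage-dependent tone
    rng = np.random.default_rng(ch_seeds[3])
    spec_emg = (rng.standard_normal(len(freqs))
                + 1j * rng.standard_normal(len(freqs)))
    carrier = _band_noise_from_spectrum(spec_emg, freqs,
                                        config.emg_band[0],
                                        config.emg_band[1], n)
    tone = np.array([config.emg_tone_uv.get(st, 0.0) for st in stages_arr])
    y_amp, _ = simulate_garch_series(garch, n_epochs, garch_seeds[3])
    mult = _expand_epochs(np.maximum(y_amp, 0.05), epoch_samples)
    emg = carrier * _expand_epochs(tone, epoch_samples) * mult
    emg += config.sensor_noise_uv * rng.standard_normal(n)
    channels[EMG_CH] = emg

    return Recording(subject_id=subject_id, age=age, age_group=age_group,
                     sex=sex, condition=condition, night=night,
                     channels=channels, sample_rate=sample_rate,
                     hypnogram=hypnogram, truth=garch)


def generate_cohort(spec: CohortSpec,
                    config: SignalConfig | None = None) -> list[Recording]:
    """Generate a full two-night cohort: one drug and one placebo night each.

    Ages are sampled uniformly within each subject's age-group range; the
    drug night alternates between night 1 and night 2 across subjects.
    Identical spec and seed reproduce the cohort bit-for-bit.
    """
    config = config or SignalConfig()
    root = np.random.SeedSequence(spec.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    subj_seeds = np.random.SeedSequence(
        entropy=root.entropy, spawn_key=root.spawn_key + (7,)).spawn(
        spec.n_subjects)

    sizes = spec.group_sizes()
    group_of_subject: list[int] = []
    for gi, size in enumerate(sizes):
        group_of_subject.extend([gi] * size)

    recordings: list[Recording] = []
    for i in range(spec.n_subjects):
        gi = group_of_subject[i]
        label, lo, hi = spec.age_groups[gi]
        age = int(meta_rng.integers(lo, hi + 1))
        sex = "F" if meta_rng.random() < 15.0 / 22.0 else "M"
        drug_night = 1 if i % 2 == 0 else 2
        night_seeds = subj_seeds[i].spawn(4)
        for night in (1, 2):
            condition = "drug" if night == drug_night else "placebo"
            hyp = generate_hypnogram(spec, label, condition,
                                     night_seeds[2 * (night - 1)])
            rec = generate_recording(
                hyp, subject_id=f"S{i:03d}", age=age, age_group=label,
                sex=sex, condition=condition, night=night,
                garch=config.garch_for_condition(condition),
                seed=night_seeds[2 * (night - 1) + 1], config=config,
                sample_rate=spec.sample_rate, age_group_index=gi)
            recordings.append(rec)
    return recordings
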