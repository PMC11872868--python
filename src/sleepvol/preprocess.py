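"""Signal conditioning for multimodal sleep recordings.

Implements the conditioning chain applied to every recording before
tensorization and feature extraction: equiripple (Parks-McClellan) FIR
band-pass filtering, Welch power spectral density and band powers,
rectified/smoothed EMG and EOG envelopes, sliding-window RMS, high-pass
removal of slow physiological contamination (heartbeat/respiration), and
automated ICA-based ocular-artifact removal.

All filters are applied with exact zero phase: the symmetric (linear-phase)
FIR is applied once by FFT convolution on a reflection-padded signal and
the group delay is compensated by alignment, so a band-interior sinusoid
suffers no phase shift and the passband ripple is the as-designed ripple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .bands import BandDefinition

__all__ = [
    "PsdEstimate",
    "IcaCleanReport",
    "design_bandpass_fir",
    "design_lowpass_fir",
    "design_highpass_fir",
    "zero_phase_filter",
    "bandpass",
    "welch_psd",
    "band_power",
    "psd_to_csv",
    "rest_rereference",
    "loglog_spectrum",
    "highpass_physio",
    "emg_envelope",
    "eog_condition",
    "rms",
    "remove_ocular_artifacts",
]

#: EMG analysis band.  The physiologically conventional 20-50 Hz range
#: collides with the 50 Hz Nyquist limit at 100 Hz sampling, so the upper
#: edge is set to 49 Hz.
EMG_BAND = BandDefinition("emg", 20.0, 49.0)
EOG_BAND = BandDefinition("eog", 0.1, 15.0)

_MAX_TAPS = 8191


class FilterDesignError(ValueError):
    """Raised when no FIR of admissible order meets the requested spec."""


@dataclass
class PsdEstimate:
    """One-sided Welch power spectral density estimate.

    ``power`` is a density in (signal units)^2 per Hz on the ``frequencies``
    grid; ``resolution`` is the actual grid spacing.
    """

    frequencies: np.ndarray
    power: np.ndarray
    window_seconds: float
    resolution: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency and power grids differ in length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power density must be non-negative")


def _ripple_deltas(ripple_db: float, atten_db: float) -> tuple[float, float]:
    delta_pass = 10.0 ** (ripple_db / 20.0) - 1.0
    delta_stop = 10.0 ** (-atten_db / 20.0)
    return delta_pass, delta_stop


def _estimate_taps(delta_pass: float, delta_stop: float,
                   transition_hz: float, fs: float) -> int:
    # Bellanger's order estimate for equiripple FIR designs.
    n = int(np.ceil((2.0 / 3.0)
                    * np.log10(1.0 / (10.0 * delta_pass * delta_stop))
                    * fs / transition_hz))
    return max(n | 1, 11)  # odd (type-I symmetric), sensible floor


def _design_kaiser(bands_hz: list[float], desired: list[float], fs: float,
                   delta_stop: float, transition_hz: float
                   ) -> np.ndarray | None:
    """Kaiser-window fallback for specs where remez will not converge
    (very narrow relative transitions, e.g. a 0.1 Hz band edge)."""
    atten = -20.0 * np.log10(delta_stop)
    cutoffs = [0.5 * (bands_hz[2 * i + 1] + bands_hz[2 * i + 2])
               for i in range(len(desired) - 1)]
    numtaps, beta = sps.kaiserord(atten + 3.0, transition_hz / (fs / 2.0))
    numtaps |= 1
    while numtaps <= _MAX_TAPS:
        taps = sps.firwin(numtaps, cutoffs, window=("kaiser", beta),
                          pass_zero=(desired[0] == 1.0), fs=fs)
        if _meets_spec(taps, bands_hz, desired, fs,
                       max(delta_stop, 1e-4), delta_stop):
            return taps
        numtaps = (numtaps * 5 // 4) | 1
    return None


def _design_remez(bands_hz: list[float], desired: list[float],
                  weights: list[float], fs: float,
                  delta_pass: float, delta_stop: float,
                  transition_hz: float) -> np.ndarray:
    """Iteratively increase the order until the measured response meets spec."""
    numtaps = _estimate_taps(delta_pass, delta_stop, transition_hz, fs)
    last_err = None
    while numtaps <= _MAX_TAPS:
        try:
            taps = sps.remez(numtaps, bands_hz, desired, weight=weights, fs=fs)
        except Exception as exc:  # remez can fail to converge at low orders
            last_err = exc
            numtaps = (numtaps * 5 // 4) | 1
            continue
        if _meets_spec(taps, bands_hz, desired, fs, delta_pass, delta_stop):
            return taps
        last_err = None
        numtaps = (numtaps * 5 // 4) | 1
    taps = _design_kaiser(bands_hz, desired, fs, delta_stop, transition_hz)
    if taps is not None:
        return taps
    raise FilterDesignError(
        "no FIR with <= %d taps meets ripple/attenuation spec "
        "(passband deviation %.4g, stopband deviation %.4g, transition %.3g Hz)%s"
        % (_MAX_TAPS, delta_pass, delta_stop, transition_hz,
           f"; last design error: {last_err}" if last_err else ""))


def _meets_spec(taps: np.ndarray, bands_hz: list[float], desired: list[float],
                fs: float, delta_pass: float, delta_stop: float) -> bool:
    w, h = sps.freqz(taps, worN=8192, fs=fs)
    mag = np.abs(h)
    for i in range(len(desired)):
        lo, hi = bands_hz[2 * i], bands_hz[2 * i + 1]
        sel = (w >= lo) & (w <= hi)
        if not np.any(sel):
            continue
        if desired[i] == 1.0:
            if np.any(np.abs(mag[sel] - 1.0) > delta_pass * 1.05):
                return False
        else:
            if np.any(mag[sel] > delta_stop * 1.05):
                return False
    return True


def _transition(edge_hz: float) -> float:
    """Default transition width: 0.5 Hz or 10% of the edge, whichever larger."""
    return max(0.5, 0.1 * edge_hz)


def design_bandpass_fir(low: float, high: float, sample_rate: float,
                        ripple_db: float = 1.0,
                        atten_db: float = 40.0) -> np.ndarray:
    """Design a linear-phase equiripple band-pass FIR.

    Transition bands default to 0.5 Hz or 10% of the adjacent band edge,
    whichever is larger; when the lower transition would reach below 0 Hz
    it is narrowed to ``[low/2, low]``.  Raises :class:`FilterDesignError`
    if no filter of admissible order meets the spec.
    """
    nyq = sample_rate / 2.0
    BandDefinition("design", low, high).validate_for_rate(sample_rate)
    dp, ds = _ripple_deltas(ripple_db, atten_db)
    t_lo = _transition(low)
    t_hi = _transition(high)
    stop_lo = low - t_lo
    if stop_lo <= 0:
        stop_lo = low / 2.0
        t_lo = low - stop_lo
    stop_hi = min(high + t_hi, nyq - 1e-9)
    trans_min = min(t_lo, stop_hi - high) if stop_hi > high else t_lo
    if stop_hi <= high:  # passband touches Nyquist: design as high-pass-like
        bands = [0.0, stop_lo, low, nyq]
        desired = [0.0, 1.0]
        weights = [1.0 / ds, 1.0 / dp]
        trans_min = t_lo
    else:
        bands = [0.0, stop_lo, low, high, stop_hi, nyq]
        desired = [0.0, 1.0, 0.0]
        weights = [1.0 / ds, 1.0 / dp, 1.0 / ds]
    return _design_remez(bands, desired, weights, sample_rate, dp, ds,
                         trans_min)


def design_lowpass_fir(cutoff: float, sample_rate: float,
                       ripple_db: float = 1.0,
                       atten_db: float = 40.0) -> np.ndarray:
    nyq = sample_rate / 2.0
    dp, ds = _ripple_deltas(ripple_db, atten_db)
    t = _transition(cutoff)
    stop = min(cutoff + t, nyq - 1e-9)
    if stop <= cutoff:
        raise FilterDesignError("low-pass cutoff too close to Nyquist")
    bands = [0.0, cutoff, stop, nyq]
    return _design_remez(bands, [1.0, 0.0], [1.0 / dp, 1.0 / ds],
                         sample_rate, dp, ds, stop - cutoff)


def design_highpass_fir(cutoff: float, sample_rate: float,
                        ripple_db: float = 1.0,
                        atten_db: float = 40.0) -> np.ndarray:
    nyq = sample_rate / 2.0
    dp, ds = _ripple_deltas(ripple_db, atten_db)
    t = _transition(cutoff)
    stop = cutoff - t
    if stop <= 0:
        stop = cutoff / 2.0
    bands = [0.0, stop, cutoff, nyq]
    return _design_remez(bands, [0.0, 1.0], [1.0 / ds, 1.0 / dp],
                         sample_rate, dp, ds, cutoff - stop)


def zero_phase_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR with exact zero phase and preserved length.

    The signal is reflection-padded by the filter half-length, convolved
    once (FFT convolution), and re-aligned to compensate the group delay.
    Requires the signal to be longer than three filter lengths.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    m = len(taps)
    if n <= 3 * m:
        raise ValueError(
            f"signal length {n} must exceed 3x filter length ({3 * m})")
    half = (m - 1) // 2
    pad = m  # generous reflection padding
    xp = np.concatenate([x[..., 1:pad + 1][..., ::-1], x,
                         x[..., -pad - 1:-1][..., ::-1]], axis=-1)
    t = np.asarray(taps, dtype=float).reshape((1,) * (x.ndim - 1) + (-1,))
    y = sps.fftconvolve(xp, t, mode="full", axes=-1)
    start = pad + half
    return y[..., start:start + n]


def bandpass(x: np.ndarray, band: BandDefinition, sample_rate: float,
             ripple_db: float = 1.0, atten_db: float = 40.0) -> np.ndarray:
    """Zero-phase band-pass filtering of ``x`` to ``band``."""
    band.validate_for_rate(sample_rate)
    taps = design_bandpass_fir(band.low, band.high, sample_rate,
                               ripple_db, atten_db)
    return zero_phase_filter(x, taps)


def highpass_physio(x: np.ndarray, sample_rate: float,
                    cutoff: float = 1.0) -> np.ndarray:
    """Remove slow physiological contamination (heartbeat, respiration).

    Zero-phase high-pass with a default 1.0 Hz cutoff.
    """
    taps = design_highpass_fir(cutoff, sample_rate)
    return zero_phase_filter(x, taps)


def welch_psd(x: np.ndarray, sample_rate: float,
              window_seconds: float = 11.0,
              overlap_fraction: float = 0.5,
              taper: str = "hamming") -> PsdEstimate:
    """Welch PSD with Hamming-tapered, 50%-overlapping segments.

    Density normalization: the trapezoidal integral of the returned density
    over frequency approximates the signal variance (plus DC power; the
    signal is not detrended, so a constant input shows up in the 0 Hz bin).
    The true frequency resolution is the grid spacing ``1/window_seconds``
    and is reported as ``resolution``.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_seconds * sample_rate))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal ({x.shape[-1]} samples) shorter than one "
            f"{window_seconds} s window ({nperseg} samples)")
    freqs, power = sps.welch(x, fs=sample_rate, window=taper,
                             nperseg=nperseg,
                             noverlap=int(round(overlap_fraction * nperseg)),
                             detrend=False, scaling="density")
    return PsdEstimate(freqs, power, window_seconds,
                       float(freqs[1] - freqs[0]))


def band_power(psd: PsdEstimate, band: BandDefinition) -> float:
    """Trapezoidal integral of the PSD over ``[band.low, band.high]`` (µV²).

    Band edges are linearly interpolated on the frequency grid, so powers
    of adjacent bands add exactly to the power of their union.
    """
    f, p = psd.frequencies, psd.power
    if band.low < f[0] - 1e-12 or band.high > f[-1] + 1e-12:
        raise ValueError(
            f"band {band.name} [{band.low}, {band.high}] Hz outside PSD "
            f"grid [{f[0]}, {f[-1]}] Hz")
    lo = max(band.low, f[0])
    hi = min(band.high, f[-1])
    inner = (f > lo) & (f < hi)
    grid = np.concatenate([[lo], f[inner], [hi]])
    vals = np.concatenate([[np.interp(lo, f, p)], p[inner],
                           [np.interp(hi, f, p)]])
    return float(np.trapezoid(vals, grid))


def rms(x: np.ndarray, sample_rate: float, window_ms: float = 100.0
        ) -> np.ndarray:
    """Sliding-window RMS with one-sample hop and length-preserving output.

    Edges are reflection-padded so the output has the input's length.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(window_ms / 1000.0 * sample_rate))
    if w < 2:
        raise ValueError(f"window of {window_ms} ms is under 2 samples")
    left = (w - 1) // 2
    right = w - 1 - left
    xp = np.pad(x, (left, right), mode="reflect")
    c = np.cumsum(np.concatenate([[0.0], xp * xp]))
    return np.sqrt(np.maximum((c[w:] - c[:-w]) / w, 0.0))


def _rectified_envelope(x: np.ndarray, sample_rate: float,
                        smooth_cutoff: float) -> np.ndarray:
    # Full-wave rectification, low-pass smoothing, then a pi/2 gain so the
    # envelope of a pure sinusoid equals its amplitude (the rectified-sine
    # mean is 2A/pi).  The smoother is normalized to unit DC gain so the
    # plateau level is exact rather than riding the equiripple deviation.
    taps = design_lowpass_fir(smooth_cutoff, sample_rate)
    taps = taps / taps.sum()
    env = zero_phase_filter(np.abs(np.asarray(x, dtype=float)), taps)
    return env * (np.pi / 2.0)


def emg_envelope(x: np.ndarray, sample_rate: float,
                 smooth_cutoff: float = 7.5) -> np.ndarray:
    """Linear EMG envelope: rectify, then 7.5 Hz low-pass smoothing.

    Expects an EMG signal already band-passed to the muscle-activity band
    (20-49 Hz).  Output is length-preserving and non-negative up to filter
    ringing.
    """
    return _rectified_envelope(x, sample_rate, smooth_cutoff)


def eog_condition(x: np.ndarray, sample_rate: float,
                  smooth_cutoff: float = 5.0) -> np.ndarray:
    """EOG conditioning: 0.1-15 Hz band-pass, rectify, 5 Hz low-pass."""
    filtered = bandpass(x, EOG_BAND, sample_rate)
    return _rectified_envelope(filtered, sample_rate, smooth_cutoff)


def rest_rereference(eeg: np.ndarray, sample_rate: float) -> np.ndarray:
    """Reference-standardization pass-through stub.

    A meaningful reference-electrode standardization needs a dense montage
    and a head model; with two referential telemetry channels it cannot be
    computed, so the input is returned unchanged with a warning.
    """
    warnings.warn("reference standardization is a pass-through with "
                  "two-channel telemetry EEG; returning input unchanged",
                  stacklevel=2)
    return np.asarray(eeg, dtype=float)


def loglog_spectrum(psd: PsdEstimate) -> tuple[np.ndarray, np.ndarray]:
    """Diagnostic log-power vs log-frequency export (DC bin dropped)."""
    keep = (psd.frequencies > 0) & (psd.power > 0)
    return np.log10(psd.frequencies[keep]), np.log10(psd.power[keep])


def psd_to_csv(psd: PsdEstimate, path) -> None:
    """Export a PSD estimate as a two-column (frequency, power) CSV."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frequency_hz", "power_uv2_per_hz"])
        for f, p in zip(psd.frequencies, psd.power):
            w.writerow([f"{f:.10g}", f"{p:.10g}"])


@dataclass
class IcaCleanReport:
    """Outcome of ICA-based ocular artifact removal."""

    status: str  # "ok", "no-eog", "not-converged"
    removed_components: list[int] = field(default_factory=list)
    correlations: list[float] = field(default_factory=list)
    n_components: int = 0


def remove_ocular_artifacts(eeg: np.ndarray, eog: np.ndarray,
                            sample_rate: float,
                            threshold: float = 0.7,
                            seed: int = 0
                            ) -> tuple[np.ndarray, IcaCleanReport]:
    """Remove EOG-correlated independent components from EEG channels.

    Spatial FastICA is run on the 1-45 Hz band-passed observation matrix
    (EEG channels stacked with the EOG reference).  Components whose
    absolute Pearson correlation with the filtered EOG exceeds
    ``threshold`` are treated as ocular artifacts; their contribution is
    subtracted from the original EEG.  If ICA does not converge the input
    is returned unchanged with a ``not-converged`` status.

    Parameters
    ----------
    eeg : array, shape (n_channels, n_samples)
    eog : array, shape (n_samples,)
    """
    from sklearn.decomposition import FastICA

    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    eog = np.asarray(eog, dtype=float)
    if eeg.shape[1] != eog.shape[0]:
        raise ValueError("EEG and EOG lengths differ")

    ica_band = BandDefinition("ica", 1.0, min(45.0, sample_rate / 2 - 1.0))
    if float(np.std(eog)) < 1e-12:
        return eeg.copy(), IcaCleanReport(status="no-eog")

    obs = np.vstack([eeg, eog[None, :]])
    taps = design_bandpass_fir(ica_band.low, ica_band.high, sample_rate)
    obs_f = np.vstack([zero_phase_filter(row, taps) for row in obs])
    eog_f = obs_f[-1]

    cov = np.cov(obs_f)
    evals = np.linalg.eigvalsh(cov)
    rank = int(np.sum(evals > 1e-10 * evals.max()))
    n_comp = max(min(rank, obs.shape[0]), 1)

    ica = FastICA(n_components=n_comp, random_state=seed, max_iter=1000,
                  whiten="unit-variance")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(obs_f.T)  # (n_samples, n_comp)
    if any("did not converge" in str(w.message) for w in caught):
        return eeg.copy(), IcaCleanReport(status="not-converged",
                                          n_components=n_comp)

    sd = sources.std(axis=0)
    sd[sd == 0] = 1.0
    corr = ((sources - sources.mean(0)) / sd).T @ (
        (eog_f - eog_f.mean()) / eog_f.std()) / len(eog_f)
    removed = [i for i, c in enumerate(corr) if abs(c) > threshold]

    cleaned = eeg.copy()
    if removed:
        # mixing_ rows follow the observation order: EEG channels first.
        artifact = sources[:, removed] @ ica.mixing_[:eeg.shape[0], removed].T
        cleaned = eeg - artifact.T
    return cleaned, IcaCleanReport(status="ok", removed_components=removed,
                                   correlations=[float(c) for c in corr],
                                   n_components=n_comp)
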