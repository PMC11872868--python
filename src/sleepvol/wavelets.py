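"""Morlet continuous wavelet transform and importance-weighted features.

The mother wavelet is the (analytic) Morlet wavelet

.. math:: \\varphi(t) = \\pi^{-1/4} e^{i\\omega_0 t} e^{-t^2/2}

with center frequency :math:`\\omega_0` (default 6, the standard choice
respecting admissibility).  The CWT of a signal :math:`x` at scale
:math:`a` and translation :math:`b` is

.. math:: W(a, b) = a^{-1/2} \\int x(t)\\, \\varphi^*((t-b)/a)\\, dt,

evaluated by FFT convolution on the sample grid.  A scale ``a`` (in
seconds) corresponds to the analysis frequency
:math:`f = \\omega_0 / (2\\pi a)` Hz.

From the scalogram, three per-window features are computed with an
importance weight :math:`b_i \\in [0, 1]` per coefficient:

* energy      :math:`E = \\sum_i |W_i|^2 b_i`
* mean        :math:`\\tfrac1N \\sum_i W_i b_i` (magnitudes by default)
* entropy     :math:`-\\sum_i p_i \\log(p_i b_i)` with
  :math:`p_i = |W_i|^2 / \\sum_j |W_j|^2`

and the Shannon entropy of each feature's distribution across windows
(quantile-binned) yields the SEEN/SEM/SEE summary values used to rank
features.  Terms with :math:`b_i = 0` or :math:`p_i = 0` are excluded from
entropy sums (the logarithm is undefined there); with all :math:`b_i = 1`
the entropy is the Shannon entropy of the normalized scalogram in nats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .bands import BandDefinition

__all__ = [
    "CwtResult",
    "WaveletFeatureSet",
    "morlet_cwt",
    "scales_for_band",
    "scale_to_frequency",
    "frequency_to_scale",
    "wavelet_energy",
    "wavelet_mean",
    "wavelet_entropy",
    "shannon_entropy",
    "epochwise_features",
    "compute_feature_set",
]

log = logging.getLogger(__name__)

DEFAULT_OMEGA0 = 6.0


@dataclass
class CwtResult:
    """Complex CWT coefficients over a scale x translation grid."""

    coefficients: np.ndarray  # (n_scales, n_times), complex
    scales: np.ndarray        # seconds, strictly positive, sorted
    omega0: float
    times: np.ndarray         # translation grid in seconds

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(self.scales <= 0):
            raise ValueError("scales must be strictly positive")
        if self.coefficients.shape != (len(self.scales), len(self.times)):
            raise ValueError("coefficient matrix does not match grids")

    @property
    def frequencies(self) -> np.ndarray:
        return scale_to_frequency(self.scales, self.omega0)

    @property
    def scalogram(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2


def scale_to_frequency(scales, omega0: float = DEFAULT_OMEGA0) -> np.ndarray:
    """Analysis frequency in Hz for scales in seconds."""
    return omega0 / (2.0 * np.pi * np.asarray(scales, dtype=float))


def frequency_to_scale(freqs, omega0: float = DEFAULT_OMEGA0) -> np.ndarray:
    return omega0 / (2.0 * np.pi * np.asarray(freqs, dtype=float))


def _morlet_kernel(scale: float, omega0: float, sample_rate: float,
                   n_sigma: float = 5.0) -> np.ndarray:
    """phi(t/a) sampled on the signal grid, truncated at ``n_sigma`` widths.

    Convolving x with this kernel equals correlation with phi* because the
    Morlet wavelet is Hermitian: phi(-t) = phi*(t).
    """
    half = max(int(np.ceil(n_sigma * scale * sample_rate)), 1)
    t = np.arange(-half, half + 1) / sample_rate / scale
    return np.pi ** -0.25 * np.exp(1j * omega0 * t) * np.exp(-0.5 * t * t)


def morlet_cwt(signal, scales, omega0: float = DEFAULT_OMEGA0,
               sample_rate: float = 100.0) -> CwtResult:
    """Continuous Morlet wavelet transform, linear in the input."""
    x = np.asarray(signal, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if scales.size == 0:
        raise ValueError("scales must be non-empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    dt = 1.0 / sample_rate
    coeffs = np.empty((len(scales), len(x)), dtype=complex)
    for i, a in enumerate(scales):
        kernel = _morlet_kernel(a, omega0, sample_rate)
        coeffs[i] = fftconvolve(x, kernel, mode="same") * dt / np.sqrt(a)
    times = np.arange(len(x)) * dt
    return CwtResult(coeffs, scales, omega0, times)


def scales_for_band(band: BandDefinition, n_bins: int,
                    omega0: float = DEFAULT_OMEGA0,
                    sample_rate: float = 100.0) -> np.ndarray:
    """``n_bins`` scales whose analysis frequencies log-span [low, high].

    Scales are returned in increasing-frequency order (hence decreasing
    scale).  With ``n_bins = 1`` the single scale sits at the band's
    geometric center frequency.
    """
    band.validate_for_rate(sample_rate)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins == 1:
        freqs = np.array([np.sqrt(band.low * band.high)])
    else:
        freqs = np.geomspace(band.low, band.high, n_bins)
    return frequency_to_scale(freqs, omega0)


def _flat_weights(coeffs, weights) -> tuple[np.ndarray, np.ndarray]:
    w_flat = np.asarray(coeffs).ravel()
    if weights is None:
        b = np.ones(w_flat.size)
    else:
        b = np.asarray(weights, dtype=float).ravel()
        if b.size != w_flat.size:
            raise ValueError(
                f"weights length {b.size} != coefficient count {w_flat.size}")
        if np.any((b < 0) | (b > 1)):
            raise ValueError("weights must lie in [0, 1]")
    return w_flat, b


def wavelet_energy(coeffs, weights=None) -> float:
    """Importance-weighted scalogram energy ``sum |W_i|^2 b_i``."""
    w, b = _flat_weights(coeffs, weights)
    return float(np.sum(np.abs(w) ** 2 * b))


def wavelet_mean(coeffs, weights=None, magnitude: bool = True):
    """Importance-weighted mean ``(1/N) sum W_i b_i``.

    Magnitudes are used by default (the reported feature); set
    ``magnitude=False`` for the complex mean.
    """
    w, b = _flat_weights(coeffs, weights)
    if w.size == 0:
        raise ValueError("empty coefficient set")
    vals = np.abs(w) if magnitude else w
    out = np.sum(vals * b) / w.size
    return float(out) if magnitude else complex(out)


def wavelet_entropy(coeffs, weights=None) -> float:
    """Importance-weighted scalogram entropy ``-sum p_i log(p_i b_i)``.

    ``p_i = |W_i|^2 / sum |W_j|^2``; terms with ``b_i = 0`` or ``p_i = 0``
    are excluded (natural log).  With all ``b_i = 1`` this is the Shannon
    entropy of the normalized scalogram.
    """
    w, b = _flat_weights(coeffs, weights)
    power = np.abs(w) ** 2
    total = power.sum()
    if total <= 0:
        raise ValueError("all-zero coefficients: entropy undefined")
    p = power / total
    keep = (p > 0) & (b > 0)
    return float(-np.sum(p[keep] * np.log(p[keep] * b[keep])))


def _quantile_bin(values: np.ndarray, bins: int) -> tuple[np.ndarray, int]:
    """Quantile-bin values; returns (bin index per value, number of bins)."""
    edges = np.unique(np.quantile(values, np.linspace(0, 1, bins + 1)))
    if len(edges) < 2:
        return np.zeros(len(values), dtype=int), 1
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1,
                  0, len(edges) - 2)
    return idx, len(edges) - 1


def shannon_entropy(values, weights=None, base: float = np.e,
                    bins: int = 10) -> float:
    """Shannon entropy of quantile-binned values with per-bin importance.

    ``H = -sum P(x_i) log_base(P(x_i) b_i)`` over occupied bins; terms with
    ``b_i = 0`` are excluded as in :func:`wavelet_entropy`.  Inputs with
    fewer than two distinct values are degenerate and return 0 (logged).
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0 or np.unique(vals).size < 2:
        log.debug("shannon_entropy: degenerate input (<2 distinct values)")
        return 0.0
    idx, n_bins = _quantile_bin(vals, bins)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    p = counts / counts.sum()
    if weights is None:
        b = np.ones(n_bins)
    else:
        b = np.asarray(weights, dtype=float).ravel()
        if b.size != n_bins:
            raise ValueError(
                f"need one weight per bin ({n_bins}), got {b.size}")
    keep = (p > 0) & (b > 0)
    return float(-np.sum(p[keep] * np.log(p[keep] * b[keep]))
                 / np.log(base))


def epochwise_features(epochs: np.ndarray, scales, omega0: float,
                       sample_rate: float) -> dict:
    """Energy, mean and entropy per row of an (n_epochs, n_samples) matrix.

    Batched over epochs with one FFT pass per scale; numerically equal to
    running :func:`morlet_cwt` per epoch and reducing, but much faster for
    per-epoch feature series over a whole night.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n_ep, n_s = epochs.shape
    scales = np.asarray(scales, dtype=float)
    dt = 1.0 / sample_rate
    sum_pow = np.zeros(n_ep)
    sum_pow_log = np.zeros(n_ep)
    sum_mag = np.zeros(n_ep)
    n_coeff = len(scales) * n_s
    for a in scales:
        kernel = _morlet_kernel(a, omega0, sample_rate)
        w = fftconvolve(epochs, kernel[None, :], mode="same", axes=1)
        w *= dt / np.sqrt(a)
        power = np.abs(w) ** 2
        sum_pow += power.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pl = power * np.log(power)
        sum_pow_log += np.where(power > 0, pl, 0.0).sum(axis=1)
        sum_mag += np.abs(w).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = np.where(sum_pow > 0,
                           np.log(sum_pow) - sum_pow_log / sum_pow, 0.0)
    return {"energy": sum_pow, "mean": sum_mag / n_coeff, "entropy": entropy}


@dataclass
class WaveletFeatureSet:
    """Per-window wavelet features plus across-window Shannon summaries.

    ``features``: one row per (window, channel, band) with energy, mean,
    entropy.  ``summaries``: per (channel, band) Shannon entropies of the
    three feature distributions across windows (SEEN, SEM, SEE).
    ``ranking``: summary cells ordered by descending Shannon entropy.
    """

    features: pd.DataFrame
    summaries: pd.DataFrame
    ranking: pd.DataFrame


def compute_feature_set(windows, recordings, bands,
                        weights: dict | None = None,
                        omega0: float = DEFAULT_OMEGA0,
                        n_scales: int = 16,
                        entropy_bins: int = 10) -> WaveletFeatureSet:
    """Wavelet features for every stage-bout window of a recording set.

    Parameters
    ----------
    windows : list of StageBoutWindow
    recordings : mapping subject_id+condition -> Recording, or list
    bands : iterable of BandDefinition
    weights : optional mapping band name -> flat importance vector applied
        to the window scalogram (binary rows of the selection matrix B by
        default upstream; all-ones when omitted).
    """
    from .synthgen import Recording  # local import to avoid cycle
    from .tensorize import slice_window

    if len(windows) == 0:
        raise ValueError("no windows supplied")
    if isinstance(recordings, Recording):
        recordings = [recordings]
    rec_by_key = {(r.subject_id, r.condition): r for r in recordings}

    rows = []
    for win in windows:
        rec = rec_by_key.get((win.subject_id, win.condition))
        if rec is None:
            raise KeyError(
                f"no recording for {(win.subject_id, win.condition)}")
        sliced = slice_window(rec, win)
        for ch_name, seg in sliced.items():
            modality = ch_name.split(" ")[0]
            for band in bands:
                scales = scales_for_band(band, n_scales, omega0,
                                         rec.sample_rate)
                res = morlet_cwt(seg, scales, omega0, rec.sample_rate)
                b = None if weights is None else weights.get(band.name)
                rows.append({
                    "subject_id": win.subject_id,
                    "condition": win.condition,
                    "age_group": rec.age_group,
                    "stage": win.stage,
                    "start_epoch": win.start_epoch,
                    "channel": ch_name,
                    "modality": modality,
                    "band": band.name,
                    "energy": wavelet_energy(res.coefficients, b),
                    "mean": wavelet_mean(res.coefficients, b),
                    "entropy": wavelet_entropy(res.coefficients, b),
                })
    features = pd.DataFrame(rows)

    summary_rows = []
    for (channel, band), grp in features.groupby(["channel", "band"],
                                                 sort=True):
        summary_rows.append({
            "channel": channel,
            "modality": channel.split(" ")[0],
            "band": band,
            "SEEN": shannon_entropy(grp["entropy"].to_numpy(),
                                    bins=entropy_bins),
            "SEM": shannon_entropy(grp["mean"].to_numpy(),
                                   bins=entropy_bins),
            "SEE": shannon_entropy(grp["energy"].to_numpy(),
                                   bins=entropy_bins),
            "n_windows": len(grp),
        })
    summaries = pd.DataFrame(summary_rows)

    melted = summaries.melt(id_vars=["channel", "modality", "band"],
                            value_vars=["SEEN", "SEM", "SEE"],
                            var_name="feature", value_name="shannon_entropy")
    ranking = melted.sort_values("shannon_entropy", ascending=False,
                                 kind="stable").reset_index(drop=True)
    return WaveletFeatureSet(features=features, summaries=summaries,
                             ranking=ranking)
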