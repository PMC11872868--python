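"""High-level drivers: per-epoch feature series, cohort MCV, cohort causality.

These functions chain the modules into the analysis a user actually runs:
wavelet-entropy series per epoch -> GARCH(1,1) per recording -> mean
conditional volatility per (age group, condition, stage); and band-limited
envelope windows -> transfer entropy -> causality index per direction.

The default GARCH input feature is the log wavelet energy per epoch,
centered within stage.  Energy is the only one of the wavelet features
that carries amplitude volatility: wavelet entropy is invariant to the
overall scale of the scalogram by construction, so epoch-amplitude
fluctuations cannot reach it, and the raw energy's heavy tails destabilize
variance estimation.  On the log scale the multiplicative amplitude
process becomes additive, and stage-centering removes the deterministic
stage-level differences so the conditional variance reflects within-stage
neural fluctuation rather than sleep architecture.  Entropy, mean, and raw
energy remain selectable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bands import BAND_BY_NAME, BandDefinition
from .causality import causality_index, window_envelope_pairs
from .synthgen import MOVEMENT, Recording
from .tensorize import find_stage_bouts
from .volatility import Garch11, GarchFit, mean_conditional_volatility
from .wavelets import DEFAULT_OMEGA0, epochwise_features, scales_for_band

__all__ = [
    "epoch_feature_series",
    "fit_recording_volatility",
    "mcv_table",
    "drug_effect_by_group",
    "cohort_causality",
]

DEFAULT_CHANNEL = "EEG Fpz-Cz"


def epoch_feature_series(recording: Recording, band: BandDefinition,
                         channel: str = DEFAULT_CHANNEL,
                         feature: str = "log_energy",
                         omega0: float = DEFAULT_OMEGA0,
                         n_scales: int = 10) -> np.ndarray:
    """Per-epoch wavelet feature series for one channel and band.

    ``feature`` is one of ``log_energy`` (default), ``energy``, ``mean``,
    ``entropy``.
    """
    x = np.asarray(recording.channels[channel], dtype=float)
    ep = recording.epoch_samples
    n_epochs = len(x) // ep
    scales = scales_for_band(band, n_scales, omega0, recording.sample_rate)
    feats = epochwise_features(x[:n_epochs * ep].reshape(n_epochs, ep),
                               scales, omega0, recording.sample_rate)
    if feature == "log_energy":
        return np.log(np.maximum(feats["energy"], 1e-300))
    if feature not in feats:
        raise KeyError(f"unknown feature {feature!r}")
    return feats[feature]


def fit_recording_volatility(recording: Recording, band: BandDefinition,
                             channel: str = DEFAULT_CHANNEL,
                             feature: str = "log_energy",
                             stage_centered: bool = True) -> GarchFit:
    """GARCH(1,1) fit to the recording's per-epoch feature series.

    With ``stage_centered=True`` (default) the series is centered within
    each stage before fitting, removing deterministic stage-level feature
    differences so that sleep architecture does not masquerade as
    volatility.
    """
    series = epoch_feature_series(recording, band, channel, feature)
    if stage_centered:
        stages = np.asarray(recording.hypnogram.stages,
                            dtype=object)[:len(series)]
        series = series.copy()
        for st in set(stages):
            sel = stages == st
            series[sel] -= series[sel].mean()
    return Garch11().fit(series).to_result()


def mcv_table(recordings, band: BandDefinition,
              channel: str = DEFAULT_CHANNEL, feature: str = "log_energy",
              by_stage: bool = False) -> pd.DataFrame:
    """Mean conditional volatility per age group and condition.

    With ``by_stage=True`` the conditional variances are additionally split
    by the stage of their epoch (movement epochs excluded).
    """
    fits_by_group: dict = {}
    for rec in recordings:
        fit = fit_recording_volatility(rec, band, channel, feature)
        stages = np.asarray(rec.hypnogram.stages, dtype=object)
        sigma2 = fit.conditional_variances
        n = min(len(stages), len(sigma2))
        stages, sigma2 = stages[:n], sigma2[:n]
        if by_stage:
            for stage in sorted(set(stages) - {MOVEMENT}):
                key = (("age_group", rec.age_group),
                       ("condition", rec.condition), ("stage", stage))
                sub = sigma2[stages == stage]
                if len(sub):
                    fits_by_group.setdefault(key, []).append(
                        _masked_fit(fit, sub))
        else:
            key = (("age_group", rec.age_group),
                   ("condition", rec.condition))
            keep = stages != MOVEMENT
            fits_by_group.setdefault(key, []).append(
                _masked_fit(fit, sigma2[keep]))
    summaries = mean_conditional_volatility(fits_by_group)
    from .volatility import volatility_table
    return volatility_table(summaries)


def _masked_fit(fit: GarchFit, sigma2: np.ndarray) -> GarchFit:
    """A copy of ``fit`` restricted to a subset of its variance samples."""
    return GarchFit(mu=fit.mu, alpha0=fit.alpha0, alpha1=fit.alpha1,
                    beta1=fit.beta1, log_likelihood=fit.log_likelihood,
                    conditional_variances=sigma2, converged=fit.converged,
                    n_obs=len(sigma2))


def drug_effect_by_group(recordings, band: BandDefinition | None = None,
                         channel: str = DEFAULT_CHANNEL,
                         feature: str = "log_energy") -> pd.DataFrame:
    """Placebo vs drug MCV per age group (the qualitative drug contrast)."""
    band = band or BAND_BY_NAME["delta"]
    table = mcv_table(recordings, band, channel, feature)
    wide = table.pivot(index="age_group", columns="condition",
                       values="mean_volatility")
    wide["drug_lower"] = wide["drug"] < wide["placebo"]
    return wide.reset_index()


def cohort_causality(recordings, band: BandDefinition | None = None,
                     stage: str = "S3", bins: int = 4, lag: int = 1,
                     env_rate: float = 4.0) -> tuple[float, float]:
    """Pooled forward and reverse causality indices for one band and stage.

    Windows are the stage-bout windows of every recording; the forward
    direction is frontal to occipital.
    """
    band = band or BAND_BY_NAME["delta"]
    windows = []
    for rec in recordings:
        windows.extend(find_stage_bouts(rec.hypnogram, rec.subject_id,
                                        rec.condition, rec.sample_rate))
    pairs = window_envelope_pairs(recordings, windows, band, stage,
                                  env_rate=env_rate)
    if not pairs:
        raise ValueError(f"no {stage} windows in the cohort")
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    fwd = causality_index(xs, ys, bins=bins, lag=lag, band=band.name,
                          stage=stage)
    rev = causality_index(ys, xs, bins=bins, lag=lag, band=band.name,
                          stage=stage)
    return fwd.causality_index, rev.causality_index
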