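"""Directed-influence estimation between neural signals via transfer entropy.

Transfer entropy from a source series ``x`` to a target ``y`` is the
information the source's past adds about the target's future beyond the
target's own past:

.. math::

    T_{X \\to Y} = \\sum p(y_{t+1}, y_t, x_t)
        \\log \\frac{p(y_{t+1} \\mid y_t, x_t)}{p(y_{t+1} \\mid y_t)}

estimated here with a plug-in histogram over quantile-discretized series
(default 4 bins, lag 1).  The causality index (CI) for a (band, stage,
age-group) cell is the arithmetic mean of per-window transfer entropies
over that cell's stage-bout windows; its standard deviation across windows
quantifies variability.  The default direction is frontal to occipital
(Fpz-Cz to Pz-Oz), with the reverse always computed alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .bands import BandDefinition
from .preprocess import bandpass, design_bandpass_fir, zero_phase_filter
from .wavelets import _quantile_bin

__all__ = [
    "CausalityResult",
    "transfer_entropy",
    "causality_index",
    "causality_grid",
    "window_envelope",
    "window_envelope_pairs",
]

log = logging.getLogger(__name__)

FORWARD = ("EEG Fpz-Cz", "EEG Pz-Oz")  # frontal -> occipital


@dataclass
class CausalityResult:
    """Transfer-entropy summary for one (direction, band, stage, group) cell."""

    source: str
    target: str
    band: str
    stage: str
    age_group: str
    te_per_window: np.ndarray
    causality_index: float
    sd: float
    n_windows: int

    def __post_init__(self) -> None:
        self.te_per_window = np.asarray(self.te_per_window, dtype=float)
        if np.any(self.te_per_window < 0):
            raise ValueError("transfer entropies must be non-negative")
        if self.n_windows != len(self.te_per_window):
            raise ValueError("n_windows != number of TE values")


def _entropy(counts: np.ndarray, n: int, miller_madow: bool) -> float:
    p = counts[counts > 0] / n
    h = float(-np.sum(p * np.log(p)))
    if miller_madow:
        h += (len(p) - 1) / (2.0 * n)
    return h


def transfer_entropy(x, y, bins: int = 4, lag: int = 1,
                     miller_madow: bool = False) -> float:
    """Plug-in transfer entropy T_{X->Y} in nats.

    Both series are quantile-discretized into ``bins`` states; the estimate
    is the conditional mutual information
    ``I(y_{t+lag}; x_t | y_t)`` of the empirical joint over lag-``lag``
    triplets, computed as an entropy combination.  Small negative numerical
    results (possible under the Miller-Madow bias correction) are clipped
    to 0.  Constant series carry no information and return 0 (logged).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 20:
        raise ValueError("need at least 20 samples")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.debug("transfer_entropy: constant series, TE = 0")
        return 0.0
    xd, kx = _quantile_bin(x, bins)
    yd, ky = _quantile_bin(y, bins)

    yf = yd[lag:]           # y_{t+lag}
    yp = yd[:-lag]          # y_t
    xp = xd[:-lag]          # x_t
    n = len(yf)
    base = max(kx, ky)
    code_yy = yf * base + yp
    code_yx = yp * base + xp
    code_yyx = (yf * base + yp) * base + xp

    h_yy = _entropy(np.bincount(code_yy), n, miller_madow)
    h_yx = _entropy(np.bincount(code_yx), n, miller_madow)
    h_yyx = _entropy(np.bincount(code_yyx), n, miller_madow)
    h_y = _entropy(np.bincount(yp), n, miller_madow)
    te = h_yy + h_yx - h_yyx - h_y
    if te < 0:
        log.debug("transfer_entropy: clipped negative estimate %.3g", te)
        te = 0.0
    return float(te)


def causality_index(source_windows, target_windows, bins: int = 4,
                    lag: int = 1, source: str = FORWARD[0],
                    target: str = FORWARD[1], band: str = "", stage: str = "",
                    age_group: str = "",
                    miller_madow: bool = False) -> CausalityResult:
    """CI = mean transfer entropy over paired windows (Eq.-style average)."""
    if len(source_windows) == 0:
        raise ValueError("no windows supplied")
    if len(source_windows) != len(target_windows):
        raise ValueError("window lists must be paired")
    te = np.array([transfer_entropy(xs, ys, bins=bins, lag=lag,
                                    miller_madow=miller_madow)
                   for xs, ys in zip(source_windows, target_windows)])
    return CausalityResult(source=source, target=target, band=band,
                           stage=stage, age_group=age_group,
                           te_per_window=te,
                           causality_index=float(te.mean()),
                           sd=float(te.std(ddof=0)), n_windows=len(te))


def window_envelope(segment: np.ndarray, band: BandDefinition,
                    sample_rate: float, env_rate: float = 4.0,
                    _taps_cache: dict = {}) -> np.ndarray:
    """Band-limited amplitude envelope of a window, resampled to ``env_rate``.

    Band-pass (zero phase), Hilbert magnitude, then block averaging down to
    ``env_rate`` samples per second.
    """
    key = (band.name, band.low, band.high, sample_rate)
    taps = _taps_cache.get(key)
    if taps is None:
        taps = design_bandpass_fir(band.low, band.high, sample_rate)
        _taps_cache[key] = taps
    filtered = zero_phase_filter(np.asarray(segment, dtype=float), taps)
    env = np.abs(hilbert(filtered))
    block = int(round(sample_rate / env_rate))
    usable = (len(env) // block) * block
    return env[:usable].reshape(-1, block).mean(axis=1)


def window_envelope_pairs(recordings, windows, band: BandDefinition,
                          stage: str, source: str = FORWARD[0],
                          target: str = FORWARD[1],
                          env_rate: float = 4.0) -> list:
    """(source, target) envelope series for every window of ``stage``."""
    from .tensorize import slice_window

    rec_by_key = {(r.subject_id, r.condition): r for r in recordings}
    pairs = []
    for win in windows:
        if win.stage != stage:
            continue
        rec = rec_by_key[(win.subject_id, win.condition)]
        seg = slice_window(rec, win)
        pairs.append((
            window_envelope(seg[source], band, rec.sample_rate, env_rate),
            window_envelope(seg[target], band, rec.sample_rate, env_rate)))
    return pairs


def causality_grid(pairs_by_cell: dict, bins: int = 4, lag: int = 1,
                   source: str = FORWARD[0], target: str = FORWARD[1],
                   include_reverse: bool = True,
                   miller_madow: bool = False) -> list[CausalityResult]:
    """Full factorial sweep of causality indices over grid cells.

    ``pairs_by_cell`` maps ``(band, stage, age_group)`` to a list of
    (source-window series, target-window series) pairs.  For each non-empty
    cell the forward CI is computed, and by default also the reverse
    direction (windows swapped).  Empty cells are skipped and logged.
    """
    results: list[CausalityResult] = []
    for (band, stage, age_group), pairs in sorted(pairs_by_cell.items()):
        if not pairs:
            log.info("causality_grid: skipping empty cell %s",
                     (band, stage, age_group))
            continue
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        results.append(causality_index(xs, ys, bins=bins, lag=lag,
                                       source=source, target=target,
                                       band=band, stage=stage,
                                       age_group=age_group,
                                       miller_madow=miller_madow))
        if include_reverse:
            results.append(causality_index(ys, xs, bins=bins, lag=lag,
                                           source=target, target=source,
                                           band=band, stage=stage,
                                           age_group=age_group,
                                           miller_madow=miller_madow))
    return results
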