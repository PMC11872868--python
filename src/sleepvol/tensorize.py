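"""Assembly of the 5-axis sleep tensor and stage-transition windows.

The tensor axes are (subject, modality, band, frequency bin, time): one
recording per subject on the subject axis, the three modalities EEG / EOG /
EMG, seven default analysis bands, ``n_bins`` uniform sub-bands per band,
and the full sample grid on the time axis (an 8 h recording at 100 Hz gives
2,880,000 time points).  Bin content is the short-time Fourier magnitude at
the sub-band center frequency, interpolated onto the sample grid — the
package's documented stand-in for per-band frequency-bin trajectories.

Because a fully materialized default tensor is enormous (22 x 3 x 7 x 100 x
2,880,000 values), :func:`build_tensor` materializes values only when the
total element count is modest and otherwise returns the tensor with axis
metadata only (``values=None``); small analysis configurations and tests
materialize, full-night cohorts are processed band-wise by the pipeline.

Stage-transition features are computed on the *last 30 s of each stage
bout* (a maximal run of identical hypnogram labels); movement ("M") epochs
split bouts and yield no window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import BandDefinition, TENSOR_BANDS
from .synthgen import MOVEMENT, Hypnogram, Recording

__all__ = [
    "SleepTensor",
    "StageBoutWindow",
    "build_tensor",
    "tensor_axes",
    "find_stage_bouts",
    "slice_window",
]

MODALITIES = ("EEG", "EOG", "EMG")
#: representative channel per modality for tensor slabs
MODALITY_CHANNEL = {"EEG": "EEG Fpz-Cz", "EOG": "EOG horizontal",
                    "EMG": "EMG submental"}

_MAX_MATERIALIZE = int(2e8)  # elements


@dataclass
class StageBoutWindow:
    """The final 30-s epoch of one homogeneous stage bout."""

    subject_id: str
    condition: str
    stage: str
    bout_start: int      # first epoch index of the bout (inclusive)
    bout_end: int        # last epoch index of the bout (inclusive)
    start_epoch: int     # epoch index of the 30-s window (== bout_end)
    start_sample: int
    end_sample: int      # exclusive

    def __post_init__(self) -> None:
        if not (self.bout_start <= self.start_epoch <= self.bout_end):
            raise ValueError("window epoch outside its bout")
        if self.end_sample <= self.start_sample:
            raise ValueError("empty sample window")


@dataclass
class SleepTensor:
    """5-axis sleep tensor with axis metadata.

    ``values`` may be None for metadata-only (lazy) tensors; ``axes`` holds
    subjects, modalities, band definitions, the per-band bin count and the
    time-axis length.
    """

    values: np.ndarray | None
    subjects: list
    modalities: tuple
    bands: tuple
    n_bins: int
    n_times: int
    sample_rate: float

    def __post_init__(self) -> None:
        if self.values is not None:
            if self.values.shape != self.shape:
                raise ValueError(
                    f"values shape {self.values.shape} != axis metadata "
                    f"{self.shape}")
            if not np.all(np.isfinite(self.values)):
                raise ValueError("tensor contains non-finite values")

    @property
    def shape(self) -> tuple:
        return (len(self.subjects), len(self.modalities), len(self.bands),
                self.n_bins, self.n_times)

    def save(self, stem) -> None:
        """Persist as ``<stem>.npy`` plus a ``<stem>.axes.json`` sidecar."""
        import json
        from pathlib import Path

        stem = Path(stem)
        meta = {"subjects": list(self.subjects),
                "modalities": list(self.modalities),
                "bands": [[b.name, b.low, b.high] for b in self.bands],
                "n_bins": self.n_bins, "n_times": self.n_times,
                "sample_rate": self.sample_rate,
                "materialized": self.values is not None}
        with open(f"{stem}.axes.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
        if self.values is not None:
            np.save(f"{stem}.npy", self.values)

    @classmethod
    def load(cls, stem) -> "SleepTensor":
        import json
        from os.path import exists

        with open(f"{stem}.axes.json") as fh:
            meta = json.load(fh)
        values = np.load(f"{stem}.npy") if exists(f"{stem}.npy") else None
        return cls(values=values, subjects=meta["subjects"],
                   modalities=tuple(meta["modalities"]),
                   bands=tuple(BandDefinition(*b) for b in meta["bands"]),
                   n_bins=meta["n_bins"], n_times=meta["n_times"],
                   sample_rate=meta["sample_rate"])

    def time_major(self, subject_index: int) -> np.ndarray:
        """Flattened 3-axis view (time x modality x band*bin) per subject."""
        if self.values is None:
            raise ValueError("tensor is not materialized")
        v = self.values[subject_index]  # (mod, band, bin, time)
        m, b, k, t = v.shape
        return v.reshape(m, b * k, t).transpose(2, 0, 1)


def tensor_axes(recordings, bands=TENSOR_BANDS, n_bins: int = 100) -> SleepTensor:
    """Axis metadata for the tensor of ``recordings`` without materializing."""
    _validate_homogeneous(recordings)
    return SleepTensor(values=None,
                       subjects=[r.subject_id for r in recordings],
                       modalities=MODALITIES, bands=tuple(bands),
                       n_bins=n_bins, n_times=recordings[0].n_samples,
                       sample_rate=recordings[0].sample_rate)


def _validate_homogeneous(recordings) -> None:
    if not recordings:
        raise ValueError("no recordings supplied")
    n = {r.n_samples for r in recordings}
    fs = {r.sample_rate for r in recordings}
    if len(n) > 1 or len(fs) > 1:
        raise ValueError(
            f"recordings are heterogeneous: lengths {sorted(n)}, "
            f"rates {sorted(fs)}")


def _band_bin_trajectories(x: np.ndarray, sample_rate: float,
                           band: BandDefinition, n_bins: int,
                           n_times: int,
                           window_seconds: float = 11.0) -> np.ndarray:
    """|STFT| at the band's sub-band centers, interpolated onto the sample grid.

    Uses the Welch window settings (Hamming taper, 50% overlap).
    """
    nperseg = min(int(round(window_seconds * sample_rate)), len(x))
    freqs, seg_times, Z = sps.stft(x, fs=sample_rate, window="hamming",
                                   nperseg=nperseg,
                                   noverlap=nperseg // 2, boundary="zeros",
                                   padded=True)
    mag = np.abs(Z)  # (freq, seg)
    width = band.width / n_bins
    centers = band.low + (np.arange(n_bins) + 0.5) * width
    t_grid = np.arange(n_times) / sample_rate
    out = np.empty((n_bins, n_times))
    # interpolate over frequency per segment, then over time per bin
    at_centers = np.empty((n_bins, mag.shape[1]))
    for j in range(mag.shape[1]):
        at_centers[:, j] = np.interp(centers, freqs, mag[:, j])
    for k in range(n_bins):
        out[k] = np.interp(t_grid, seg_times, at_centers[k])
    return out


def build_tensor(recordings, bands=TENSOR_BANDS, n_bins: int = 100,
                 materialize: str | bool = "auto",
                 window_seconds: float = 11.0) -> SleepTensor:
    """Build the 5-axis tensor (subject x modality x band x bin x time).

    ``materialize`` may be True, False, or "auto" (materialize only when
    the element count stays below ~2e8).  Metadata-only tensors carry the
    full axis description and can be materialized later on subsets.
    """
    meta = tensor_axes(recordings, bands, n_bins)
    n_elements = int(np.prod(meta.shape))
    if materialize == "auto":
        materialize = n_elements <= _MAX_MATERIALIZE
    if not materialize:
        return meta
    if n_elements > 4 * _MAX_MATERIALIZE:
        raise MemoryError(
            f"refusing to materialize {n_elements:.2e} tensor elements; "
            "use materialize=False or a smaller configuration")
    values = np.zeros(meta.shape, dtype=np.float32)
    for si, rec in enumerate(recordings):
        for mi, mod in enumerate(MODALITIES):
            x = np.asarray(rec.channels[MODALITY_CHANNEL[mod]], dtype=float)
            for bi, band in enumerate(bands):
                values[si, mi, bi] = _band_bin_trajectories(
                    x, rec.sample_rate, band, n_bins, meta.n_times,
                    window_seconds)
    return SleepTensor(values=values, subjects=meta.subjects,
                       modalities=meta.modalities, bands=meta.bands,
                       n_bins=n_bins, n_times=meta.n_times,
                       sample_rate=meta.sample_rate)


def find_stage_bouts(hypnogram: Hypnogram, subject_id: str = "",
                     condition: str = "",
                     sample_rate: float = 100.0) -> list[StageBoutWindow]:
    """Maximal runs of identical stage labels, one window per run.

    Each run contributes its final 30-s epoch as the feature window;
    movement epochs split runs and contribute nothing.
    """
    stages = list(hypnogram.stages)
    if not stages:
        raise ValueError("empty hypnogram")
    epoch_samples = int(round(hypnogram.epoch_seconds * sample_rate))
    windows: list[StageBoutWindow] = []
    run_start = 0
    for i in range(1, len(stages) + 1):
        if i == len(stages) or stages[i] != stages[run_start]:
            stage = stages[run_start]
            if stage != MOVEMENT:
                end = i - 1
                windows.append(StageBoutWindow(
                    subject_id=subject_id, condition=condition, stage=stage,
                    bout_start=run_start, bout_end=end, start_epoch=end,
                    start_sample=end * epoch_samples,
                    end_sample=(end + 1) * epoch_samples))
            run_start = i
    return windows


def slice_window(obj, window: StageBoutWindow):
    """Extract the window's samples from a Recording or SleepTensor.

    For a :class:`Recording` returns a dict channel -> samples (exactly
    ``epoch_seconds * sample_rate`` samples per channel); for a
    materialized :class:`SleepTensor` returns the (subject, modality, band,
    bin, window-time) slab.
    """
    s, e = window.start_sample, window.end_sample
    if isinstance(obj, Recording):
        if e > obj.n_samples or s < 0:
            raise IndexError(
                f"window samples [{s}, {e}) outside recording of "
                f"{obj.n_samples} samples")
        return {name: np.asarray(sig[s:e], dtype=float)
                for name, sig in obj.channels.items()}
    if isinstance(obj, SleepTensor):
        if obj.values is None:
            raise ValueError("tensor is not materialized")
        if e > obj.n_times or s < 0:
            raise IndexError("window outside tensor time axis")
        return obj.values[..., s:e]
    raise TypeError(f"cannot slice a {type(obj).__name__}")
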