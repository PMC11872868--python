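"""Recording I/O: EDF signals with a sidecar hypnogram CSV.

The writer emits a plain 16-bit EDF file (one data record per second) plus
``<stem>.hypnogram.csv`` (columns ``epoch_index, stage``) and
``<stem>.meta.json`` with subject metadata, mirroring how the Sleep-EDF
sleep-telemetry recordings pair a signal file with a hypnogram file.  The
reader accepts the same trio — or a real EDF/EDF+ recording with a
compatible channel set and a CSV hypnogram — so archive data can be
substituted for synthetic cohorts.  Signals round-trip within the 16-bit
EDF amplitude quantization; stage labels round-trip exactly.

EDF reading is delegated to :mod:`mne`; the writer is a minimal standard-
conforming EDF encoder (field-major ASCII headers, little-endian int16
records), which no installed library provides.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .synthgen import CHANNEL_NAMES, GarchParams, Hypnogram, Recording

__all__ = ["write_recording", "read_recording"]

_HDR_DATE = "01.01.00"
_HDR_TIME = "00.00.00"


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    for fmt in ("%g", "%.5g", "%.4g", "%.3g"):
        s = fmt % x
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {x} in {width} chars")


def write_recording(recording: Recording, stem) -> dict:
    """Write ``<stem>.edf``, ``<stem>.hypnogram.csv`` and ``<stem>.meta.json``.

    Returns the mapping of written file roles to paths.  The signal length
    must be an integer number of seconds (one EDF record per second).
    """
    stem = Path(stem)
    fs = recording.sample_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("sample rate must be an integer for EDF records")
    n = recording.n_samples
    if n % spr:
        raise ValueError("signal length must be a whole number of seconds")
    n_records = n // spr
    names = list(recording.channels)
    ns = len(names)

    # physical scaling per channel: symmetric range covering the data
    phys_max = {}
    for name in names:
        amax = float(np.max(np.abs(recording.channels[name])))
        phys_max[name] = max(np.ceil(amax * 1.01), 1.0)

    header = b""
    header += _ascii("0", 8)
    header += _ascii(f"{recording.subject_id} {recording.sex} "
                     f"{recording.age}", 80)
    header += _ascii(f"night {recording.night} {recording.condition}", 80)
    header += _ascii(_HDR_DATE, 8)
    header += _ascii(_HDR_TIME, 8)
    header += _ascii(256 * (1 + ns), 8)
    header += _ascii("", 44)
    header += _ascii(n_records, 8)
    header += _ascii("1", 8)
    header += _ascii(ns, 4)
    # field-major per-signal headers
    header += b"".join(_ascii(nm, 16) for nm in names)
    header += b"".join(_ascii("", 80) for _ in names)
    header += b"".join(_ascii("uV", 8) for _ in names)
    header += b"".join(_ascii(_fmt_float(-phys_max[nm]), 8) for nm in names)
    header += b"".join(_ascii(_fmt_float(phys_max[nm]), 8) for nm in names)
    header += b"".join(_ascii("-32768", 8) for _ in names)
    header += b"".join(_ascii("32767", 8) for _ in names)
    header += b"".join(_ascii("", 80) for _ in names)
    header += b"".join(_ascii(spr, 8) for _ in names)
    header += b"".join(_ascii("", 32) for _ in names)

    digital = np.empty((ns, n), dtype="<i2")
    for i, nm in enumerate(names):
        x = np.asarray(recording.channels[nm], dtype=float)
        scaled = np.clip(x / phys_max[nm], -1.0, 1.0) * 32767.0
        digital[i] = np.round(scaled).astype("<i2")
    # records: (record, signal, sample)
    records = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)

    edf_path = stem.with_suffix(".edf")
    with open(edf_path, "wb") as fh:
        fh.write(header)
        fh.write(records.tobytes())

    hyp_path = Path(str(stem) + ".hypnogram.csv")
    with open(hyp_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "stage"])
        for i, st in enumerate(recording.hypnogram.stages):
            w.writerow([i, st])

    meta_path = Path(str(stem) + ".meta.json")
    meta = {"subject_id": recording.subject_id, "age": recording.age,
            "age_group": recording.age_group, "sex": recording.sex,
            "condition": recording.condition, "night": recording.night,
            "epoch_seconds": recording.hypnogram.epoch_seconds}
    if recording.truth is not None:
        meta["garch_truth"] = {"alpha0": recording.truth.alpha0,
                               "alpha1": recording.truth.alpha1,
                               "beta1": recording.truth.beta1,
                               "mu": recording.truth.mu}
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return {"edf": edf_path, "hypnogram": hyp_path, "meta": meta_path}


def _match_channel(wanted: str, available: list) -> str:
    if wanted in available:
        return wanted
    tail = wanted.split(" ")[-1].lower()
    for ch in available:
        if ch.lower().endswith(tail):
            return ch
    raise ValueError(
        f"channel {wanted!r} not found in EDF (has {available})")


def read_recording(edf_path, hypnogram_path=None, meta_path=None) -> Recording:
    """Read an EDF/EDF+ recording plus its sidecar hypnogram CSV.

    Channels are matched by name (tolerating label prefix differences
    between writers); amplitudes are returned in µV.
    """
    import mne

    edf_path = Path(edf_path)
    stem = edf_path.with_suffix("")
    if hypnogram_path is None:
        hypnogram_path = Path(str(stem) + ".hypnogram.csv")
    if meta_path is None:
        candidate = Path(str(stem) + ".meta.json")
        meta_path = candidate if candidate.exists() else None

    try:
        raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="ERROR")
    except Exception as exc:
        raise ValueError(f"malformed EDF file {edf_path}: {exc}") from exc
    available = list(raw.ch_names)
    if len(available) < len(CHANNEL_NAMES):
        raise ValueError(
            f"expected {len(CHANNEL_NAMES)} channels, found "
            f"{len(available)}: {available}")
    channels = {}
    for wanted in CHANNEL_NAMES:
        name = _match_channel(wanted, available)
        data = raw.get_data(picks=[name])[0]
        channels[wanted] = data * 1e6  # mne returns SI volts

    stages = []
    with open(hypnogram_path, newline="") as fh:
        for row in csv.DictReader(fh):
            stages.append(row["stage"])

    meta = {}
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
    truth = None
    if "garch_truth" in meta:
        truth = GarchParams(**meta["garch_truth"])
    return Recording(
        subject_id=meta.get("subject_id", edf_path.stem),
        age=int(meta.get("age", 0)),
        age_group=meta.get("age_group", ""),
        sex=meta.get("sex", ""),
        condition=meta.get("condition", ""),
        night=int(meta.get("night", 1)),
        channels=channels,
        sample_rate=float(raw.info["sfreq"]),
        hypnogram=Hypnogram(np.array(stages, dtype=object),
                            float(meta.get("epoch_seconds", 30.0))),
        truth=truth)
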