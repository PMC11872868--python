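"""Physiological frequency-band definitions for sleep EEG/EMG/EOG.

The canonical EEG bands used throughout the package.  ``DEFAULT_BANDS``
holds all eight analysis bands; ``TENSOR_BANDS`` is the seven-band subset
that forms the default band axis of the sleep tensor (sigma, which overlaps
the spindle band almost entirely, is computed as a feature band but left
off the tensor axis by default).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[low, high]`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(
                f"invalid band {self.name}: need 0 <= low < high, got "
                f"[{self.low}, {self.high}]"
            )

    def validate_for_rate(self, sample_rate: float) -> None:
        if self.high > sample_rate / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz exceeds the "
                f"Nyquist frequency {sample_rate / 2} Hz"
            )

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


DELTA = BandDefinition("delta", 0.5, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 14.0, 30.0)
# Gamma capped at 45 Hz: the 100 Hz sampling rate puts Nyquist at 50 Hz.
GAMMA = BandDefinition("gamma", 30.0, 45.0)
SWA = BandDefinition("swa", 0.5, 2.0)
SPINDLE = BandDefinition("spindle", 12.0, 16.0)
SIGMA = BandDefinition("sigma", 12.0, 15.0)

DEFAULT_BANDS = (DELTA, THETA, ALPHA, BETA, GAMMA, SWA, SPINDLE, SIGMA)
TENSOR_BANDS = (DELTA, THETA, ALPHA, BETA, GAMMA, SWA, SPINDLE)

BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}
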