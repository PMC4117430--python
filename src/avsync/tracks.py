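"""Uniformly sampled articulatory / acoustic trajectory tracks.

A :class:`TrajectoryTrack` is the common currency of the package: one channel
(lip height in cm, acoustic intensity in dB, or a formant frequency in Hz)
sampled at a fixed rate.  Lip tracks are sampled at 50 Hz (the video field
rate), acoustic tracks at 100 Hz.  Samples where the quantity is physically
undefined (formants during silence or voiceless closure) are stored as NaN;
every consumer in the package treats NaN as "undefined" and must skip it.

Times are absolute seconds from the start of the recording, never sample
indices, so channels with different rates can be mixed freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Channel identifiers used throughout the package.
LIP = "lip_height_cm"
INTENSITY = "intensity_dB"
F1 = "F1_Hz"
F2 = "F2_Hz"
F3 = "F3_Hz"

CHANNELS = (LIP, INTENSITY, F1, F2, F3)
ACOUSTIC_CHANNELS = (INTENSITY, F1, F2, F3)

#: Default sample rates per channel (Hz).
DEFAULT_RATES = {LIP: 50.0, INTENSITY: 100.0, F1: 100.0, F2: 100.0, F3: 100.0}


@dataclass
class TrajectoryTrack:
    """One uniformly sampled channel.

    Parameters
    ----------
    channel:
        One of :data:`CHANNELS`.
    sample_rate_hz:
        Sampling rate, > 0.
    t0_s:
        Time of the first sample, seconds.
    values:
        Sample values; NaN marks undefined samples.
    """

    channel: str
    sample_rate_hz: float
    t0_s: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        finite = self.values[np.isfinite(self.values)]
        if self.channel == LIP and finite.size and finite.min() < -1e-9:
            raise ValueError("lip height must be non-negative")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz

    @property
    def n(self) -> int:
        return self.values.size

    def times(self) -> np.ndarray:
        """Absolute sample times in seconds."""
        return self.t0_s + np.arange(self.n) / self.sample_rate_hz

    def value_at(self, t) -> np.ndarray:
        """Linear interpolation at time(s) ``t``, over defined samples only."""
        t = np.asarray(t, dtype=float)
        defined = np.isfinite(self.values)
        if defined.sum() < 2:
            return np.full(t.shape, np.nan)
        return np.interp(t, self.times()[defined], self.values[defined])

    def derivative_at(self, t, half_step_s: float = 0.005) -> np.ndarray:
        """Central finite-difference velocity at time(s) ``t`` (units/s)."""
        hi = self.value_at(np.asarray(t) + half_step_s)
        lo = self.value_at(np.asarray(t) - half_step_s)
        return (hi - lo) / (2.0 * half_step_s)
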