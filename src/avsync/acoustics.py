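"""Frame-wise intensity and LPC formant analysis of waveforms.

Optional real-audio path: instead of taking intensity and formant tracks
from the synthetic generator, compute them from a mono waveform the way a
phonetician would in standard speech-analysis software — frame-wise RMS
intensity in dB, and formants from the roots of an autocorrelation-LPC
polynomial per frame.  A small cascade-resonator formant synthesizer rounds
the analysis off: synthesizing a vowel with known resonances and recovering
them through the LPC path is the module's core self-check.

Analysis defaults follow common formant-analysis practice: 25 ms frames with
a 10 ms hop, pre-emphasis 0.97, downsampling to 10 kHz with LPC order 12,
and a 400 Hz bandwidth ceiling for counting a pole as a formant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.signal import resample_poly

from .tracks import F1, F2, F3, INTENSITY, TrajectoryTrack

logger = logging.getLogger(__name__)


@dataclass
class Waveform:
    sample_rate_hz: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


@dataclass
class AnalysisConfig:
    frame_length_s: float = 0.025
    hop_s: float = 0.010
    lpc_order: int = 12
    analysis_band_hz: float = 10_000.0
    preemphasis: float = 0.97
    formant_bandwidth_max_hz: float = 400.0
    f1_search_range_hz: tuple = (150.0, 1000.0)
    silence_floor_db: float = -60.0

    def __post_init__(self) -> None:
        if not (0 < self.hop_s <= self.frame_length_s):
            raise ValueError("need 0 < hop_s <= frame_length_s")
        if self.lpc_order < 4:
            raise ValueError("lpc_order must be >= 4")


def _frame_starts(n: int, frame: int, hop: int) -> np.ndarray:
    if n < frame:
        return np.array([], dtype=int)
    return np.arange(0, n - frame + 1, hop)


def compute_intensity(w: Waveform, cfg: AnalysisConfig | None = None
                      ) -> TrajectoryTrack:
    """Frame-wise intensity, dB re full scale (0 dB = unit mean square).

    Frames are ``frame_length_s`` long every ``hop_s``; each value is
    10 log10 of the frame's mean squared amplitude, floored at
    ``silence_floor_db``.  Track times refer to frame centres.
    """
    cfg = cfg or AnalysisConfig()
    if w.samples.size == 0:
        raise ValueError("empty waveform")
    frame = max(int(round(cfg.frame_length_s * w.sample_rate_hz)), 1)
    hop = max(int(round(cfg.hop_s * w.sample_rate_hz)), 1)
    starts = _frame_starts(w.samples.size, frame, hop)
    if starts.size == 0:
        starts = np.array([0])
        frame = w.samples.size
    vals = np.empty(starts.size)
    for i, s0 in enumerate(starts):
        ms = np.mean(w.samples[s0:s0 + frame] ** 2)
        vals[i] = 10.0 * np.log10(ms) if ms > 0 else -np.inf
    vals = np.maximum(vals, cfg.silence_floor_db)
    return TrajectoryTrack(INTENSITY, 1.0 / cfg.hop_s,
                           t0_s=0.5 * frame / w.sample_rate_hz, values=vals)


def _lpc_coefficients(frame: np.ndarray, order: int) -> np.ndarray:
    """Autocorrelation-method LPC prediction polynomial [1, a1..ap]."""
    r = np.correlate(frame, frame, mode="full")[frame.size - 1:
                                                frame.size + order]
    if r[0] <= 0:
        raise np.linalg.LinAlgError("zero-energy frame")
    r = r + np.finfo(float).eps * r[0] * np.arange(order + 1)
    a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    return np.concatenate(([1.0], a))


def _roots_to_formants(a: np.ndarray, fs: float, cfg: AnalysisConfig):
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * fs / (2.0 * np.pi)
    bws = -np.log(np.maximum(np.abs(roots), 1e-12)) * fs / np.pi
    keep = (freqs > 60.0) & (freqs < fs / 2 - 60.0) & \
           (bws < cfg.formant_bandwidth_max_hz)
    return np.sort(freqs[keep])


def lpc_formants(w: Waveform, cfg: AnalysisConfig | None = None) -> dict:
    """F1-F3 tracks from per-frame LPC root-finding.

    Per frame: pre-emphasis, Hamming window, autocorrelation LPC
    (Levinson-Durbin via a Toeplitz solve), polynomial roots; poles with
    bandwidth below the ceiling count as formant candidates.  F1 is the
    lowest candidate inside the F1 search range; F2 and F3 the next two
    above it, continuity-matched to the previous frame (nearest frequency,
    ties toward the lower candidate).  Frames at or below the silence floor,
    and unstable LPC frames, yield undefined (NaN) samples — never an
    exception.
    """
    cfg = cfg or AnalysisConfig()
    # Downsample so the LPC order matches the analysis band.
    if w.sample_rate_hz > cfg.analysis_band_hz:
        from fractions import Fraction

        frac = Fraction(int(cfg.analysis_band_hz),
                        int(w.sample_rate_hz)).limit_denominator(1000)
        samples = resample_poly(w.samples, frac.numerator, frac.denominator)
        fs = w.sample_rate_hz * frac.numerator / frac.denominator
    else:
        samples, fs = w.samples, w.sample_rate_hz
    emph = np.append(samples[0], samples[1:] - cfg.preemphasis * samples[:-1])

    frame = int(round(cfg.frame_length_s * fs))
    hop = int(round(cfg.hop_s * fs))
    starts = _frame_starts(emph.size, frame, hop)
    window = np.hamming(frame)
    floor_ms = 10.0 ** (cfg.silence_floor_db / 10.0)

    out = np.full((starts.size, 3), np.nan)
    prev = None
    for i, s0 in enumerate(starts):
        seg = samples[s0:s0 + frame]
        if np.mean(seg ** 2) <= floor_ms:
            prev = None
            continue
        try:
            a = _lpc_coefficients(emph[s0:s0 + frame] * window, cfg.lpc_order)
            cands = _roots_to_formants(a, fs, cfg)
        except np.linalg.LinAlgError:
            logger.warning("unstable LPC frame at %d; undefined", s0)
            prev = None
            continue
        lo, hi = cfg.f1_search_range_hz
        in_range = cands[(cands >= lo) & (cands <= hi)]
        if in_range.size == 0 or cands.size < 3:
            prev = None
            continue
        f1 = in_range[0]
        above = cands[cands > f1]
        if above.size < 2:
            prev = None
            continue
        if prev is not None and above.size > 2:
            # Continuity: choose the pair closest to the previous (F2, F3).
            best, best_cost = None, np.inf
            for j in range(above.size - 1):
                for k in range(j + 1, above.size):
                    cost = abs(above[j] - prev[1]) + abs(above[k] - prev[2])
                    if cost < best_cost:  # strict: ties go to lower pair
                        best, best_cost = (above[j], above[k]), cost
            f2, f3 = best
        else:
            f2, f3 = above[0], above[1]
        out[i] = (f1, f2, f3)
        prev = out[i]

    rate = 1.0 / cfg.hop_s
    t0 = 0.5 * frame / fs
    return {
        F1: TrajectoryTrack(F1, rate, t0, out[:, 0]),
        F2: TrajectoryTrack(F2, rate, t0, out[:, 1]),
        F3: TrajectoryTrack(F3, rate, t0, out[:, 2]),
    }


def synthesize_formant_audio(formant_tracks: dict,
                             intensity: TrajectoryTrack | None,
                             fs: float = 22_050.0, f0_hz: float = 120.0,
                             bandwidths_hz=(80.0, 100.0, 140.0),
                             noise_mix: float = 0.0,
                             duration_s: float | None = None,
                             seed: int = 0) -> Waveform:
    """Cascade-resonator formant synthesizer (the analysis oracle).

    An impulse train at ``f0_hz`` (optionally with a white-noise admixture,
    ``noise_mix``) is passed through three cascaded second-order resonators
    following the F1-F3 tracks, then frame-scaled to the intensity track
    (dB re full scale).  Formants at or above the Nyquist frequency are
    rejected.
    """
    tracks = [formant_tracks[ch] for ch in (F1, F2, F3)]
    if duration_s is None:
        duration_s = max(tr.t0_s + tr.n / tr.sample_rate_hz for tr in tracks)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    f_per_sample = np.vstack([tr.value_at(t) for tr in tracks])
    if np.any(f_per_sample >= fs / 2):
        raise ValueError("formant frequency at or above Nyquist")

    rng = np.random.default_rng(seed)
    period = max(int(round(fs / f0_hz)), 1)
    source = np.zeros(n)
    source[::period] = 1.0
    source = source + noise_mix * rng.standard_normal(n)

    y = source
    for row, bw in zip(f_per_sample, bandwidths_hz):
        r = np.exp(-np.pi * bw / fs)
        theta = 2.0 * np.pi * row / fs
        c1 = 2.0 * r * np.cos(theta)
        c2 = -r * r
        gain = (1.0 - r) * np.sqrt(1.0 + r * r - 2.0 * r * np.cos(2 * theta))
        out = np.zeros(n)
        y1 = y2 = 0.0
        for i in range(n):
            out[i] = gain[i] * y[i] + c1[i] * y1 + c2 * y2
            y2, y1 = y1, out[i]
        y = out

    if intensity is not None:
        # Frame-wise scale to the requested dB (re full scale) contour.
        hop = max(int(round(fs * 0.010)), 1)
        for s0 in range(0, n, hop):
            seg = y[s0:s0 + hop]
            target_db = float(intensity.value_at((s0 + 0.5 * hop) / fs))
            target_rms = 10.0 ** (target_db / 20.0)
            rms = np.sqrt(np.mean(seg ** 2))
            seg *= target_rms / rms if rms > 0 else 0.0
    else:
        peak = np.max(np.abs(y))
        if peak > 0:
            y = 0.5 * y / peak
    return Waveform(fs, np.clip(y, -1.0, 1.0))
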