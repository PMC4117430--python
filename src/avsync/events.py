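"""Onset event detection on trajectory tracks.

Events are onsets of closing or opening gestures, found with a hysteresis
scan referenced to running extrema: for decrease-onsets the scan maintains
the running maximum of the track; when the signal departs from that extremum
by at least the channel threshold (1 dB intensity, 60 Hz formant, 0.15 cm lip
height), an event is emitted at the *time of the extremum* — the beginning of
the decrease, not the later threshold-crossing instant, which would bias all
events late by a slope-dependent amount — and the extremum tracker resets.
Increase-onsets mirror this around the running minimum.  Undefined (NaN)
samples are skipped and break extremum runs.

Several refinements make the extremum time robust on sampled, noisy tracks
(each is an internal tuning of the detector, not a scientific threshold):

* acoustic tracks are median-filtered (width 5 at 100 Hz) before scanning —
  the median is invariant on monotone segments, so transitions keep their
  timing;
* the extremum tracker follows the signal while successive samples stay
  within a flatness tolerance (half the channel threshold) of the current
  extremum, so noise peaks neither freeze the tracker nor steal the onset
  time on long plateaus;
* a departure is only accepted once it deepens to twice the threshold (or
  runs into undefined samples) within the same excursion — real closing and
  opening gestures travel far past the detection threshold, noise dips do
  not — and after each event the scan is refractory until the signal
  rebounds a full threshold (one monotone gesture fires exactly once);
* the emitted onset time is re-anchored to the last sample consistent with a
  robust local plateau level (75th percentile of the recent window) and then
  refined to sub-sample precision with a small set of closed-form models
  (quadratic gesture foot, linear ramp, saturating jump, post-silence
  boundary; see :func:`_refine_onset_time`).  Refinement matters most for
  the 50 Hz lip track, where one sample is 20 ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .tracks import F1, INTENSITY, LIP, TrajectoryTrack

logger = logging.getLogger(__name__)

#: kind -> (channel, phase, direction)
EVENT_TABLE = {
    "CVL": (LIP, "closing", "decrease"),
    "OVL": (LIP, "opening", "increase"),
    "CAI": (INTENSITY, "closing", "decrease"),
    "OAI": (INTENSITY, "opening", "increase"),
    "CAF": (F1, "closing", "decrease"),
    "OAF": (F1, "opening", "increase"),
}


@dataclass
class DetectionThresholds:
    """Departure-from-extremum thresholds per channel."""

    intensity_delta_db: float = 1.0
    formant_delta_hz: float = 60.0
    lip_delta_cm: float = 0.15

    def __post_init__(self) -> None:
        if min(self.intensity_delta_db, self.formant_delta_hz,
               self.lip_delta_cm) <= 0:
            raise ValueError("thresholds must be > 0")

    def for_channel(self, channel: str) -> float:
        if channel == LIP:
            return self.lip_delta_cm
        if channel == INTENSITY:
            return self.intensity_delta_db
        if channel in (F1,):
            return self.formant_delta_hz
        raise ValueError(f"no threshold for channel {channel!r}")


@dataclass
class DetectorSettings:
    """Internal detector tuning (not the scientific thresholds).

    ``tie_tol_frac`` is the extremum flatness tolerance as a fraction of the
    channel threshold; ``median_width_acoustic`` is the median-filter width
    (samples) applied to 100 Hz acoustic tracks; ``min_gap_s`` suppresses
    spurious micro-events closer than this to the previous event.
    """

    tie_tol_frac: float = 0.5
    median_width_acoustic: int = 5
    median_width_lip: int = 1
    min_gap_s: float = 0.05
    plateau_window: int = 10
    max_walk_back: int = 30
    confirm_mult: float = 2.0
    confirm_window: int = 30


@dataclass
class EventLabel:
    kind: str
    time_s: float
    channel: str
    phase: str
    direction: str
    token_id: str = ""
    consonant: str = ""
    mode: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_TABLE:
            raise ValueError(f"unknown event kind {self.kind!r}")
        ch, phase, direction = EVENT_TABLE[self.kind]
        if (self.channel, self.phase, self.direction) != (ch, phase, direction):
            raise ValueError(
                f"{self.kind} must be ({ch}, {phase}, {direction})")


def _quad_onset(ta: float, da: float, tb: float, db: float) -> float:
    """Onset of a quadratic departure d = a (t - t*)^2 from two depths."""
    r = float(np.sqrt(da / db))
    return (ta - r * tb) / (1.0 - r)


def _refine_onset_time(raw: np.ndarray, anchor: int, level: float, dt: float,
                       t0: float, direction: str, tie_tol: float,
                       noise_scale: float, boundary: bool,
                       allow_foot: bool) -> float:
    """Sub-sample onset estimate at a plateau-to-gesture corner.

    Four physically distinct shapes are handled, all reducing to simple
    closed forms on the raw samples around the anchor:

    * gesture foot under the anchor (slow gestures, e.g. 50 Hz lip tracks):
      the anchor already sits measurably below the plateau level — solve the
      quadratic-foot model through the anchor and its successor;
    * accelerating departure from the plateau corner: quadratic-foot model
      through the two post-anchor samples;
    * linear or saturating departure (ramps, plosive bursts): secant through
      the two post-anchor samples extrapolated back to the plateau level;
    * ``boundary`` onsets (first defined sample after a silence gap, where
      no plateau exists): plain parabola vertex through three samples,
      clamped to at most one interval before the anchor.

    Estimates are clamped to one inter-sample interval around the anchor.
    """
    t_a = t0 + anchor * dt
    if anchor + 2 >= raw.size:
        return t_a
    y0, y1, y2 = raw[anchor], raw[anchor + 1], raw[anchor + 2]
    if not (np.isfinite(y0) and np.isfinite(y1) and np.isfinite(y2)):
        return t_a
    sign = 1.0 if direction == "decrease" else -1.0
    y0, y1, y2 = sign * y0, sign * y1, sign * y2
    t1, t2 = t_a + dt, t_a + 2 * dt

    if boundary:
        curv = y0 - 2.0 * y1 + y2
        if curv >= 0:  # not a local maximum of the oriented signal
            return t_a
        x_v = (3.0 * y0 - 4.0 * y1 + y2) / (2.0 * curv)
        return t_a + float(np.clip(x_v, -1.0, 0.0)) * dt

    lev = sign * level
    d0, d1, d2 = lev - y0, lev - y1, lev - y2
    if not (0 < d1 < d2):
        return t_a
    foot_gate = max(3.0 * noise_scale, 0.1 * tie_tol)
    if allow_foot and d0 > foot_gate and d0 < d1:
        # The anchor itself is measurably on the gesture foot (only trusted
        # on the lip channel; the gate sits above the robust noise spread of
        # the plateau window).
        t_star = _quad_onset(t_a, d0, t1, d1)
    else:
        if anchor + 3 < raw.size and np.isfinite(raw[anchor + 3]):
            d3 = lev - sign * raw[anchor + 3]
        else:
            d3 = np.inf
        if d3 - d2 < 0.1 * (d2 - d1):
            # Depth increments collapsed: the transition is essentially
            # complete within two samples (e.g. a plosive burst) — secant
            # through the two departure samples back to the plateau level.
            t_star = t1 - d1 * dt / (y1 - y2)
        else:
            # Smooth gesture: quadratic-foot model through the departures.
            t_star = _quad_onset(t1, d1, t2, d2)
    return float(np.clip(t_star, t_a - dt, t_a + dt))


def _plateau_anchor(s: np.ndarray, j: int, tol: float,
                    settings: DetectorSettings, fallback: int):
    """Robust onset anchor: the last pre-departure sample still on the
    extremum plateau.

    The plateau level is estimated as the 75th percentile of the recent
    window before the departure sample ``j`` (robust to the few transition
    samples the window may contain); the anchor is the last index before
    ``j`` whose value is within ``tol`` of that level.  This keeps the onset
    time tied to the local plateau even when the running-extremum tracker
    settled on a noise excursion.
    """
    lo = max(0, j - settings.plateau_window)
    window = s[lo:j]
    window = window[np.isfinite(window)]
    if window.size == 0:
        return fallback, None, 0.0
    level = float(np.median(window))
    spread = 1.4826 * float(np.median(np.abs(window - level)))  # robust SD
    for k in range(j - 1, max(-1, j - 1 - settings.max_walk_back), -1):
        if not np.isfinite(s[k]):
            break
        if s[k] >= level - tol:
            return k, level, spread
    return fallback, level, spread


def _filtered(values: np.ndarray, width: int) -> np.ndarray:
    """Median-filter each contiguous defined segment; NaN gaps are opaque."""
    if width <= 1:
        return values
    out = values.copy()
    defined = np.isfinite(values)
    if not defined.any():
        return out
    edges = np.flatnonzero(np.diff(defined.astype(int)))
    starts = np.r_[0, edges + 1]
    stops = np.r_[edges + 1, values.size]
    for a, b in zip(starts, stops):
        if defined[a] and b - a > 1:
            out[a:b] = median_filter(values[a:b], size=width, mode="nearest")
    return out


def detect_onsets(track: TrajectoryTrack, thresholds: DetectionThresholds,
                  direction: str, interpolate: bool = True,
                  settings: DetectorSettings | None = None) -> list:
    """Hysteresis scan for gesture onsets in one direction.

    Returns a list of ``(onset_time_s, extremum_value)`` pairs, in time
    order.  ``direction`` is ``"decrease"`` (onsets of falls, referenced to
    running maxima) or ``"increase"`` (onsets of rises, referenced to running
    minima).
    """
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    if track.n < 3:
        raise ValueError("track must have at least 3 samples")
    settings = settings or DetectorSettings()
    threshold = thresholds.for_channel(track.channel)
    tie_tol = settings.tie_tol_frac * threshold
    width = (settings.median_width_lip if track.channel == LIP
             else settings.median_width_acoustic)

    raw = track.values
    v = _filtered(raw, width)
    sign = 1.0 if direction == "decrease" else -1.0
    s = sign * v  # now always looking for departures below a running maximum

    dt = track.dt
    events = []
    ext_val = None          # tracked extremum (None: unarmed, e.g. after NaN)
    ext_idx = -1
    rebound_ref = None      # not None: refractory after an emission
    last_emit_t = -np.inf
    for i in range(s.size):
        if not np.isfinite(s[i]):
            ext_val = None
            rebound_ref = None
            continue
        if rebound_ref is not None:
            # Refractory: a single monotone gesture must fire once.  Re-arm
            # only after the signal rebounds a full threshold above its
            # post-event minimum (the opposite-phase gesture has begun).
            rebound_ref = min(rebound_ref, s[i])
            if s[i] >= rebound_ref + threshold:
                ext_val, ext_idx = s[i], i
                rebound_ref = None
            continue
        if ext_val is None:
            ext_val, ext_idx = s[i], i
            continue
        if s[i] >= ext_val - tie_tol:
            # Still on the extremum plateau (within the flatness tolerance):
            # follow the local level so slow drifts and noise peaks do not
            # freeze the tracker, and keep the latest plateau time.
            ext_val, ext_idx = s[i], i
        elif s[i] <= ext_val - threshold:
            # Confirm a genuine gesture: the departure must deepen to
            # confirm_mult x threshold below the extremum (real closing and
            # opening gestures travel far past the detection threshold;
            # noise excursions do not).  An undefined sample also confirms:
            # the signal left the plateau into silence.
            conf_level = ext_val - settings.confirm_mult * threshold
            confirmed = False
            for q in range(i, min(s.size, i + settings.confirm_window)):
                if not np.isfinite(s[q]) or s[q] <= conf_level:
                    confirmed = True  # deepened (or vanished into silence)
                    break
                if s[q] > ext_val - threshold:
                    break  # excursion recovered above threshold: noise dip
            if not confirmed:
                ext_val, ext_idx = s[i], i  # re-seat on the dip and move on
                continue
            anchor, level, spread = _plateau_anchor(s, i, tie_tol, settings,
                                                    ext_idx)
            t = track.t0_s + anchor * dt
            if interpolate and level is not None:
                boundary = anchor == 0 or not np.isfinite(s[anchor - 1])
                t = _refine_onset_time(raw, anchor, sign * level, dt,
                                       track.t0_s, direction, tie_tol,
                                       spread, boundary,
                                       track.channel == LIP)
            if t - last_emit_t >= settings.min_gap_s:
                events.append((t, float(raw[anchor])))
                last_emit_t = t
            rebound_ref = s[i]
        # else: in the hysteresis band below the extremum — hold state.
    return events


def label_token(tracks: dict, thresholds: DetectionThresholds, mode: str,
                interpolate: bool = True,
                settings: DetectorSettings | None = None,
                token_id: str = "", consonant: str = "") -> list:
    """Detect the (up to six) onset events of one syllable episode.

    Runs the scan per channel and direction and pairs the first closing onset
    with the first subsequent opening onset on each channel.  In isolated
    mode the pre-burst span is silent, so no audible closing event exists:
    decrease-onsets on acoustic channels are never emitted (a detector that
    fabricated one would be reporting an artefact).
    """
    if mode not in ("isolated", "chained"):
        raise ValueError("mode must be 'isolated' or 'chained'")
    labels = []
    for kind in ("CVL", "OVL", "CAI", "OAI", "CAF", "OAF"):
        channel, phase, direction = EVENT_TABLE[kind]
        if mode == "isolated" and phase == "closing" and channel != LIP:
            continue
        if channel not in tracks:
            continue
        onsets = detect_onsets(tracks[channel], thresholds, direction,
                               interpolate=interpolate, settings=settings)
        if not onsets:
            logger.warning("token %s: no %s event detected", token_id, kind)
            continue
        if phase == "closing":
            t = onsets[0][0]
        else:
            # first opening onset after the channel's closing onset (if any)
            t_close = None
            if mode == "chained" or channel == LIP:
                closing = detect_onsets(tracks[channel], thresholds,
                                        "decrease", interpolate=interpolate,
                                        settings=settings)
                t_close = closing[0][0] if closing else None
            later = [o for o in onsets if t_close is None or o[0] > t_close]
            if not later:
                logger.warning("token %s: no %s after closing", token_id, kind)
                continue
            t = later[0][0]
        labels.append(EventLabel(kind=kind, time_s=float(t), channel=channel,
                                 phase=phase, direction=direction,
                                 token_id=token_id, consonant=consonant,
                                 mode=mode))
    return labels


def label_corpus(tokens, thresholds: DetectionThresholds | None = None,
                 interpolate: bool = True,
                 settings: DetectorSettings | None = None) -> list:
    """:func:`label_token` over a token list; returns a flat label list."""
    thresholds = thresholds or DetectionThresholds()
    labels = []
    for tok in tokens:
        labels.extend(label_token(tok.tracks, thresholds, tok.spec.mode,
                                  interpolate=interpolate, settings=settings,
                                  token_id=tok.token_id,
                                  consonant=tok.spec.consonant))
    return labels


def _pair_episodes(onsets_close, onsets_open):
    """Pair the i-th closing onset with the first opening onset after it."""
    pairs = []
    j = 0
    for t_close, _ in onsets_close:
        while j < len(onsets_open) and onsets_open[j][0] <= t_close:
            j += 1
        if j >= len(onsets_open):
            pairs.append((t_close, None))
        else:
            pairs.append((t_close, onsets_open[j][0]))
            j += 1
    return pairs


def segment_chained_sequence(tracks: dict, thresholds: DetectionThresholds,
                             interpolate: bool = True,
                             settings: DetectorSettings | None = None) -> list:
    """Split a concatenated chained utterance into per-consonant episodes.

    Per channel, alternating closing/opening onsets are paired into episodes;
    episodes across channels are then aligned to the lip episodes by temporal
    overlap of their [closing, opening] intervals.  Returns a list of dicts
    ``{kind: time_s}`` with up to six events each, in time order.
    """
    per_channel = {}
    for channel in (LIP, INTENSITY, F1):
        if channel not in tracks:
            continue
        closing = detect_onsets(tracks[channel], thresholds, "decrease",
                                interpolate=interpolate, settings=settings)
        opening = detect_onsets(tracks[channel], thresholds, "increase",
                                interpolate=interpolate, settings=settings)
        per_channel[channel] = _pair_episodes(closing, opening)

    lip_eps = per_channel.get(LIP, [])
    counts = {ch: len(eps) for ch, eps in per_channel.items()}
    if len(set(counts.values())) > 1:
        logger.warning("episode counts disagree across channels: %s; "
                       "aligning by interval overlap", counts)

    kind_for = {(LIP, 0): "CVL", (LIP, 1): "OVL",
                (INTENSITY, 0): "CAI", (INTENSITY, 1): "OAI",
                (F1, 0): "CAF", (F1, 1): "OAF"}
    episodes = []
    for t_close, t_open in lip_eps:
        ep = {"CVL": t_close}
        if t_open is not None:
            ep["OVL"] = t_open
        hi = t_open if t_open is not None else t_close + 0.5
        for channel in (INTENSITY, F1):
            best, best_overlap = None, 0.0
            for c2, o2 in per_channel.get(channel, []):
                o2_eff = o2 if o2 is not None else c2 + 0.5
                overlap = min(hi, o2_eff) - max(t_close, c2)
                if overlap > best_overlap:
                    best, best_overlap = (c2, o2), overlap
            if best is not None:
                ep[kind_for[(channel, 0)]] = best[0]
                if best[1] is not None:
                    ep[kind_for[(channel, 1)]] = best[1]
        episodes.append(ep)
    return episodes
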