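"""Onset detection: frozen examples, brute-force oracle equivalence,
parameter recovery, and detector invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from avsync.events import (DetectionThresholds, DetectorSettings, EventLabel,
                           detect_onsets, label_token,
                           segment_chained_sequence)
from avsync.synth import (NoiseSpec, SyllableSpec, generate_chained_sequence,
                          generate_token, make_default_calibration)
from avsync.tracks import F1, INTENSITY, LIP, TrajectoryTrack


def brute_force_onsets(track, thresholds, direction,
                       settings=None):
    """Clean-room reference for the hysteresis scan (no sub-sample
    refinement): re-derives the tracker state sample by sample from the
    documented semantics, checking every sample as candidate extremum."""
    settings = settings or DetectorSettings()
    theta = thresholds.for_channel(track.channel)
    tol = settings.tie_tol_frac * theta
    width = (settings.median_width_lip if track.channel == LIP
             else settings.median_width_acoustic)

    # median prefilter per defined segment
    values = track.values.copy()
    defined = np.isfinite(values)
    segments = []
    start = None
    for i, d in enumerate(defined):
        if d and start is None:
            start = i
        elif not d and start is not None:
            segments.append((start, i))
            start = None
    if start is not None:
        segments.append((start, values.size))
    if width > 1:
        from scipy.ndimage import median_filter

        for a, b in segments:
            values[a:b] = median_filter(values[a:b], size=width,
                                        mode="nearest")
    sgn = 1.0 if direction == "decrease" else -1.0
    s = sgn * values

    def plateau_anchor(j, fallback):
        lo = max(0, j - settings.plateau_window)
        window = s[lo:j][np.isfinite(s[lo:j])]
        if window.size == 0:
            return fallback
        level = np.median(window)
        candidates = [k for k in range(max(0, j - settings.max_walk_back), j)
                      if np.isfinite(s[k]) and s[k] >= level - tol
                      and np.all(np.isfinite(s[k:j]))]
        return candidates[-1] if candidates else fallback

    events = []
    last_emit = -np.inf
    for a, b in segments:
        state = "armed"
        ext_val, ext_idx = s[a], a
        rebound = None
        for i in range(a + 1, b):
            if state == "refractory":
                rebound = min(rebound, s[i])
                if s[i] >= rebound + theta:
                    state, ext_val, ext_idx = "armed", s[i], i
                continue
            if s[i] >= ext_val - tol:
                ext_val, ext_idx = s[i], i
            elif s[i] <= ext_val - theta:
                confirmed = False
                for q in range(i, min(s.size, i + settings.confirm_window)):
                    if not np.isfinite(s[q]):
                        confirmed = True  # departure ran into a NaN gap
                        break
                    if s[q] <= ext_val - settings.confirm_mult * theta:
                        confirmed = True
                        break
                    if s[q] > ext_val - theta:
                        break
                if not confirmed:
                    ext_val, ext_idx = s[i], i
                    continue
                anchor = plateau_anchor(i, ext_idx)
                t = track.t0_s + anchor * track.dt
                if t - last_emit >= settings.min_gap_s:
                    events.append(t)
                    last_emit = t
                state, rebound = "refractory", s[i]
    return events


def piecewise_linear_track(rng, channel=INTENSITY, rate=100.0):
    n_knots = rng.integers(3, 8)
    knot_t = np.sort(rng.uniform(0, 1.2, n_knots))
    knot_t = np.concatenate([[0.0], knot_t, [1.4]])
    knot_v = rng.uniform(30, 70, knot_t.size)
    t = np.arange(0, 1.4, 1.0 / rate)
    return TrajectoryTrack(channel, rate, 0.0,
                           np.interp(t, knot_t, knot_v))


class TestDetectOnsets:
    def test_constant_track_yields_nothing(self, thresholds):
        tr = TrajectoryTrack(INTENSITY, 100.0, 0.0, np.full(200, 70.0))
        assert detect_onsets(tr, thresholds, "decrease") == []
        assert detect_onsets(tr, thresholds, "increase") == []

    def test_ramp_onset_detected_at_extremum(self, thresholds):
        """70 dB plateau then a -100 dB/s ramp from t=0.300 s: the event is
        timed at the beginning of the decrease, not the 1 dB crossing."""
        t = np.arange(0, 1.0, 0.01)
        v = np.where(t < 0.300, 70.0, 70.0 - 100.0 * (t - 0.300))
        tr = TrajectoryTrack(INTENSITY, 100.0, 0.0, v)
        onsets = detect_onsets(tr, thresholds, "decrease", interpolate=False)
        assert len(onsets) == 1
        assert onsets[0][0] == pytest.approx(0.300, abs=1e-9)
        assert onsets[0][1] == pytest.approx(70.0)

    def test_short_track_rejected(self, thresholds):
        tr = TrajectoryTrack(LIP, 50.0, 0.0, np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            detect_onsets(tr, thresholds, "decrease")

    def test_unknown_direction_rejected(self, thresholds):
        tr = TrajectoryTrack(LIP, 50.0, 0.0, np.full(10, 1.0))
        with pytest.raises(ValueError):
            detect_onsets(tr, thresholds, "sideways")

    def test_lip_interpolation_beats_sample_grid(self, thresholds):
        """Raised-cosine lip closures with random onset phase relative to
        the 50 Hz grid: interpolated onsets land within 10 ms of truth,
        uninterpolated within 20 ms (one sample)."""
        rng = np.random.default_rng(12)
        err_interp, err_raw = [], []
        for _ in range(60):
            onset = 0.3 + rng.uniform(0, 0.02)
            t = np.arange(0, 1.0, 0.02)
            v = np.where(
                t < onset, 1.5,
                np.where(t < onset + 0.15,
                         1.5 * 0.5 * (1 + np.cos(np.pi * (t - onset) / 0.15)),
                         0.0))
            tr = TrajectoryTrack(LIP, 50.0, 0.0, v)
            for flag, acc in ((True, err_interp), (False, err_raw)):
                onsets = detect_onsets(tr, thresholds, "decrease",
                                       interpolate=flag)
                assert len(onsets) == 1
                acc.append(abs(onsets[0][0] - onset) * 1000)
        assert np.median(err_interp) <= 10.0
        assert np.median(err_raw) <= 20.0
        assert np.median(err_interp) < np.median(err_raw)

    def test_matches_brute_force_on_random_piecewise_linear(self, thresholds):
        rng = np.random.default_rng(99)
        for _ in range(200):
            tr = piecewise_linear_track(rng)
            for direction in ("decrease", "increase"):
                fast = [t for t, _ in detect_onsets(tr, thresholds, direction,
                                                    interpolate=False)]
                slow = brute_force_onsets(tr, thresholds, direction)
                assert fast == pytest.approx(slow)

    def test_raising_threshold_never_adds_events(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            tr = piecewise_linear_track(rng)
            counts = []
            for delta in (0.5, 1.0, 2.0, 4.0):
                th = DetectionThresholds(intensity_delta_db=delta)
                counts.append(len(detect_onsets(tr, th, "decrease")))
            assert counts == sorted(counts, reverse=True)

    def test_nan_spans_break_extremum_runs(self, thresholds):
        v = np.concatenate([np.full(50, 700.0), np.full(30, np.nan),
                            np.full(5, 250.0),
                            250 + 450 * np.linspace(0, 1, 20) ** 2,
                            np.full(20, 700.0)])
        tr = TrajectoryTrack(F1, 100.0, 0.0, v)
        dec = detect_onsets(tr, thresholds, "decrease")
        assert dec == []  # the fall is hidden inside the NaN gap
        inc = detect_onsets(tr, thresholds, "increase")
        assert len(inc) == 1
        # the onset lies within the defined post-gap rise, never inside or
        # before the NaN span
        assert 0.84 <= inc[0][0] <= 0.98


class TestLabelToken:
    def test_chained_token_recovers_all_six_events(self, calib_nojitter,
                                                   thresholds):
        tok = generate_token(SyllableSpec("p", "chained"), calib_nojitter,
                             NoiseSpec.zero(), seed=0)
        labels = label_token(tok.tracks, thresholds, "chained")
        assert sorted(l.kind for l in labels) == sorted(
            ["CVL", "OVL", "CAI", "OAI", "CAF", "OAF"])
        for lab in labels:
            err = abs(lab.time_s - tok.truth_events[lab.kind]) * 1000
            assert err <= 5.0, (lab.kind, err)

    def test_isolated_token_yields_exactly_four_events(self, calib_nojitter,
                                                       thresholds):
        tok = generate_token(SyllableSpec("p", "isolated"), calib_nojitter,
                             NoiseSpec.zero(), seed=0)
        labels = label_token(tok.tracks, thresholds, "isolated")
        assert sorted(l.kind for l in labels) == ["CVL", "OAF", "OAI", "OVL"]

    def test_velar_audio_leads_at_release(self, calib_nojitter, thresholds):
        tok = generate_token(SyllableSpec("k", "chained"), calib_nojitter,
                             NoiseSpec.zero(), seed=0)
        times = {l.kind: l.time_s for l in
                 label_token(tok.tracks, thresholds, "chained")}
        assert times["OAI"] < times["OVL"]

    def test_isolated_mode_never_fabricates_acoustic_closing(
            self, isolated_labels_50):
        assert not any(l.kind in ("CAI", "CAF") for l in isolated_labels_50)

    def test_event_label_kind_channel_consistency(self):
        with pytest.raises(ValueError):
            EventLabel(kind="CVL", time_s=0.1, channel=INTENSITY,
                       phase="closing", direction="decrease")

    def test_noisy_recovery_median_errors(self, chained_corpus_50,
                                          thresholds):
        """Median |detected - truth| stays within 5 ms on acoustic events
        and 10 ms on 50 Hz lip events over the noisy corpus."""
        errors = {LIP: [], INTENSITY: [], F1: []}
        for tok in chained_corpus_50:
            for lab in label_token(tok.tracks, thresholds, "chained"):
                err = abs(lab.time_s - tok.truth_events[lab.kind]) * 1000
                errors[lab.channel].append(err)
        assert np.median(errors[INTENSITY]) <= 5.0
        assert np.median(errors[F1]) <= 5.0
        assert np.median(errors[LIP]) <= 10.0


class TestSegmentChainedSequence:
    def test_eight_syllable_sequence_yields_eight_sextuples(
            self, calib_nojitter, thresholds):
        tracks, truth = generate_chained_sequence(calib_nojitter,
                                                  NoiseSpec.zero(), seed=2)
        episodes = segment_chained_sequence(tracks, thresholds)
        assert len(episodes) == 8
        for det, tru in zip(episodes, truth):
            assert len(det) == 6
            for kind, t_det in det.items():
                assert abs(t_det - tru["events"][kind]) * 1000 <= 5.0

    def test_episode_alignment_lip_vs_intensity(self, calib, thresholds):
        tracks, _ = generate_chained_sequence(calib, NoiseSpec(), seed=8)
        episodes = segment_chained_sequence(tracks, thresholds)
        for ep in episodes:
            if "CVL" in ep and "CAI" in ep:
                assert abs(ep["CVL"] - ep["CAI"]) * 1000 <= 100.0

    def test_silence_only_tracks_yield_no_episodes(self, thresholds):
        tracks = {
            LIP: TrajectoryTrack(LIP, 50.0, 0.0, np.full(100, 1.5)),
            INTENSITY: TrajectoryTrack(INTENSITY, 100.0, 0.0,
                                       np.full(200, 30.0)),
            F1: TrajectoryTrack(F1, 100.0, 0.0, np.full(200, np.nan)),
        }
        assert segment_chained_sequence(tracks, thresholds) == []
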