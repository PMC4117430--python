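"""Synthetic articulatory-acoustic corpus of plosive-vowel syllables.

The generator emulates a small audiovisual recording corpus: 8 consonants
/p t k b d g m n/ in the open-vowel context /a/, produced either in isolation
(/Ca/ embedded in silence) or chained (/aCa/, no silence).  Each token bundles
a 50 Hz lip-height track with 100 Hz acoustic tracks (intensity in dB, F1-F3
in Hz) plus the ground-truth times of the six onset events

    CVL/OVL  closing/opening onset of the visible lips,
    CAI/OAI  closing/opening onset of the acoustic intensity,
    CAF/OAF  closing/opening onset of the first formant,

so that event detection and asynchrony estimation can be validated by
parameter recovery.  Audio-visual timing offsets are injected per consonant
from a :class:`TimingCalibration` whose defaults encode the empirically
observed pattern: the visible closing gesture leads the acoustic consequences
by ~35 ms (intensity) / ~60 ms (formants); at the release the two streams are
near-synchronous for labials while velars show a >20 ms audio lead (the
tongue-back release precedes any visible lip event); in isolated syllables
the silent preparatory closure puts the first visible event 200-400 ms before
the first audible one.

Gesture kinematics use raised-cosine (half-cosine) interpolation between
articulatory targets: smooth, velocity-peaked mid-gesture, flat at both ends,
which is a standard minimal model of lip and tongue transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .tracks import DEFAULT_RATES, F1, F2, F3, INTENSITY, LIP, TrajectoryTrack

CONSONANTS = ("p", "t", "k", "b", "d", "g", "m", "n")
LABIALS = ("p", "b", "m")
DENTALS = ("t", "d", "n")
VELARS = ("k", "g")
VOICELESS = ("p", "t", "k")
NASALS = ("m", "n")

#: The six onset event kinds.
EVENT_KINDS = ("CVL", "OVL", "CAI", "OAI", "CAF", "OAF")
#: Events that exist for an isolated token (no audible closing in silence).
ISOLATED_EVENT_KINDS = ("CVL", "OVL", "OAI", "OAF")

MODES = ("isolated", "chained")

# Articulatory / acoustic targets (implementation constants).
VOWEL_LIP_CM = 1.5          # open /a/ lip height
VOWEL_INTENSITY_DB = 70.0
SILENCE_DB = 30.0           # also the closure floor for voiceless plosives
PREVOICING_DB = 45.0        # voiced-plosive closure murmur
NASAL_MURMUR_DB = 55.0
VOWEL_F1_HZ = 700.0
CLOSURE_F1_HZ = 250.0
VOWEL_F2_HZ = 1300.0
VOWEL_F3_HZ = 2500.0
#: Formants are undefined wherever (noiseless) intensity is below this level.
VOICING_FLOOR_DB = 40.0

#: Consonant locus targets in the F2-F3 plane (Hz).  Classical locus-theory
#: geometry: the labial locus pulls both formants down, the dental locus pulls
#: F2 up, the velar locus shows the F2-F3 "pinch".  Early in the transition
#: all three classes sit near the vowel values, so audio alone is ambiguous.
F2_LOCUS = {"p": 1100.0, "b": 1100.0, "m": 1100.0,
            "t": 1700.0, "d": 1700.0, "n": 1700.0,
            "k": 1900.0, "g": 1900.0}
F3_LOCUS = {"p": 2300.0, "b": 2300.0, "m": 2300.0,
            "t": 2600.0, "d": 2600.0, "n": 2600.0,
            "k": 2100.0, "g": 2100.0}

#: Residual lip height at closure: full closure for labials, residual opening
#: for lingual constrictions (the lips never seal for /t d n k g/).
CLOSURE_LIP_CM = {c: 0.0 if c in LABIALS else 0.8 for c in CONSONANTS}

CLOSURE_DB = {**{c: SILENCE_DB for c in VOICELESS},
              **{c: PREVOICING_DB for c in ("b", "d", "g")},
              **{c: NASAL_MURMUR_DB for c in NASALS}}

# Segment durations (s) of the acoustic parameter transitions.
INTENSITY_FALL_S = 0.080
INTENSITY_RISE_S = 0.020   # burst: near-instantaneous
F1_TRANSITION_S = 0.060
F2F3_TRANSITION_S = 0.150  # slow place transition; defines the closure point

#: Base time of the lip closing onset inside a token (s); chosen on both the
#: 50 Hz and 100 Hz sample grids.
CHAINED_CVL_S = 0.24


def _as_cons_map(values) -> dict:
    out = dict(zip(CONSONANTS, np.asarray(values, dtype=float)))
    if len(out) != 8:
        raise ValueError("need one value per consonant")
    return out


@dataclass
class SyllableSpec:
    """Specification of one /Ca/ or /aCa/ token."""

    consonant: str
    mode: str = "chained"
    vowel: str = "a"
    syllable_period_s: float = 0.8
    silence_s: float = 0.5
    repetition_index: int = 1

    def __post_init__(self) -> None:
        if self.consonant not in CONSONANTS:
            raise ValueError(f"consonant must be one of {CONSONANTS}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.syllable_period_s <= 0:
            raise ValueError("syllable_period_s must be > 0")
        if self.silence_s < 0:
            raise ValueError("silence_s must be >= 0")
        if self.repetition_index < 1:
            raise ValueError("repetition_index must be >= 1")


@dataclass
class TimingCalibration:
    """Per-consonant audio-visual timing offsets and gesture durations (ms).

    Offsets are signed event-time differences: ``closing_intensity_offset_ms``
    is CAI − CVL (positive: the audible intensity decrease lags the visible
    lip closing), ``opening_intensity_offset_ms`` is OAI − OVL (negative:
    audio leads at the release, as for velars), and analogously for formants.
    ``isolated_lead_ms`` (OAI − CVL in isolated mode) is not free: it equals
    closing + hold duration by construction.
    """

    closing_intensity_offset_ms: dict
    closing_formant_offset_ms: dict
    opening_intensity_offset_ms: dict
    opening_formant_offset_ms: dict
    isolated_lead_ms: dict
    closing_duration_ms: dict
    opening_duration_ms: dict
    offset_jitter_sd_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.offset_jitter_sd_ms < 0:
            raise ValueError("offset_jitter_sd_ms must be >= 0")
        for c in CONSONANTS:
            if self.closing_duration_ms[c] <= 0 or self.opening_duration_ms[c] <= 0:
                raise ValueError("durations must be > 0")
            if self.hold_duration_ms(c) <= 0:
                raise ValueError(
                    "isolated_lead_ms must exceed closing_duration_ms")

    def hold_duration_ms(self, consonant: str) -> float:
        """Closure hold duration; isolated_lead = closing + hold."""
        return (self.isolated_lead_ms[consonant]
                - self.closing_duration_ms[consonant])


def make_default_calibration(offset_jitter_sd_ms: float = 5.0) -> TimingCalibration:
    """Default per-consonant timing table.

    The table realises the empirically reported pattern: closing intensity
    offsets in [20, 40] ms with an (unweighted) mean of 35 ms; closing formant
    offsets in [40, 80] ms with mean 60 ms; release near-synchronous for
    labials, slightly audio-lagged for dentals, audio-leading by 22-25 ms for
    velars; opening formant offsets with mean below 10 ms; isolated leads in
    [200, 400] ms.  The per-consonant split within those ranges is a modelling
    choice.
    """
    return TimingCalibration(
        #                              p    t    k    b    d    g    m    n
        closing_intensity_offset_ms=_as_cons_map([40, 35, 25, 40, 30, 30, 40, 40]),
        closing_formant_offset_ms=_as_cons_map([70, 55, 45, 70, 50, 60, 65, 65]),
        opening_intensity_offset_ms=_as_cons_map([0, 5, -22, 0, 5, -25, 0, 5]),
        opening_formant_offset_ms=_as_cons_map([8, 10, 0, 8, 10, 0, 8, 10]),
        isolated_lead_ms=_as_cons_map([350, 280, 240, 330, 260, 250, 360, 300]),
        closing_duration_ms=_as_cons_map([150] * 8),
        opening_duration_ms=_as_cons_map([120] * 8),
        offset_jitter_sd_ms=offset_jitter_sd_ms,
    )


@dataclass
class NoiseSpec:
    """Additive white Gaussian measurement noise, one SD per channel.

    Defaults sit well below the detection thresholds (0.15 cm / 1 dB / 60 Hz)
    so that event recovery is possible, while the 5 ms timing jitter of the
    calibration reproduces nonzero between-repetition variability.
    """

    lip_sd_cm: float = 0.01
    intensity_sd_db: float = 0.3
    formant_sd_hz: float = 10.0

    def __post_init__(self) -> None:
        if min(self.lip_sd_cm, self.intensity_sd_db, self.formant_sd_hz) < 0:
            raise ValueError("noise SDs must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0)


@dataclass
class SyllableToken:
    """One generated syllable episode with ground truth."""

    spec: SyllableSpec
    tracks: dict = field(repr=False)
    truth_events: dict
    injected_offsets_ms: dict
    seed: int
    closure_time_s: float | None = None
    token_id: str = ""

    def track(self, channel: str) -> TrajectoryTrack:
        return self.tracks[channel]


def _raised_cosine(t, t_on, duration, start, end):
    """Half-cosine interpolation from ``start`` to ``end`` over the gesture."""
    x = np.clip((t - t_on) / duration, 0.0, 1.0)
    return start + (end - start) * 0.5 * (1.0 - np.cos(np.pi * x))


def _clamp_same_sign(value: float, nominal: float) -> float:
    """Truncate a jittered offset so the sign of the nominal offset survives."""
    if nominal > 0:
        return max(value, 0.5)
    if nominal < 0:
        return min(value, -0.5)
    return value


def _jittered_offsets(consonant: str, calib: TimingCalibration,
                      rng: np.random.Generator) -> dict:
    sd = calib.offset_jitter_sd_ms
    names = {
        "closing_intensity_offset_ms": calib.closing_intensity_offset_ms,
        "closing_formant_offset_ms": calib.closing_formant_offset_ms,
        "opening_intensity_offset_ms": calib.opening_intensity_offset_ms,
        "opening_formant_offset_ms": calib.opening_formant_offset_ms,
        "isolated_lead_ms": calib.isolated_lead_ms,
    }
    out = {}
    for name, table in names.items():
        nominal = table[consonant]
        out[name] = _clamp_same_sign(nominal + rng.normal(0.0, sd), nominal)
    return out


def generate_token(spec: SyllableSpec, calib: TimingCalibration,
                   noise: NoiseSpec, seed: int) -> SyllableToken:
    """Generate one syllable token; deterministic given ``seed``.

    Chained tokens run /a C a/: an initial vowel plateau, the closing gesture
    starting at CVL, a closure hold, the opening gesture starting at OVL, and
    a final vowel.  Isolated tokens replace the initial vowel by silence
    (intensity at the silence floor, formants undefined), so no audible
    closing event exists.  Truth events are recorded exactly at the
    parameter-level change onsets.
    """
    rng = np.random.default_rng(seed)
    c = spec.consonant
    off = _jittered_offsets(c, calib, rng)

    closing_s = calib.closing_duration_ms[c] / 1000.0
    opening_s = calib.opening_duration_ms[c] / 1000.0
    lead_s = off["isolated_lead_ms"] / 1000.0
    if spec.mode == "isolated":
        t_cvl = spec.silence_s
    else:
        t_cvl = CHAINED_CVL_S
    t_ovl = t_cvl + lead_s                      # lead = closing + hold
    t_oai = t_ovl + off["opening_intensity_offset_ms"] / 1000.0
    t_oaf = t_ovl + off["opening_formant_offset_ms"] / 1000.0

    truth = {"CVL": t_cvl, "OVL": t_ovl, "OAI": t_oai, "OAF": t_oaf}
    closure_time = None
    if spec.mode == "chained":
        truth["CAI"] = t_cvl + off["closing_intensity_offset_ms"] / 1000.0
        truth["CAF"] = t_cvl + off["closing_formant_offset_ms"] / 1000.0
        closure_time = truth["CAF"] + F2F3_TRANSITION_S

    duration = t_ovl + max(opening_s, F2F3_TRANSITION_S) + 0.15
    if spec.mode == "chained":
        duration = max(duration, spec.syllable_period_s)

    # --- lip track (50 Hz) ------------------------------------------------
    t_lip = np.arange(0.0, duration, 0.02)
    lip_lo = CLOSURE_LIP_CM[c]
    lip = np.where(
        t_lip < t_ovl,
        _raised_cosine(t_lip, t_cvl, closing_s, VOWEL_LIP_CM, lip_lo),
        _raised_cosine(t_lip, t_ovl, opening_s, lip_lo, VOWEL_LIP_CM),
    )

    # --- acoustic tracks (100 Hz) ----------------------------------------
    t_ac = np.arange(0.0, duration, 0.01)
    floor = CLOSURE_DB[c]
    if spec.mode == "chained":
        inten = np.where(
            t_ac < t_oai,
            _raised_cosine(t_ac, truth["CAI"], INTENSITY_FALL_S,
                           VOWEL_INTENSITY_DB, floor),
            _raised_cosine(t_ac, t_oai, INTENSITY_RISE_S,
                           floor, VOWEL_INTENSITY_DB),
        )
        f1 = np.where(
            t_ac < t_oaf,
            _raised_cosine(t_ac, truth["CAF"], F1_TRANSITION_S,
                           VOWEL_F1_HZ, CLOSURE_F1_HZ),
            _raised_cosine(t_ac, t_oaf, F1_TRANSITION_S,
                           CLOSURE_F1_HZ, VOWEL_F1_HZ),
        )
        f2 = np.where(
            t_ac < t_oaf,
            _raised_cosine(t_ac, truth["CAF"], F2F3_TRANSITION_S,
                           VOWEL_F2_HZ, F2_LOCUS[c]),
            _raised_cosine(t_ac, t_oaf, F2F3_TRANSITION_S,
                           F2_LOCUS[c], VOWEL_F2_HZ),
        )
        f3 = np.where(
            t_ac < t_oaf,
            _raised_cosine(t_ac, truth["CAF"], F2F3_TRANSITION_S,
                           VOWEL_F3_HZ, F3_LOCUS[c]),
            _raised_cosine(t_ac, t_oaf, F2F3_TRANSITION_S,
                           F3_LOCUS[c], VOWEL_F3_HZ),
        )
    else:
        # Silence before the burst; the syllable opens straight into /a/.
        inten = np.where(
            t_ac < t_oai,
            SILENCE_DB,
            _raised_cosine(t_ac, t_oai, INTENSITY_RISE_S,
                           SILENCE_DB, VOWEL_INTENSITY_DB),
        )
        f1 = _raised_cosine(t_ac, t_oaf, F1_TRANSITION_S,
                            CLOSURE_F1_HZ, VOWEL_F1_HZ)
        f2 = _raised_cosine(t_ac, t_oaf, F2F3_TRANSITION_S,
                            F2_LOCUS[c], VOWEL_F2_HZ)
        f3 = _raised_cosine(t_ac, t_oaf, F2F3_TRANSITION_S,
                            F3_LOCUS[c], VOWEL_F3_HZ)

    # Formants do not exist without voicing/resonance: undefined wherever the
    # noiseless intensity is below the voicing floor.
    silent = inten < VOICING_FLOOR_DB
    for f in (f1, f2, f3):
        f[silent] = np.nan

    # --- additive measurement noise ---------------------------------------
    lip = np.maximum(lip + rng.normal(0.0, noise.lip_sd_cm, lip.size), 0.0)
    inten = inten + rng.normal(0.0, noise.intensity_sd_db, inten.size)
    f1 = f1 + rng.normal(0.0, noise.formant_sd_hz, f1.size)
    f2 = f2 + rng.normal(0.0, noise.formant_sd_hz, f2.size)
    f3 = f3 + rng.normal(0.0, noise.formant_sd_hz, f3.size)

    tracks = {
        LIP: TrajectoryTrack(LIP, 50.0, 0.0, lip),
        INTENSITY: TrajectoryTrack(INTENSITY, 100.0, 0.0, inten),
        F1: TrajectoryTrack(F1, 100.0, 0.0, f1),
        F2: TrajectoryTrack(F2, 100.0, 0.0, f2),
        F3: TrajectoryTrack(F3, 100.0, 0.0, f3),
    }
    token_id = f"{spec.mode}-{c}a-r{spec.repetition_index:03d}"
    return SyllableToken(spec=spec, tracks=tracks, truth_events=truth,
                         injected_offsets_ms=off, seed=int(seed),
                         closure_time_s=closure_time, token_id=token_id)


def _token_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] & 0x7FFFFFFF)
            for child in ss.spawn(n)]


def generate_corpus(calib: TimingCalibration, noise: NoiseSpec,
                    n_repetitions: int, modes=("isolated", "chained"),
                    seed: int = 0, consonants=CONSONANTS) -> list:
    """Generate ``n_repetitions`` of each syllable in each mode.

    Tokens appear in fixed order /pa ta ka ba da ga ma na/ within each
    repetition; per-token offsets are jittered around the calibration table
    (truncated so offset signs are preserved).
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    modes = tuple(modes)
    for m in modes:
        if m not in MODES:
            raise ValueError(f"unknown mode {m!r}")
    seeds = iter(_token_seeds(seed, len(modes) * n_repetitions * len(consonants)))
    tokens = []
    for mode in modes:
        for rep in range(1, n_repetitions + 1):
            for c in consonants:
                spec = SyllableSpec(consonant=c, mode=mode,
                                    repetition_index=rep)
                tokens.append(generate_token(spec, calib, noise, next(seeds)))
    return tokens


def generate_chained_sequence(calib: TimingCalibration, noise: NoiseSpec,
                              seed: int = 0, consonants=CONSONANTS,
                              syllable_period_s: float = 0.8):
    """One concatenated multi-syllable utterance /aC1aC2a.../.

    Returns ``(tracks, episodes)`` where ``episodes`` is a list of per-
    consonant truth-event dicts with absolute times in the concatenated
    utterance.  Episodes are built from chained tokens laid end to end on a
    common vowel plateau, one syllable period apart.
    """
    seeds = _token_seeds(seed, len(consonants))
    episodes = []
    parts = {ch: [] for ch in (LIP, INTENSITY, F1, F2, F3)}
    for i, c in enumerate(consonants):
        spec = SyllableSpec(consonant=c, mode="chained", repetition_index=1,
                            syllable_period_s=syllable_period_s)
        tok = generate_token(spec, calib, noise, seeds[i])
        offset = i * syllable_period_s
        episodes.append({
            "consonant": c,
            "events": {k: t + offset for k, t in tok.truth_events.items()},
        })
        for ch, tr in tok.tracks.items():
            n_keep = int(round(syllable_period_s * tr.sample_rate_hz))
            parts[ch].append(tr.values[:n_keep])
    tracks = {
        ch: TrajectoryTrack(ch, DEFAULT_RATES[ch], 0.0, np.concatenate(v))
        for ch, v in parts.items()
    }
    return tracks, episodes
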