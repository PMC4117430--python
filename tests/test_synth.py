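"""Synthetic corpus generator: calibration constraints, determinism,
injected-offset bookkeeping, and track invariants."""

import numpy as np
import pytest

from avsync.synth import (CONSONANTS, ISOLATED_EVENT_KINDS, NoiseSpec,
                          SyllableSpec, TimingCalibration, VELARS,
                          generate_corpus, generate_token,
                          make_default_calibration)
from avsync.tracks import F1, F2, F3, INTENSITY, LIP


class TestDefaultCalibration:
    def test_closing_offset_means_match_reported_values(self, calib):
        ci = np.array(list(calib.closing_intensity_offset_ms.values()))
        cf = np.array(list(calib.closing_formant_offset_ms.values()))
        assert ci.mean() == pytest.approx(35.0)
        assert cf.mean() == pytest.approx(60.0)
        assert np.all((ci >= 20) & (ci <= 40))
        assert np.all((cf >= 40) & (cf <= 80))

    def test_velar_audio_lead_reaches_20ms(self, calib):
        lead = min(-calib.opening_intensity_offset_ms[c] for c in VELARS)
        assert lead >= 20

    def test_opening_formant_mean_below_10ms(self, calib):
        of = np.array(list(calib.opening_formant_offset_ms.values()))
        assert of.mean() < 10

    def test_isolated_leads_inside_printed_range(self, calib):
        leads = np.array(list(calib.isolated_lead_ms.values()))
        assert np.all((leads >= 200) & (leads <= 400))

    def test_isolated_lead_equals_closing_plus_hold(self, calib):
        for c in CONSONANTS:
            assert calib.isolated_lead_ms[c] == pytest.approx(
                calib.closing_duration_ms[c] + calib.hold_duration_ms(c))

    def test_invalid_durations_rejected(self):
        calib = make_default_calibration()
        calib.closing_duration_ms["p"] = -10
        with pytest.raises(ValueError):
            TimingCalibration(**{f: getattr(calib, f) for f in (
                "closing_intensity_offset_ms", "closing_formant_offset_ms",
                "opening_intensity_offset_ms", "opening_formant_offset_ms",
                "isolated_lead_ms", "closing_duration_ms",
                "opening_duration_ms")})


class TestGenerateToken:
    def test_same_seed_reproduces_tracks_and_events(self, calib):
        spec = SyllableSpec("t", "chained")
        a = generate_token(spec, calib, NoiseSpec(), seed=42)
        b = generate_token(spec, calib, NoiseSpec(), seed=42)
        assert a.truth_events == b.truth_events
        for ch in a.tracks:
            np.testing.assert_array_equal(a.tracks[ch].values,
                                          b.tracks[ch].values)

    @pytest.mark.parametrize("consonant", CONSONANTS)
    def test_injected_closing_offset_is_exact(self, calib_nojitter, consonant):
        tok = generate_token(SyllableSpec(consonant, "chained"),
                             calib_nojitter, NoiseSpec.zero(), seed=0)
        delta = (tok.truth_events["CAI"] - tok.truth_events["CVL"]) * 1000
        assert delta == pytest.approx(
            calib_nojitter.closing_intensity_offset_ms[consonant])

    def test_isolated_lead_forced_by_construction(self, calib_nojitter):
        tok = generate_token(SyllableSpec("p", "isolated"), calib_nojitter,
                             NoiseSpec.zero(), seed=0)
        delta = (tok.truth_events["OAI"] - tok.truth_events["CVL"]) * 1000
        assert delta == pytest.approx(calib_nojitter.isolated_lead_ms["p"])

    def test_isolated_tokens_lack_audible_closing_events(self, calib):
        tok = generate_token(SyllableSpec("d", "isolated"), calib,
                             NoiseSpec(), seed=5)
        assert set(tok.truth_events) == set(ISOLATED_EVENT_KINDS)

    def test_truth_event_ordering(self, calib):
        for c in CONSONANTS:
            tok = generate_token(SyllableSpec(c, "chained"), calib,
                                 NoiseSpec(), seed=9)
            ev = tok.truth_events
            assert ev["CVL"] < ev["OVL"]
            assert ev["CAI"] < ev["OAI"]
            assert ev["CAF"] < ev["OAF"]

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(lip_sd_cm=-0.1)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SyllableSpec("x", "chained")
        with pytest.raises(ValueError):
            SyllableSpec("p", "chained", syllable_period_s=0.0)

    def test_zero_noise_tracks_piecewise_monotone(self, calib_nojitter):
        tok = generate_token(SyllableSpec("p", "chained"), calib_nojitter,
                             NoiseSpec.zero(), seed=0)
        lip = tok.tracks[LIP]
        t = lip.times()
        closing = (t >= tok.truth_events["CVL"]) & (t <= tok.truth_events["OVL"])
        assert np.all(np.diff(lip.values[closing]) <= 1e-12)
        opening = t >= tok.truth_events["OVL"]
        assert np.all(np.diff(lip.values[opening]) >= -1e-12)

    def test_formant_ordering_and_lip_positivity(self, calib):
        tok = generate_token(SyllableSpec("g", "chained"), calib,
                             NoiseSpec(), seed=11)
        f1, f2, f3 = (tok.tracks[ch].values for ch in (F1, F2, F3))
        defined = np.isfinite(f1) & np.isfinite(f2) & np.isfinite(f3)
        assert np.all(f1[defined] < f2[defined])
        assert np.all(f2[defined] < f3[defined])
        assert np.all(tok.tracks[LIP].values >= 0)

    def test_formants_undefined_in_voiceless_closure(self, calib_nojitter):
        tok = generate_token(SyllableSpec("k", "chained"), calib_nojitter,
                             NoiseSpec.zero(), seed=0)
        f1 = tok.tracks[F1]
        mid = 0.5 * (tok.truth_events["CAF"] + tok.truth_events["OAF"])
        i = int(round((mid - f1.t0_s) * f1.sample_rate_hz))
        assert not np.isfinite(f1.values[i])


class TestGenerateCorpus:
    def test_token_count_and_order(self, calib):
        toks = generate_corpus(calib, NoiseSpec(), 6,
                               modes=("isolated", "chained"), seed=1)
        assert len(toks) == 96
        first_rep = [t.spec.consonant for t in toks[:8]]
        assert first_rep == list(CONSONANTS)

    def test_zero_jitter_repetitions_identical(self, calib_nojitter):
        toks = generate_corpus(calib_nojitter, NoiseSpec(), 3,
                               modes=("chained",), seed=2)
        by_cons = {}
        for t in toks:
            by_cons.setdefault(t.spec.consonant, []).append(
                t.injected_offsets_ms)
        for offs in by_cons.values():
            assert all(o == offs[0] for o in offs)

    def test_jittered_offsets_recover_calibration_mean(self, calib):
        toks = generate_corpus(calib, NoiseSpec(), 200, modes=("chained",),
                               seed=6, consonants=("p",))
        vals = [t.injected_offsets_ms["closing_intensity_offset_ms"]
                for t in toks]
        assert np.mean(vals) == pytest.approx(
            calib.closing_intensity_offset_ms["p"], abs=1.0)

    def test_offset_signs_preserved_under_jitter(self):
        calib = make_default_calibration(offset_jitter_sd_ms=30.0)
        toks = generate_corpus(calib, NoiseSpec(), 50, modes=("chained",),
                               seed=7, consonants=("k", "p"))
        for t in toks:
            off = t.injected_offsets_ms["opening_intensity_offset_ms"]
            nominal = calib.opening_intensity_offset_ms[t.spec.consonant]
            if nominal < 0:
                assert off < 0
            elif nominal > 0:
                assert off > 0

    def test_invalid_repetitions_rejected(self, calib):
        with pytest.raises(ValueError):
            generate_corpus(calib, NoiseSpec(), 0)
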