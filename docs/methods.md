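# Methods

This note documents the models, defaults and numerical choices behind
`avsync`, and what its synthetic-data tests do and do not show.

## 1. The measurement problem

For a consonant–vowel syllable, six onset events characterise the
audiovisual timing of the consonantal gesture:

* **CVL / OVL** — closing/opening onset of the visible lips (lip-height
  track, 50 Hz, the video field rate);
* **CAI / OAI** — closing/opening onset of the acoustic intensity (dB,
  100 Hz);
* **CAF / OAF** — closing/opening onset of the first formant F1 (Hz,
  100 Hz; F1 falls toward closure, rises at release).

Two asynchrony measures apply, depending on production context.  For an
isolated /Ca/ the closing gesture is *preparatory* — visible but silent —
so the only defined delay is first-visible to first-audible, CVL−OAI and
CVL−OAF; it is large and negative (visual lead of hundreds of ms) for the
trivial reason that lips must close before they can open.  For a chained
/aCa/ the gesture is *comodulatory* — every phase is both audible and
visible — and asynchrony must be measured within phase: CVL−CAI and
CVL−CAF for closing, OVL−OAI and OVL−OAF for opening.  Applying the
preparatory measure to chained material conflates closure duration with
asynchrony; `avsync` raises `AsynchronyModeError` rather than computing it.
Delays are literal subtractions in ms (negative: acoustic lags visual);
per-consonant statistics are mean ± SD over repetitions, and grand means
weight the 8 consonants equally (pooling tokens instead would let missing
events re-weight consonants).

## 2. Synthetic corpus

No public recording of this corpus design exists, so the package ships a
generator whose *defaults are the study conditions*: 8 consonants
/p t k b d g m n/ in /a/ context, isolated and chained modes, ~800 ms per
syllable, ~500 ms silence between isolated syllables, 6 (or more)
repetitions, lips sampled every 20 ms.

Kinematics: articulatory and acoustic parameters move between targets along
raised-cosine (half-cosine) segments — smooth, velocity-peaked mid-gesture,
flat at both ends, a standard minimal model of speech gestures.  Targets
(implementation constants): open-/a/ lip height 1.5 cm; closure height 0 cm
for labials and 0.8 cm residual for lingual consonants; vowel intensity
70 dB with closure floors of 30 dB (voiceless), 45 dB (voiced prevoicing),
55 dB (nasal murmur); F1 700 → 250 Hz; F2/F3 move from the /a/ loci (1300,
2500 Hz) to classical locus-theory consonant targets — labial (1100, 2300),
dental (1700, 2600), velar (1900, 2100), the velar "pinch".  Closing lip
gesture 150 ms, opening 120 ms, intensity fall 80 ms, burst rise 20 ms, F1
transition 60 ms, F2/F3 transition 150 ms.  Formants are undefined (NaN)
wherever the noiseless intensity is below a 40 dB voicing floor — formants
do not exist without resonance — so voiceless closures and isolated-mode
silence carry no formant samples, and isolated tokens have no CAI/CAF by
construction.

Timing offsets are injected per consonant (ms, CAI−CVL etc.); the default
table satisfies the empirically reported pattern while the per-consonant
split within each range is a modelling choice:

| offset | p | t | k | b | d | g | m | n | constraint |
|---|--|--|--|--|--|--|--|--|---|
| CAI−CVL | 40 | 35 | 25 | 40 | 30 | 30 | 40 | 40 | mean 35, range [20, 40] |
| CAF−CVL | 70 | 55 | 45 | 70 | 50 | 60 | 65 | 65 | mean 60, range [40, 80] |
| OAI−OVL | 0 | 5 | −22 | 0 | 5 | −25 | 0 | 5 | labials synchronous; velars audio-lead ≥ 20 ms |
| OAF−OVL | 8 | 10 | 0 | 8 | 10 | 0 | 8 | 10 | mean < 10 |
| OAI−CVL (isolated) | 350 | 280 | 240 | 330 | 260 | 250 | 360 | 300 | range [200, 400] |

The isolated lead equals closing duration + closure hold by construction.
Per-token Gaussian jitter (SD 5 ms) is added to every offset, truncated so
no offset changes sign; measurement noise is white Gaussian per channel
(lip 0.01 cm, intensity 0.3 dB, formants 10 Hz) — deliberately below the
detection thresholds so that recovery is possible, while the jitter
reproduces the nonzero between-repetition error bars of real data.  All
randomness flows from one integer seed through `numpy` seed sequences; the
same seed reproduces every sample exactly.

What the generator does **not** emulate: coarticulation between neighbouring
syllables, articulatory curvature differences across consonants, formant
transitions whose shape depends on place, amplitude/f0 declination, or any
video-processing artefacts.  Passing recovery tests therefore shows that the
estimation pipeline is unbiased under the stated noise model, not that it
would perform identically on recorded audio-video material.

## 3. Event detection

Events are found with threshold-from-extremum criteria: scanning a track, a
decrease-onset is emitted when the signal departs from its running maximum
by at least the channel threshold — 1 dB (intensity), 60 Hz (F1), 0.15 cm
(lip height) — and the event time is the *beginning of the decrease* (the
extremum), not the threshold-crossing instant, which would be biased late
by a slope-dependent amount.  Increase-onsets mirror this around running
minima.  NaN samples break extremum runs.

Robustness on noisy sampled tracks requires care, because the literal
argmax of a noisy plateau lands wherever the noise peaked.  The detector
therefore (each item an internal tuning constant, not a scientific
threshold):

1. median-filters acoustic tracks (width 5 at 100 Hz) per defined segment —
   the median is invariant on monotone spans, so transition timing is
   preserved;
2. lets the extremum tracker *follow* the signal while successive samples
   stay within a flatness tolerance (half the threshold) of the current
   extremum: noise peaks neither freeze the tracker nor steal the onset
   time;
3. accepts a departure only if it deepens to 2× the threshold (or runs into
   NaN) within the same excursion — real gestures travel far past the
   threshold, noise dips do not — and is refractory after each event until
   the signal rebounds a full threshold, so one monotone gesture fires
   exactly once (plus a 50 ms minimum inter-event gap);
4. re-anchors the emitted time to the last sample consistent with a robust
   local plateau estimate (median of the 10 preceding samples; its MAD
   provides a noise scale);
5. refines the anchored time to sub-sample precision with closed-form onset
   models chosen by the local sample geometry: a quadratic gesture foot
   (`level − y = a(t−t*)²`, exact for the start of a raised cosine), a
   secant extrapolation back to the plateau level for saturating jumps
   (bursts), and a plain parabola vertex for post-silence boundaries where
   no plateau exists.  On the 50 Hz lip track, where one sample is 20 ms,
   this refinement implements the "interpolate between consecutive images"
   step; it is applied to the 100 Hz acoustic tracks as well, because the
   10 ms sampling alone leaves a uniform 0–10 ms error whose median sits
   exactly at the recovery tolerance.

Known limitation: a gesture slower than the flatness tolerance per sample
(< 3.75 cm/s lip, < 50 dB/s intensity, < 3 kHz/s F1) is followed as plateau
drift and never fires; real gestures in this corpus are 4–100× faster.
Sub-sample refinement assumes a quadratic foot, so the onset of an exactly
linear ramp is estimated up to ~0.7 samples early; sample-level detection
(no interpolation) has no such bias.

Under the default noise model, recovery over 400 noisy chained tokens gives
per-event mean absolute biases below ~3 ms and median absolute errors below
3 ms (acoustic) and 5 ms (lip); segmenting a full 8-syllable chained
utterance yields 8 episodes × 6 events with the same accuracy.

## 4. Endpoint prediction (audio vs audiovisual)

The predictive model asks: observing the unfolding /aC/ trajectory some
time before closure, how well can the acoustic closure endpoint (F2, F3 at
closure) be predicted — and does adding the visible lip aperture help, even
though audio and video events are synchronous?  Classes are C ∈ {b, d, g};
the acoustic closure point is the end of the F2/F3 place transition.

Model: per class and per 10 ms time-to-closure bin, the observation vector
is Gaussian with mean and covariance fitted on training tokens (diagonal
regularisation: 10⁻³ of the mean variance); class posteriors follow from
Bayes' rule with equal priors at the nearest bin; the predicted endpoint is
the posterior-weighted mixture of class endpoint means.  Four observation
variants: A = (F2, F3); AD adds finite-difference velocities; AV adds lip
aperture; AVD adds all.  Efficiency per bin:

    C_eff(t) = 1 − ⟨‖pred(t) − endpoint‖⟩ / ⟨‖prior-mean endpoint − endpoint‖⟩

(1 = perfect, 0 = no better than predicting the prior mixture mean).  The
time grid covers the final 200 ms before closure: the earliest articulatory
onset in the corpus (the labial lip closing) lies ~220 ms before the
acoustic closure point, so earlier bins contain no class information and
their efficiency is sampling noise around zero.  Train/test splits are by
repetition index, deterministic given the seed.

Mechanism of the audiovisual advantage: during the first ~half of the
closing gesture the three classes' formants still sit together near the
vowel values (audio ambiguous), while the lip aperture already separates
/b/ (closing toward 0) from /d, g/ (residual opening ≥ 0.8 cm) by several
within-class SDs.  The visual stream is informative about the *future*
acoustic endpoint without leading the present acoustic events — AV beats A
at every bin earlier than ~120 ms before closure, with both near ceiling at
closure.  This is a toy demonstration: three classes, one vowel context,
Gaussian classes, ground-truth closure times; it makes no claim about
continuous speech.

## 5. Waveform analysis path

For real audio, intensity is frame-wise 10·log₁₀ mean-square amplitude
(25 ms frames, 10 ms hop, dB re full scale, floored at −60 dB) and formants
come from autocorrelation LPC (downsample to 10 kHz, pre-emphasis 0.97,
Hamming window, order 12, roots with bandwidth < 400 Hz; F1 = lowest
candidate in 150–1000 Hz; F2/F3 continuity-matched to the previous frame).
All settings are standard formant-analysis practice; no numeric identity
with any particular analysis program is claimed — the module's contract is
the round trip: synthesizing a vowel through the cascade-resonator
synthesizer (impulse train at 120 Hz, resonator bandwidths 80/100/140 Hz)
and re-analysing it recovers steady 700/1300/2500 Hz tracks within ±50 Hz.

## 6. Test and acceptance problem sizes

Recovery statistics in the test suite use 50 repetitions × 8 consonants per
mode (400 tokens per corpus), the predictor 30 training and 34 held-out
repetitions per class (102 held-out tokens); the detector is additionally
checked for exact agreement with an independent brute-force reference on
1000 random piecewise-linear tracks.  These sizes give sub-ms standard
errors on grand means while keeping the whole suite at a few seconds of
runtime.
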