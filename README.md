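# avsync — audiovisual speech asynchrony on plosive–vowel syllables

`avsync` is a Python package for studying the temporal relationship between
what a speaker's lips show and what their voice sounds like, on the simplest
possible speech material: consonant–vowel syllables /pa ta ka ba da ga ma na/
produced either in isolation (/Ca/ surrounded by silence) or chained
(/aCa.../, no silence).

The claim it operationalises: the often-quoted "~150 ms visual lead of
speech" only describes **preparatory** gestures — an utterance-initial lip
closure that is visible but silent, so the first visible event precedes the
first audible one by hundreds of ms.  In chained speech, gestures are
**comodulatory**: every closing and opening movement is *simultaneously*
visible (lip height) and audible (intensity, first formant), and the proper
within-phase asynchrony is small — a few tens of ms of video lead at
closure, near-synchrony or even audio lead at the release (velars release
with the tongue back before the lips move).  Visual *prediction* of upcoming
sound needs no visual lead at all, which a small Bayesian audiovisual
predictor demonstrates.

## What is in the package

| module | contents |
| --- | --- |
| `avsync.synth` | synthetic articulatory–acoustic corpus generator: 50 Hz lip-height tracks, 100 Hz intensity/F1/F2/F3 tracks, raised-cosine gestures, per-consonant audio-visual timing offsets with ground truth |
| `avsync.events` | onset event detection (CVL/OVL, CAI/OAI, CAF/OAF) by hysteresis thresholds from running extrema — 1 dB intensity, 60 Hz formant, 0.15 cm lip height — with sub-sample onset refinement |
| `avsync.asynchrony` | preparatory (CVL−OAI, CVL−OAF) and comodulatory (CVL−CAI, CVL−CAF, OVL−OAI, OVL−OAF) delays, per-consonant mean ± SD, grand means |
| `avsync.prediction` | time-binned class-conditional Gaussian predictor of the acoustic closure endpoint; audio-only vs audiovisual variants; C_efficiency curves |
| `avsync.acoustics` | frame-wise intensity (dB) and LPC formant tracking for real audio, plus a cascade-resonator formant synthesizer used as the analysis oracle |
| `avsync.io` / `avsync.pipeline` / `avsync.cli` | CSV/JSON/WAV formats, the validated end-to-end pipeline, and the `avsync` command line |

Delays are signed literal event-time differences in ms: negative means the
acoustic event lags the visual one (video lead), positive means the acoustic
event leads.

## Worked example

```python
from avsync import (DetectionThresholds, NoiseSpec, generate_corpus,
                    label_corpus, make_default_calibration)
from avsync import asynchrony as asyn

calib = make_default_calibration()           # per-consonant offsets, ms
tokens = generate_corpus(calib, NoiseSpec(), n_repetitions=50,
                         modes=("chained",), seed=3)
labels = label_corpus(tokens, DetectionThresholds())
records = asyn.records_from_labels(labels, "chained")
summary = asyn.summarize(records, expected_per_group=50)
print(asyn.grand_means(summary).round(1))
```

prints

```
measure
CVL-CAF   -57.0
CVL-CAI   -31.8
OVL-OAF    -7.0
OVL-OAI     5.5
Name: mean_ms, dtype: float64
```

Reading: in chained syllables the visible lip closing leads the audible
intensity decrease by ~32 ms and the F1 fall by ~57 ms on average (negative
= video lead), while at the release the two streams are near-synchronous
(opening-phase means within ±10 ms of zero; the positive OVL−OAI grand mean
is pulled by the velar audio lead).  These are *recovered* values:
the generator injected per-consonant offsets averaging 35 ms and 60 ms, and
the detection pipeline recovers them through 50 Hz lip sampling, measurement
noise, and 5 ms token-level timing jitter.

The same pipeline is available from the shell:

```sh
avsync run --out out/ --seed 3          # generate + detect + summarize
avsync predict --out eff.csv --seed 7   # efficiency curves of the 4 models
```

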