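"""File formats: track CSVs, event tables, token sidecars, corpus manifests,
and mono PCM WAV.

All tabular formats are headered CSV; times are serialized in seconds as
decimals at microsecond precision (never sample indices), so channels with
different rates coexist.  A token is stored as one CSV per channel plus a
JSON sidecar holding the spec, seed, ground-truth events and injected
offsets; a corpus is a JSON manifest listing its token directories.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .events import EVENT_TABLE, EventLabel
from .synth import NoiseSpec, SyllableSpec, SyllableToken
from .tracks import CHANNELS, TrajectoryTrack

logger = logging.getLogger(__name__)

_TIME_FMT = "%.6f"


class FormatError(ValueError):
    """Malformed input file (message carries the offending line)."""


def write_track_csv(track: TrajectoryTrack, path) -> None:
    times = track.times()
    with open(path, "w") as fh:
        fh.write(f"time_s,value # channel={track.channel} "
                 f"rate_hz={track.sample_rate_hz:g}\n")
        for t, v in zip(times, track.values):
            val = "" if not np.isfinite(v) else f"{v:.6f}"
            fh.write(f"{_TIME_FMT % t},{val}\n")


def read_track_csv(path, channel: str | None = None) -> TrajectoryTrack:
    """Read a track CSV; rejects non-uniform time columns.

    The channel and rate are taken from the header comment when present,
    else ``channel`` must be given and the rate is inferred from the time
    column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    rate = None
    if "#" in header:
        for tokn in header.split("#", 1)[1].split():
            if tokn.startswith("channel="):
                channel = channel or tokn.split("=", 1)[1]
            elif tokn.startswith("rate_hz="):
                rate = float(tokn.split("=", 1)[1])
    if channel is None:
        raise FormatError(f"{path}: no channel in header and none given")
    times, values = [], []
    with open(path) as fh:
        next(fh)
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]) if parts[1] else np.nan)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    times = np.asarray(times)
    if times.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dts = np.diff(times)
    dt = float(np.median(dts))
    if dt <= 0 or np.any(np.abs(dts - dt) > 2e-6):
        raise FormatError(f"{path}: non-uniform time column")
    if rate is None:
        rate = 1.0 / dt
    return TrajectoryTrack(channel, rate, float(times[0]), np.asarray(values))


def write_events_csv(labels, path) -> None:
    df = pd.DataFrame(
        [(l.token_id, l.consonant, l.mode, l.kind, l.time_s, l.channel)
         for l in labels],
        columns=["token_id", "consonant", "mode", "kind", "time_s", "channel"])
    df.to_csv(path, index=False, float_format=_TIME_FMT)


def read_events_csv(path) -> list:
    df = pd.read_csv(path)
    labels = []
    for i, row in df.iterrows():
        try:
            channel, phase, direction = EVENT_TABLE[row["kind"]]
            labels.append(EventLabel(
                kind=row["kind"], time_s=float(row["time_s"]),
                channel=channel, phase=phase, direction=direction,
                token_id=str(row["token_id"]), consonant=str(row["consonant"]),
                mode=str(row["mode"])))
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
    return labels


def write_token(token: SyllableToken, directory) -> Path:
    """One CSV per channel plus a JSON sidecar; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for channel, track in token.tracks.items():
        write_track_csv(track, directory / f"{channel}.csv")
    sidecar = {
        "token_id": token.token_id,
        "spec": asdict(token.spec),
        "seed": token.seed,
        "truth_events": token.truth_events,
        "injected_offsets_ms": token.injected_offsets_ms,
        "closure_time_s": token.closure_time_s,
        "channels": sorted(token.tracks),
    }
    with open(directory / "token.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return directory


def read_token(directory) -> SyllableToken:
    directory = Path(directory)
    with open(directory / "token.json") as fh:
        sidecar = json.load(fh)
    tracks = {ch: read_track_csv(directory / f"{ch}.csv")
              for ch in sidecar["channels"]}
    return SyllableToken(
        spec=SyllableSpec(**sidecar["spec"]), tracks=tracks,
        truth_events=sidecar["truth_events"],
        injected_offsets_ms=sidecar["injected_offsets_ms"],
        seed=sidecar["seed"], closure_time_s=sidecar["closure_time_s"],
        token_id=sidecar["token_id"])


def write_corpus(tokens, directory) -> Path:
    """Token directories plus a ``manifest.json``; returns the manifest
    path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for token in tokens:
        write_token(token, directory / token.token_id)
        entries.append(token.token_id)
    manifest = directory / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"tokens": entries}, fh, indent=1)
    return manifest


def read_corpus(manifest_path) -> list:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = manifest_path.parent
    return [read_token(root / token_id) for token_id in manifest["tokens"]]


def write_wav(path, waveform, expected_rate_hz: float | None = None) -> None:
    """Mono 16-bit PCM."""
    samples = np.clip(waveform.samples, -1.0, 1.0)
    wavfile.write(path, int(round(waveform.sample_rate_hz)),
                  (samples * 32767.0).astype(np.int16))


def read_wav(path, expected_rate_hz: float | None = None):
    """Mono 16-bit PCM WAV; resamples (with a warning) on rate mismatch."""
    from .acoustics import Waveform

    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise FormatError(f"{path}: only mono WAV supported")
    if data.dtype == np.int16:
        samples = data.astype(float) / 32768.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(float)
    else:
        raise FormatError(f"{path}: unsupported sample format {data.dtype}")
    if expected_rate_hz is not None and rate != expected_rate_hz:
        warnings.warn(f"{path}: rate {rate} != expected {expected_rate_hz}; "
                      "resampling")
        from fractions import Fraction

        frac = Fraction(int(expected_rate_hz), int(rate)).limit_denominator(
            10_000)
        samples = resample_poly(samples, frac.numerator, frac.denominator)
        rate = expected_rate_hz
    return Waveform(float(rate), samples)
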