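"""Audiovisual asynchrony measures and per-consonant statistics.

Two measures, chosen by the production context:

* **Preparatory** (isolated /Ca/): the closing gesture is visible but silent,
  so the only meaningful delay is first-visible to first-audible event,
  CVL−OAI and CVL−OAF.  These are strongly negative (visual lead of several
  hundred ms) simply because lips must close before they can open.
* **Comodulatory** (chained /aCa/): closing and opening are each both audible
  and visible, so asynchrony is measured within phase: CVL−CAI and CVL−CAF
  for the closing phase, OVL−OAI and OVL−OAF for the opening phase.

Delays are literal event-time subtractions in ms: negative means the
acoustic event lags the visual one (video lead), positive means the acoustic
event leads.  Applying the preparatory measure to a chained episode is a
category error (it ignores the audible closing events) and raises
:class:`AsynchronyModeError` rather than silently producing the wrong
number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PREPARATORY_MEASURES = ("CVL-OAI", "CVL-OAF")
COMODULATORY_MEASURES = ("CVL-CAI", "CVL-CAF", "OVL-OAI", "OVL-OAF")
MEASURES = PREPARATORY_MEASURES + COMODULATORY_MEASURES


class AsynchronyModeError(ValueError):
    """Raised when a measure is requested in the wrong production mode."""


@dataclass
class AsynchronyRecord:
    token_id: str
    consonant: str
    measure: str
    delay_ms: float

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")


def _event_times(events) -> dict:
    """Accept a {kind: time_s} dict or a list of EventLabel."""
    if isinstance(events, dict):
        return dict(events)
    return {e.kind: e.time_s for e in events}


def _delay(times: dict, first: str, second: str) -> float | None:
    if first not in times or second not in times:
        return None
    return (times[first] - times[second]) * 1000.0


def preparatory_asynchrony(events, token_id: str = "",
                           consonant: str = "") -> list:
    """CVL−OAI and CVL−OAF delays (ms) of one isolated token.

    Raises :class:`AsynchronyModeError` if the episode carries audible
    closing events (CAI/CAF): the preparatory measure is undefined for
    comodulatory (chained) material.
    """
    times = _event_times(events)
    if "CAI" in times or "CAF" in times:
        raise AsynchronyModeError(
            "preparatory asynchrony is undefined for chained episodes "
            "(audible closing events present); use comodulatory_asynchrony")
    if "CVL" not in times:
        logger.warning("token %s: no CVL event, preparatory asynchrony "
                       "skipped", token_id)
        return []
    records = []
    for measure, second in (("CVL-OAI", "OAI"), ("CVL-OAF", "OAF")):
        d = _delay(times, "CVL", second)
        if d is None:
            logger.warning("token %s: missing %s", token_id, second)
            continue
        records.append(AsynchronyRecord(token_id, consonant, measure, d))
    return records


def comodulatory_asynchrony(events, token_id: str = "",
                            consonant: str = "") -> list:
    """Within-phase delays (ms) of one chained episode.

    Emits every pair present among CVL−CAI, CVL−CAF (closing) and OVL−OAI,
    OVL−OAF (opening); a missing member of a pair drops that record only.
    """
    times = _event_times(events)
    pairs = (("CVL-CAI", "CVL", "CAI"), ("CVL-CAF", "CVL", "CAF"),
             ("OVL-OAI", "OVL", "OAI"), ("OVL-OAF", "OVL", "OAF"))
    records = []
    for measure, first, second in pairs:
        d = _delay(times, first, second)
        if d is None:
            logger.warning("token %s: missing events for %s", token_id,
                           measure)
            continue
        records.append(AsynchronyRecord(token_id, consonant, measure, d))
    return records


def records_from_labels(labels, mode: str) -> list:
    """Asynchrony records for a flat list of event labels, one token at a
    time (grouped by ``token_id``)."""
    fn = preparatory_asynchrony if mode == "isolated" else comodulatory_asynchrony
    by_token: dict = {}
    for lab in labels:
        if lab.mode != mode:
            continue
        by_token.setdefault((lab.token_id, lab.consonant), []).append(lab)
    records = []
    for (token_id, consonant), labs in by_token.items():
        records.extend(fn(labs, token_id=token_id, consonant=consonant))
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.token_id, r.consonant, r.measure, r.delay_ms) for r in records],
        columns=["token_id", "consonant", "measure", "delay_ms"],
    )


def summarize(records, expected_per_group: int | None = None) -> pd.DataFrame:
    """Per consonant × measure mean, SD (ddof=1) and counts.

    ``expected_per_group`` (e.g. the number of repetitions) fills the
    ``n_missing`` column; empty groups are excluded with a warning.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        logger.warning("no asynchrony records to summarize")
        return pd.DataFrame(columns=["consonant", "measure", "mean_ms",
                                     "sd_ms", "n_tokens", "n_missing"])
    out = (df.groupby(["consonant", "measure"])["delay_ms"]
             .agg(mean_ms="mean", sd_ms=lambda x: x.std(ddof=1), n_tokens="size")
             .reset_index())
    if expected_per_group is not None:
        out["n_missing"] = expected_per_group - out["n_tokens"]
    else:
        out["n_missing"] = 0
    return out


def grand_means(summary: pd.DataFrame) -> pd.Series:
    """Unweighted mean over consonants of the per-consonant means, per
    measure (each consonant counts equally, regardless of token counts)."""
    return summary.groupby("measure")["mean_ms"].mean()
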