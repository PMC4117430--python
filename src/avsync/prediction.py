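"""Bayesian audiovisual prediction of the acoustic closure endpoint.

A toy predictive-coding model for /aCa/ trajectories with C in {b, d, g}:
given an observation taken some time before the acoustic closure, predict
where the (F2, F3) trajectory will end up at closure.  The point of the
model is that the *visual* stream (lip aperture) improves this prediction
even though audio and video events are essentially synchronous: lips
disambiguate the labial class early — while the formant trajectories of the
three classes still sit together near the vowel — because the lip closing
gesture is informative as soon as it starts, about the *future* acoustic
endpoint rather than about any time-shifted present.

Model: per consonant class and per time-to-closure bin, the observation
vector is Gaussian (class-conditional mean and covariance estimated from
training tokens); class posteriors follow from Bayes' rule at the nearest
bin, and the predicted endpoint is the posterior-weighted mixture of the
class endpoint means.  Four observation variants are compared:

====  =========================================================
A     (F2, F3) — audio only
AD    (F2, F3, dF2/dt, dF3/dt) — audio + audio velocities
AV    (F2, F3, lip aperture) — audiovisual
AVD   all six — audiovisual + velocities
====  =========================================================

Prediction quality is summarised by the efficiency score

    C_efficiency(t) = 1 - <||predicted(t) - endpoint||> / <||prior - endpoint||>

where the prior predictor is the class-prior-weighted mean endpoint (what
one would predict with no observation at all): 0 means no better than the
prior, 1 means perfect prediction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from .tracks import F2, F3, LIP

logger = logging.getLogger(__name__)

VARIANTS = ("A", "AD", "AV", "AVD")

#: Observation-vector fields per variant, in order.
VARIANT_FIELDS = {
    "A": ("F2", "F3"),
    "AD": ("F2", "F3", "dF2", "dF3"),
    "AV": ("F2", "F3", "lip"),
    "AVD": ("F2", "F3", "dF2", "dF3", "lip", "dlip"),
}

#: Default time-to-closure grid: 10 ms bins over the final 200 ms.  The
#: earliest articulatory onset of the corpus lies ~220 ms before closure, so
#: earlier bins would carry no class information at all.
DEFAULT_BINS_S = np.round(np.arange(0.0, 0.201, 0.010), 3)

PREDICTION_CONSONANTS = ("b", "d", "g")


@dataclass
class AVObservation:
    """One observation of the unfolding /aC/ trajectory."""

    time_to_closure_s: float
    f2_hz: float
    f3_hz: float
    lip_aperture_cm: float | None = None
    df2_hz_s: float | None = None
    df3_hz_s: float | None = None
    dlip_cm_s: float | None = None

    def vector(self, variant: str) -> np.ndarray:
        lookup = {"F2": self.f2_hz, "F3": self.f3_hz,
                  "dF2": self.df2_hz_s, "dF3": self.df3_hz_s,
                  "lip": self.lip_aperture_cm, "dlip": self.dlip_cm_s}
        vals = []
        for name in VARIANT_FIELDS[variant]:
            v = lookup[name]
            if v is None or not np.isfinite(v):
                raise ValueError(f"variant {variant} needs field {name}")
            vals.append(float(v))
        return np.array(vals)


@dataclass
class ClosureEndpoint:
    f2c_hz: float
    f3c_hz: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f2c_hz, self.f3c_hz])


@dataclass
class AVPredictorModel:
    """Time-binned class-conditional Gaussian predictor."""

    variant: str
    classes: tuple
    bins_s: np.ndarray
    priors: np.ndarray
    means: np.ndarray        # (n_class, n_bin, dim)
    covs: np.ndarray         # (n_class, n_bin, dim, dim)
    endpoint_means: np.ndarray  # (n_class, 2)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")

    @property
    def dim(self) -> int:
        return len(VARIANT_FIELDS[self.variant])

    def prior_endpoint(self) -> np.ndarray:
        """Class-prior-weighted mean endpoint (the no-observation guess)."""
        return self.priors @ self.endpoint_means

    def nearest_bin(self, time_to_closure_s: float) -> int:
        return int(np.argmin(np.abs(self.bins_s - time_to_closure_s)))

    def to_json(self, path) -> None:
        obj = {
            "variant": self.variant,
            "classes": list(self.classes),
            "bins_s": self.bins_s.tolist(),
            "priors": self.priors.tolist(),
            "means": self.means.tolist(),
            "covs": self.covs.tolist(),
            "endpoint_means": self.endpoint_means.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "AVPredictorModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(variant=obj["variant"], classes=tuple(obj["classes"]),
                   bins_s=np.asarray(obj["bins_s"]),
                   priors=np.asarray(obj["priors"]),
                   means=np.asarray(obj["means"]),
                   covs=np.asarray(obj["covs"]),
                   endpoint_means=np.asarray(obj["endpoint_means"]))


@dataclass
class EfficiencyCurve:
    variant: str
    bins_s: np.ndarray
    mean: np.ndarray
    min: np.ndarray
    max: np.ndarray


def observe_token(token, time_to_closure_s: float,
                  half_step_s: float = 0.005) -> AVObservation:
    """Sample the observation vector of a token at a given time before its
    (ground-truth) acoustic closure point."""
    if token.closure_time_s is None:
        raise ValueError("token has no closure time (isolated mode?)")
    t = token.closure_time_s - time_to_closure_s
    f2t, f3t, lipt = token.track(F2), token.track(F3), token.track(LIP)
    return AVObservation(
        time_to_closure_s=time_to_closure_s,
        f2_hz=float(f2t.value_at(t)),
        f3_hz=float(f3t.value_at(t)),
        lip_aperture_cm=float(lipt.value_at(t)),
        df2_hz_s=float(f2t.derivative_at(t, half_step_s)),
        df3_hz_s=float(f3t.derivative_at(t, half_step_s)),
        dlip_cm_s=float(lipt.derivative_at(t, half_step_s)),
    )


def token_endpoint(token) -> np.ndarray:
    """True (F2, F3) at the token's acoustic closure point."""
    t = token.closure_time_s
    return np.array([float(token.track(F2).value_at(t)),
                     float(token.track(F3).value_at(t))])


def fit_predictor(tokens, variant: str, bins_s=None,
                  priors=None, reg_eps: float = 1e-3) -> AVPredictorModel:
    """Fit the class-conditional Gaussians on a training token list.

    ``reg_eps`` scales the diagonal regularisation added to each covariance
    (eps times the mean variance of that covariance).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    bins_s = DEFAULT_BINS_S if bins_s is None else np.asarray(bins_s)
    classes = tuple(sorted({t.spec.consonant for t in tokens}))
    dim = len(VARIANT_FIELDS[variant])
    n_class, n_bin = len(classes), bins_s.size
    means = np.zeros((n_class, n_bin, dim))
    covs = np.zeros((n_class, n_bin, dim, dim))
    endpoint_means = np.zeros((n_class, 2))
    for ci, c in enumerate(classes):
        members = [t for t in tokens if t.spec.consonant == c]
        if len(members) < 2:
            raise ValueError(f"need >= 2 training tokens per class ({c})")
        endpoint_means[ci] = np.mean([token_endpoint(t) for t in members],
                                     axis=0)
        for bi, tc in enumerate(bins_s):
            X = np.array([observe_token(t, tc).vector(variant)
                          for t in members])
            means[ci, bi] = X.mean(axis=0)
            cov = np.cov(X, rowvar=False, ddof=1).reshape(dim, dim)
            cov += reg_eps * max(np.trace(cov) / dim, 1e-12) * np.eye(dim)
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"singular covariance for class {c}, bin {tc}") from exc
            covs[ci, bi] = cov
    if priors is None:
        priors = np.full(n_class, 1.0 / n_class)
    priors = np.asarray(priors, dtype=float)
    return AVPredictorModel(variant=variant, classes=classes, bins_s=bins_s,
                            priors=priors, means=means, covs=covs,
                            endpoint_means=endpoint_means)


def _log_gauss(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    diff = x - mean
    chol = np.linalg.cholesky(cov)
    sol = solve_triangular(chol, diff, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return float(-0.5 * (sol @ sol + logdet + diff.size * np.log(2 * np.pi)))


def predict_endpoint(model: AVPredictorModel, obs: AVObservation):
    """Posterior over classes and mixture endpoint for one observation.

    Returns ``(ClosureEndpoint, posterior)`` where ``posterior`` maps class
    labels to probabilities (summing to 1).
    """
    x = obs.vector(model.variant)
    bi = model.nearest_bin(obs.time_to_closure_s)
    logp = np.array([
        np.log(model.priors[ci]) + _log_gauss(x, model.means[ci, bi],
                                              model.covs[ci, bi])
        for ci in range(len(model.classes))
    ])
    logp -= logp.max()
    post = np.exp(logp)
    post /= post.sum()
    endpoint = post @ model.endpoint_means
    return (ClosureEndpoint(float(endpoint[0]), float(endpoint[1])),
            dict(zip(model.classes, post)))


def efficiency_curve(model: AVPredictorModel, tokens,
                     bins_s=None) -> EfficiencyCurve:
    """Prediction-efficiency score per time-to-closure bin on held-out
    tokens.

    Per bin t:  C_eff = 1 - <||pred - true||> / <||prior - true||>, with the
    prior predictor fixed at the class-prior-weighted endpoint mean.  The
    per-token scores share the cohort-mean baseline, so the bin mean equals
    the ratio-of-means definition; min and max are taken across tokens.
    """
    bins_s = model.bins_s if bins_s is None else np.asarray(bins_s)
    truths = np.array([token_endpoint(t) for t in tokens])
    prior = model.prior_endpoint()
    baseline = float(np.mean(np.linalg.norm(prior - truths, axis=1)))
    mean, mn, mx, kept = [], [], [], []
    for tc in bins_s:
        scores = []
        for tok, truth in zip(tokens, truths):
            try:
                pred, _ = predict_endpoint(model, observe_token(tok, tc))
            except ValueError:
                continue
            err = float(np.linalg.norm(pred.as_array() - truth))
            scores.append(1.0 - err / baseline)
        if not scores:
            logger.warning("empty bin at %.3f s omitted", tc)
            continue
        kept.append(tc)
        mean.append(np.mean(scores))
        mn.append(np.min(scores))
        mx.append(np.max(scores))
    return EfficiencyCurve(model.variant, np.asarray(kept), np.asarray(mean),
                           np.asarray(mn), np.asarray(mx))


def train_test_split_tokens(tokens, n_train_repetitions: int):
    """Deterministic split by repetition index: repetitions 1..n go to
    training, the rest to held-out testing."""
    train = [t for t in tokens if t.spec.repetition_index <= n_train_repetitions]
    test = [t for t in tokens if t.spec.repetition_index > n_train_repetitions]
    return train, test


def efficiency_table(curves) -> "object":
    """Long-format DataFrame (variant, time_ms_before_closure, mean, min,
    max) for CSV export."""
    import pandas as pd

    rows = []
    for c in curves:
        for tc, m, lo, hi in zip(c.bins_s, c.mean, c.min, c.max):
            rows.append((c.variant, 1000.0 * tc, m, lo, hi))
    return pd.DataFrame(rows, columns=["variant", "time_ms_before_closure",
                                       "mean", "min", "max"])
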