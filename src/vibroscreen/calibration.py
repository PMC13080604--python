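"""Probability post-processing: temperature scaling, Youden cutpoints,
three-tier stratification, and calibration diagnostics.

Temperature scaling divides the logit of each risk probability by a
single fitted scalar T > 0 (``σ(logit(p)/T)``); it is strictly monotone,
so discrimination (ROC/AUC) is untouched while calibration improves.
Operating thresholds are picked by maximising the Youden index
J = sensitivity + specificity − 1, applied twice (against the
"severity >= 3" and "severity >= 4" gold binarizations) to obtain the
two cutpoints that split calibrated probabilities into three risk tiers:
(1) asymptomatic/mild, (2) moderate, (3) severe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TemperatureScaler",
    "fit_temperature",
    "youden_threshold",
    "TierThresholds",
    "assign_tier",
    "TierStratifier",
    "brier_score",
    "calibration_curve",
]

_EPS = 1e-6


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1 - _EPS)
    return np.log(p / (1 - p))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class TemperatureScaler(BaseEstimator, TransformerMixin):
    """Fit a single temperature to recalibrate risk probabilities.

    ``fit(p, y)`` minimises the negative log-likelihood of
    ``σ(logit(p)/T)`` over T ∈ [t_min, t_max] with a bounded scalar
    optimizer; ``transform(p)`` applies the fitted temperature.

    Attributes
    ----------
    temperature_ : float
        Fitted T (> 0).  T > 1 flattens overconfident probabilities
        toward 0.5; T < 1 sharpens underconfident ones.
    nll_ : float
        Mean negative log-likelihood at the fitted temperature.
    """

    def __init__(self, t_min: float = 0.05, t_max: float = 20.0):
        self.t_min = t_min
        self.t_max = t_max

    def fit(self, probs, labels):
        probs = np.asarray(probs, dtype=np.float64)
        labels = np.asarray(labels).astype(np.float64)
        if probs.size == 0 or probs.shape != labels.shape:
            raise ValueError("probs and labels must be equal-length and non-empty")
        if probs.min() <= 0 or probs.max() >= 1:
            raise ValueError("probabilities must lie strictly in (0, 1)")
        uniq = np.unique(labels)
        if not np.isin(uniq, (0.0, 1.0)).all() or uniq.size < 2:
            raise ValueError("labels must be binary with both classes present")
        logits = _logit(probs)

        def nll(t: float) -> float:
            q = np.clip(_sigmoid(logits / t), _EPS, 1 - _EPS)
            return float(-np.mean(labels * np.log(q) + (1 - labels) * np.log(1 - q)))

        res = minimize_scalar(nll, bounds=(self.t_min, self.t_max), method="bounded",
                              options={"xatol": 1e-5})
        self.temperature_ = float(res.x)
        self.nll_ = float(res.fun)
        return self

    def transform(self, probs) -> np.ndarray:
        if not hasattr(self, "temperature_"):
            raise AttributeError("TemperatureScaler is not fitted")
        probs = np.asarray(probs, dtype=np.float64)
        return _sigmoid(_logit(probs) / self.temperature_)

    predict_proba = transform


def fit_temperature(probs, labels, **kwargs) -> TemperatureScaler:
    """Functional wrapper: fit and return a :class:`TemperatureScaler`."""
    return TemperatureScaler(**kwargs).fit(probs, labels)


def youden_threshold(scores, labels) -> tuple[float, float]:
    """Cutpoint maximising J = sensitivity + specificity − 1.

    Candidates are the midpoints between adjacent sorted unique scores;
    a score is called positive when it is >= the cutpoint.  Ties in J
    break toward the lowest cutpoint.  Returns ``(threshold, J)``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("scores are constant; no cutpoint exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    best_t, best_j = None, -np.inf
    for t in candidates:  # ascending, so strict > keeps the lowest tie
        pred = scores >= t
        j = (pred & labels).sum() / n_pos + ((~pred) & (~labels)).sum() / n_neg - 1
        if j > best_j + 1e-12:
            best_t, best_j = float(t), float(j)
    return best_t, best_j


@dataclass(frozen=True)
class TierThresholds:
    """Two ascending probability cutpoints splitting risk into three tiers."""

    t1: float
    t2: float

    def __post_init__(self):
        if not (0 < self.t1 < self.t2 < 1):
            raise ValueError(f"need 0 < t1 < t2 < 1, got ({self.t1}, {self.t2})")


def assign_tier(p: float, thresholds: TierThresholds) -> int:
    """Map a calibrated probability to a risk tier (left-closed intervals).

    p < t1 → 1 (asymptomatic/mild); t1 <= p < t2 → 2 (moderate);
    p >= t2 → 3 (severe).
    """
    if not (0 <= p <= 1):
        raise ValueError(f"probability out of [0, 1]: {p}")
    if p < thresholds.t1:
        return 1
    if p < thresholds.t2:
        return 2
    return 3


class TierStratifier(BaseEstimator):
    """Derive the two tier cutpoints from gold severities and stratify.

    The Youden procedure is applied twice on the supplied risk
    probabilities: against the ``severity >= 3`` binarization (moderate
    boundary, t1) and against ``severity >= 4`` (severe boundary, t2).
    ``predict`` then maps probabilities to tiers 1–3.

    Attributes
    ----------
    thresholds_ : TierThresholds
    j_moderate_, j_severe_ : float
        Youden J at each fitted cutpoint.
    """

    def __init__(self, moderate_cutoff: int = 3, severe_cutoff: int = 4):
        self.moderate_cutoff = moderate_cutoff
        self.severe_cutoff = severe_cutoff

    def fit(self, probs, severities):
        probs = np.asarray(probs, dtype=np.float64)
        severities = np.asarray(severities, dtype=int)
        t1, j1 = youden_threshold(probs, severities >= self.moderate_cutoff)
        t2, j2 = youden_threshold(probs, severities >= self.severe_cutoff)
        if not t1 < t2:
            # the two binarizations picked the same (or inverted) cutpoints;
            # keep tiers monotone by moving t2 to the next candidate above t1
            t1 = min(t1, t2)
            uniq = np.unique(probs)
            candidates = (uniq[:-1] + uniq[1:]) / 2
            above = candidates[candidates > t1]
            if above.size == 0:
                raise ValueError(
                    "no candidate cutpoint above t1; cannot form three tiers"
                )
            t2 = float(above[0])
        self.thresholds_ = TierThresholds(t1=t1, t2=t2)
        self.j_moderate_, self.j_severe_ = j1, j2
        return self

    def predict(self, probs) -> np.ndarray:
        if not hasattr(self, "thresholds_"):
            raise AttributeError("TierStratifier is not fitted")
        return np.array([assign_tier(float(p), self.thresholds_) for p in
                         np.asarray(probs, dtype=np.float64)])


def brier_score(probs, labels) -> float:
    """Mean squared difference between probability and binary outcome."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(np.float64)
    if probs.size == 0 or probs.shape != labels.shape:
        raise ValueError("probs and labels must be equal-length and non-empty")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((probs - labels) ** 2))


def calibration_curve(probs, labels, n_bins: int = 10):
    """Reliability-diagram points on equal-width bins of [0, 1].

    Returns ``(mean_prob, observed_rate, count)`` arrays over the
    non-empty bins.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(np.float64)
    if probs.size == 0:
        raise ValueError("empty input")
    edges = np.linspace(0, 1, n_bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    mean_p, obs, count = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            mean_p.append(probs[sel].mean())
            obs.append(labels[sel].mean())
            count.append(int(sel.sum()))
    return np.array(mean_p), np.array(obs), np.array(count)
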