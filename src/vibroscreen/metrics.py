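"""Screening-performance statistics and combined-screen gain analysis.

Everything downstream of a binary screen lives here: confusion-matrix
metrics (sensitivity, specificity, precision, F1), rank-based ROC AUC,
macro-averaged multi-class F1, percentile bootstrap confidence intervals,
decision-curve net benefit, the logical-OR combination of two screens,
and relative-gain reporting.

Undefined ratios (zero denominators) are reported as ``None`` — never
silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinaryConfusion",
    "binary_metrics",
    "confusion_from_predictions",
    "combine_or",
    "macro_f1",
    "roc_auc",
    "bootstrap_ci",
    "decision_curve",
    "gain_report",
]


@dataclass(frozen=True)
class BinaryConfusion:
    """TP/FP/FN/TN counts of a binary screen against the gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Gold-standard positives."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def binary_metrics(cm: BinaryConfusion) -> dict[str, float | None]:
    """Point estimates of the standard screening metrics.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    precision = TP/(TP+FP); F1 = 2TP/(2TP+FP+FN).
    A metric whose denominator is zero is returned as ``None``.
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    f1 = _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "recall": sens,
        "f1": f1,
        "accuracy": _ratio(cm.tp + cm.tn, cm.n),
        "prevalence": _ratio(cm.tp + cm.fn, cm.n),
    }


def confusion_from_predictions(pred, gold) -> BinaryConfusion:
    """Tabulate binary predictions against binary gold labels."""
    pred = np.asarray(pred, dtype=bool)
    gold = np.asarray(gold, dtype=bool)
    if pred.shape != gold.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gold {gold.shape}")
    return BinaryConfusion(
        tp=int((pred & gold).sum()),
        fp=int((pred & ~gold).sum()),
        fn=int((~pred & gold).sum()),
        tn=int((~pred & ~gold).sum()),
    )


def combine_or(pred_a, pred_b, ids_a=None, ids_b=None) -> np.ndarray:
    """Logical-OR combination: positive iff either screen is positive.

    Raises sensitivity and lowers specificity relative to either
    component.  When subject id arrays are supplied, they must match
    element-wise (the screens must describe the same subjects in the
    same order).
    """
    a = np.asarray(pred_a, dtype=bool)
    b = np.asarray(pred_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("prediction vectors have different lengths")
    if ids_a is not None or ids_b is not None:
        ids_a, ids_b = np.asarray(ids_a), np.asarray(ids_b)
        if ids_a.shape != ids_b.shape or (ids_a != ids_b).any():
            raise ValueError("subject ids of the two screens are not aligned")
    return a | b


def macro_f1(confusion: np.ndarray) -> tuple[float, np.ndarray]:
    """Macro-averaged F1 of a K×K confusion matrix (rows = true class).

    Per-class one-vs-rest F1 is averaged with equal weight.  A class
    absent from both the rows and columns contributes F1 = 0 and emits a
    warning.  Returns ``(macro, per_class)``.
    """
    c = np.asarray(confusion, dtype=np.int64)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] < 2:
        raise ValueError(f"need a square K×K matrix with K >= 2, got {c.shape}")
    if c.sum() == 0:
        raise ValueError("empty confusion matrix")
    k = c.shape[0]
    per_class = np.zeros(k)
    for i in range(k):
        tp = c[i, i]
        fn = c[i, :].sum() - tp
        fp = c[:, i].sum() - tp
        if tp + fn + fp == 0:
            warnings.warn(
                f"class {i} absent from both true and predicted labels; "
                "its F1 counts as 0 in the macro average",
                stacklevel=2,
            )
            per_class[i] = 0.0
        else:
            per_class[i] = 2 * tp / (2 * tp + fp + fn)
    return float(per_class.mean()), per_class


def roc_auc(scores, labels, return_curve: bool = False):
    """ROC AUC via the rank (Mann–Whitney) formulation, ties counted 1/2.

    Equivalent to the probability that a random positive outranks a
    random negative.  With ``return_curve=True`` also returns the ROC
    points (fpr, tpr, thresholds) at all score cutpoints.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    if not return_curve:
        return float(auc)
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return float(auc), (fpr, tpr, thr)


def bootstrap_ci(
    statistic,
    data,
    b: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    stratify=None,
    max_redraws: int = 100,
) -> tuple[float, float, int]:
    """95% (by default) percentile bootstrap interval of a statistic.

    ``data`` is a tuple of equal-length arrays resampled jointly with
    replacement; ``stratify`` (a binary label array) switches to
    class-stratified resampling, appropriate for AUC, sensitivity and
    specificity, whose definition needs both classes present.  A
    resample on which the statistic raises is redrawn; the number of
    redraws is capped and reported as the third return value.

    Returns ``(low, high, n_redraws)``.
    """
    if b < 100:
        raise ValueError(f"need at least 100 bootstrap repetitions, got {b}")
    arrays = [np.asarray(a) for a in data]
    n = arrays[0].shape[0]
    if n == 0 or any(a.shape[0] != n for a in arrays):
        raise ValueError("data arrays must be non-empty and equal-length")
    rng = np.random.default_rng(seed)
    if stratify is not None:
        stratify = np.asarray(stratify).astype(bool)
        groups = [np.flatnonzero(stratify), np.flatnonzero(~stratify)]
        if any(g.size == 0 for g in groups):
            raise ValueError("stratified bootstrap needs both classes present")
    stats = np.empty(b)
    redraws = 0
    for i in range(b):
        while True:
            if stratify is None:
                idx = rng.integers(0, n, size=n)
            else:
                idx = np.concatenate(
                    [rng.choice(g, size=g.size, replace=True) for g in groups]
                )
            try:
                stats[i] = statistic(*(a[idx] for a in arrays))
                break
            except (ValueError, ZeroDivisionError):
                redraws += 1
                if redraws >= max_redraws:
                    raise RuntimeError(
                        f"statistic undefined on {redraws} resamples; giving up"
                    )
    low, high = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(low), float(high), redraws


def decision_curve(probs, labels, pt_grid=None) -> dict[str, np.ndarray]:
    """Decision-curve analysis: net benefit across threshold probabilities.

    net benefit(pt) = TP(pt)/n − FP(pt)/n · pt/(1−pt), thresholding the
    risk probabilities at pt.  The treat-all and treat-none reference
    policies are included.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if probs.size == 0:
        raise ValueError("empty input")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if pt_grid is None:
        pt_grid = np.linspace(0.05, 0.95, 19)
    pt = np.asarray(pt_grid, dtype=np.float64)
    if pt.size == 0:
        raise ValueError("empty threshold grid")
    if pt.min() <= 0 or pt.max() >= 1:
        raise ValueError("threshold probabilities must lie strictly in (0, 1)")
    n = probs.size
    prev = labels.mean()
    odds = pt / (1 - pt)
    nb = np.empty_like(pt)
    for i, t in enumerate(pt):
        treat = probs >= t
        tp = (treat & labels).sum()
        fp = (treat & ~labels).sum()
        nb[i] = tp / n - fp / n * odds[i]
    return {
        "thresholds": pt,
        "net_benefit": nb,
        "treat_all": prev - (1 - prev) * odds,
        "treat_none": np.zeros_like(pt),
    }


def gain_report(metrics_single: dict, metrics_combined: dict) -> dict[str, float | None]:
    """Relative improvement (%) of each shared metric over the baseline.

    gain = (combined − single) / single × 100.  A metric undefined or
    zero in the baseline yields ``None``.
    """
    gains: dict[str, float | None] = {}
    for key, base in metrics_single.items():
        comb = metrics_combined.get(key)
        if base is None or comb is None or base == 0:
            gains[key] = None
        else:
            gains[key] = (comb - base) / base * 100.0
    return gains
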