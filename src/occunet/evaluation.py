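"""Model evaluation: ROC/AUC, maximum discrimination threshold, extrapolation.

The maximum discrimination threshold (MDT) is the probability cutoff,
scanned on a fixed grid (0.01 by default), that balances the true-presence
rate against the true-absence rate: it minimizes |TPR - TNR|, with the
smallest qualifying threshold returned on ties.  A patch is classified as
breeding iff its predicted probability is *strictly* greater than the
threshold.

The park-wide extrapolation applies the class-conditional accuracy rates
at the MDT to the unsurveyed patches above and below it, rounding each
product half-up, and adds the known breeding count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "EvaluationReport",
    "ExtrapolationResult",
    "roc_auc",
    "mdt",
    "confusion_rates",
    "evaluate",
    "extrapolate_total",
]


def _check_two_class(labels: np.ndarray) -> None:
    if labels.sum() < 1 or (1 - labels).sum() < 1:
        raise ValueError("need at least one presence and one absence label")


def _as_arrays(probs, labels) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    _check_two_class(labels)
    return probs, labels


def roc_auc(probs, labels) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney probability that a random presence outscores a
    random absence, with ties counted half.
    """
    probs, labels = _as_arrays(probs, labels)
    return float(roc_auc_score(labels, probs))


def roc_points(probs, labels) -> np.ndarray:
    """(FPR, TPR, threshold) triples of the empirical ROC curve."""
    probs, labels = _as_arrays(probs, labels)
    fpr, tpr, thr = roc_curve(labels, probs)
    return np.column_stack([fpr, tpr, thr])


def confusion_rates(probs, labels, threshold: float) -> tuple[float, float]:
    """(true_presence_rate, true_absence_rate) at ``prob > threshold``."""
    probs, labels = _as_arrays(probs, labels)
    pred = probs > threshold
    tpr = float(pred[labels == 1].mean())
    tnr = float((~pred[labels == 0]).mean())
    return tpr, tnr


def mdt(probs, labels, grid: float = 0.01) -> float:
    """Maximum discrimination threshold on a fixed grid.

    Scans thresholds 0, grid, 2·grid, ..., 1 and returns the smallest one
    minimizing |true_presence_rate - true_absence_rate|.
    """
    if not 0.0 < grid < 1.0:
        raise ValueError("grid step must be in (0, 1)")
    probs, labels = _as_arrays(probs, labels)
    thresholds = np.arange(0.0, 1.0 + grid / 2, grid)
    pres = probs[labels == 1]
    absn = probs[labels == 0]
    tpr = (pres[None, :] > thresholds[:, None]).mean(axis=1)
    tnr = (absn[None, :] <= thresholds[:, None]).mean(axis=1)
    return float(thresholds[int(np.argmin(np.abs(tpr - tnr)))])


@dataclass
class EvaluationReport:
    """AUC, MDT and the confusion rates at the MDT for one prediction set."""

    auc: float
    mdt: float
    true_presence_rate: float
    true_absence_rate: float
    n_presence: int
    n_absence: int
    threshold_grid: float = 0.01

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(probs, labels, grid: float = 0.01) -> EvaluationReport:
    """Full evaluation: AUC, MDT, and rates at the MDT."""
    probs, labels = _as_arrays(probs, labels)
    t = mdt(probs, labels, grid)
    tpr, tnr = confusion_rates(probs, labels, t)
    return EvaluationReport(
        auc=roc_auc(probs, labels),
        mdt=t,
        true_presence_rate=tpr,
        true_absence_rate=tnr,
        n_presence=int(labels.sum()),
        n_absence=int((1 - labels).sum()),
        threshold_grid=grid,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ExtrapolationResult:
    """Predicted number of breeding patches landscape-wide.

    ``predicted_unsurveyed = round(n_above · rate_above) +
    round(n_below · rate_below)`` (half-up per product) and
    ``predicted_total = n_known_breeding + predicted_unsurveyed``.
    """

    n_known_breeding: int
    n_unsurveyed_above: int
    n_unsurveyed_below: int
    rate_above: float
    rate_below: float
    predicted_unsurveyed: int
    predicted_total: int

    def to_dict(self) -> dict:
        return asdict(self)


def extrapolate_total(
    n_known: int,
    n_above: int,
    rate_above: float,
    n_below: int,
    rate_below: float,
) -> ExtrapolationResult:
    """Extrapolate the landscape-wide breeding total from threshold rates.

    ``rate_above`` is the fraction of above-threshold patches expected to
    breed (the true-presence rate at the MDT); ``rate_below`` the fraction
    of below-threshold patches expected to breed anyway (1 - true-absence
    rate).
    """
    for name, v in (("n_known", n_known), ("n_above", n_above), ("n_below", n_below)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    for name, r in (("rate_above", rate_above), ("rate_below", rate_below)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    predicted_unsurveyed = _round_half_up(n_above * rate_above) + _round_half_up(
        n_below * rate_below
    )
    return ExtrapolationResult(
        n_known_breeding=n_known,
        n_unsurveyed_above=n_above,
        n_unsurveyed_below=n_below,
        rate_above=rate_above,
        rate_below=rate_below,
        predicted_unsurveyed=predicted_unsurveyed,
        predicted_total=n_known + predicted_unsurveyed,
    )
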