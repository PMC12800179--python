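"""Evaluation suite: confusion metrics, ROC/PR, calibration, Wilcoxon test.

"Manipulated" is the positive class throughout. Metrics whose denominator is
zero are reported as ``None`` (an explicit undefined marker), never as 0.
The Wilcoxon signed-rank test is the pinned variant: zero differences
dropped, midranks for ties, statistic ``W = min(W+, W-)``, exact two-sided
p by full sign-assignment enumeration for small samples and a normal
approximation with tie correction beyond.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from ._exceptions import ParameterError, ShapeError
from .data import LABEL_MANIPULATED

#: Largest sample size for which the Wilcoxon p-value is computed exactly.
WILCOXON_EXACT_LIMIT = 12


def _to_binary(values) -> np.ndarray:
    """Map label sequences ("real"/"manipulated" or 0/1) to {0, 1} ints."""
    arr = np.asarray(values)
    if arr.size == 0:
        raise ParameterError("empty label sequence")
    if arr.dtype.kind in "USO":
        return (arr == LABEL_MANIPULATED).astype(np.int64)
    out = arr.astype(np.int64)
    if not np.isin(out, (0, 1)).all():
        raise ParameterError("numeric labels must be 0/1")
    return out


@dataclass
class ConfusionCounts:
    """Counts with "manipulated" as the positive class."""

    true_real: int  # TN: real predicted real
    true_manip: int  # TP: manipulated predicted manipulated
    false_pos: int  # real predicted manipulated
    false_neg: int  # manipulated predicted real

    @property
    def n(self) -> int:
        return self.true_real + self.true_manip + self.false_pos + self.false_neg


def metrics_from_counts(counts: ConfusionCounts) -> dict[str, Optional[float]]:
    """Accuracy/precision/recall/F1 from counts; None where undefined."""
    tn, tp, fp, fn = counts.true_real, counts.true_manip, counts.false_pos, counts.false_neg
    n = counts.n
    if n == 0:
        raise ParameterError("empty confusion counts")
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def confusion_and_metrics(labels, predictions) -> tuple[ConfusionCounts, dict[str, Optional[float]]]:
    """Confusion counts and scalar metrics for hard predictions."""
    y = _to_binary(labels)
    p = _to_binary(predictions)
    if y.shape != p.shape:
        raise ShapeError(f"labels shape {y.shape} != predictions shape {p.shape}")
    counts = ConfusionCounts(
        true_real=int(np.sum((y == 0) & (p == 0))),
        true_manip=int(np.sum((y == 1) & (p == 1))),
        false_pos=int(np.sum((y == 0) & (p == 1))),
        false_neg=int(np.sum((y == 1) & (p == 0))),
    )
    return counts, metrics_from_counts(counts)


def _check_scores(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = _to_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ShapeError(f"labels shape {y.shape} != scores shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ParameterError("scores contain non-finite values")
    return y, s


def roc_auc(labels, scores) -> tuple[Optional[float], dict[str, np.ndarray]]:
    """AUC (rank/pair convention: ties count one half) plus ROC points.

    Returns ``(None, {})`` when only one class is present.
    """
    y, s = _check_scores(labels, scores)
    if len(np.unique(y)) < 2:
        return None, {}
    fpr, tpr, thresholds = roc_curve(y, s)
    return float(roc_auc_score(y, s)), {"fpr": fpr, "tpr": tpr, "thresholds": thresholds}


def pr_curve(labels, scores) -> tuple[Optional[float], dict[str, np.ndarray]]:
    """Average precision (step interpolation) plus PR points."""
    y, s = _check_scores(labels, scores)
    if len(np.unique(y)) < 2:
        return None, {}
    precision, recall, thresholds = precision_recall_curve(y, s)
    return float(average_precision_score(y, s)), {
        "precision": precision,
        "recall": recall,
        "thresholds": thresholds,
    }


@dataclass
class CalibrationBin:
    mean_score: float
    fraction_positive: float
    count: int


def calibration_curve(labels, scores, n_bins: int = 10) -> list[CalibrationBin]:
    """Reliability table over equal-width bins of [0, 1]; empty bins omitted.

    Bin index is ``min(floor(score * n_bins), n_bins - 1)`` so a score of
    exactly 1.0 lands in the last bin. Bin counts sum to n.
    """
    if n_bins < 1:
        raise ParameterError(f"n_bins must be >= 1, got {n_bins}")
    y, s = _check_scores(labels, scores)
    if s.min() < 0 or s.max() > 1:
        raise ParameterError("calibration scores must lie in [0, 1]")
    idx = np.minimum((s * n_bins).astype(np.int64), n_bins - 1)
    bins = []
    for b in range(n_bins):
        members = idx == b
        count = int(members.sum())
        if count:
            bins.append(
                CalibrationBin(
                    mean_score=float(s[members].mean()),
                    fraction_positive=float(y[members].mean()),
                    count=count,
                )
            )
    return bins


def probability_summary(scores) -> dict[str, float]:
    """Median and quartiles (linear interpolation convention)."""
    s = np.asarray(scores, dtype=np.float64)
    if s.size == 0:
        raise ParameterError("empty score sequence")
    q25, q50, q75 = np.percentile(s, [25, 50, 75])
    return {"median": float(q50), "iqr_low": float(q25), "iqr_high": float(q75)}


def wilcoxon_signed_rank(series_a, series_b) -> tuple[Optional[float], float]:
    """Paired two-sided Wilcoxon signed-rank test.

    Returns ``(W, p)`` with ``W = min(W+, W-)`` over the nonzero paired
    differences (midranks for tied magnitudes). Exact p by enumerating all
    sign assignments when the effective sample size is at most
    :data:`WILCOXON_EXACT_LIMIT`; a normal approximation with tie correction
    otherwise. All-zero differences give ``(None, 1.0)`` by convention.
    """
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError("paired series must be 1-D and equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return None, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    total = n * (n + 1) / 2.0

    if n <= WILCOXON_EXACT_LIMIT:
        # All 2^n sign assignments of the (mid)ranks.
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        sums = bits @ ranks
        p = (np.sum(sums <= w + 1e-9) + np.sum(sums >= total - w - 1e-9)) / 2.0**n
        return w, float(min(1.0, p))

    _, tie_counts = np.unique(ranks, return_counts=True)
    mean = total / 2.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return w, 1.0
    z = (w_plus - mean) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * norm.sf(abs(z))))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment for multiple comparisons."""
    p = np.asarray(p_values, dtype=np.float64)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adjusted[i] = min(1.0, running)
    return adjusted.tolist()


@dataclass
class EvaluationReport:
    """Everything measured for one model on one evaluated split."""

    model: str
    counts: ConfusionCounts
    metrics: dict[str, Optional[float]]
    auc: Optional[float]
    average_precision: Optional[float]
    roc_points: dict = field(default_factory=dict)
    pr_points: dict = field(default_factory=dict)
    calibration: list[CalibrationBin] = field(default_factory=list)
    probability: dict[str, float] = field(default_factory=dict)
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        out = asdict(self)
        out["roc_points"] = {k: np.asarray(v).tolist() for k, v in self.roc_points.items()}
        out["pr_points"] = {k: np.asarray(v).tolist() for k, v in self.pr_points.items()}
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_scores(
    labels,
    scores,
    model: str = "model",
    threshold: float = 0.5,
    n_bins: int = 10,
    seed: Optional[int] = None,
) -> EvaluationReport:
    """Full evaluation of probabilistic scores against binary labels.

    Hard predictions use ``score >= threshold`` (the ensemble's convention:
    ties flag "manipulated").
    """
    y, s = _check_scores(labels, scores)
    preds = (s >= threshold).astype(np.int64)
    counts, scalar = confusion_and_metrics(y, preds)
    auc, roc_points = roc_auc(y, s)
    ap, pr_points = pr_curve(y, s)
    return EvaluationReport(
        model=model,
        counts=counts,
        metrics=scalar,
        auc=auc,
        average_precision=ap,
        roc_points=roc_points,
        pr_points=pr_points,
        calibration=calibration_curve(y, np.clip(s, 0, 1), n_bins=n_bins),
        probability=probability_summary(s),
        seed=seed,
    )
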