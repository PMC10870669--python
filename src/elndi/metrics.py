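"""Diagnostic performance: confusion-matrix metrics, ROC/AUC with 95% CI,
and reconstruction of derived metrics from published sensitivity/specificity.

``confusion_from_rates`` deliberately permits fractional counts: when a
report prints sensitivity, specificity and the class sizes, the implied
TP/FP/TN/FN are generally non-integer after rounding, and the downstream
metrics (PPV, NPV, accuracy, MCC, likelihood ratios) are reproduced most
faithfully from the fractional reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import InvalidInputError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts; fractional values are allowed (rate reconstruction)."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")
        if self.total <= 0:
            raise InvalidInputError("confusion matrix must have positive total")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        return cls(
            tp=float(np.sum((yt == 1) & (yp == 1))),
            fp=float(np.sum((yt == 0) & (yp == 1))),
            tn=float(np.sum((yt == 0) & (yp == 0))),
            fn=float(np.sum((yt == 1) & (yp == 0))),
        )

    def rounded(self) -> "ConfusionMatrix":
        """Integer-rounded copy, for sanity checks against count tables."""
        return ConfusionMatrix(round(self.tp), round(self.fp), round(self.tn), round(self.fn))


def confusion_from_rates(
    sensitivity: float, specificity: float, n: float, n_pos: float
) -> ConfusionMatrix:
    """Reconstruct the confusion matrix implied by printed rates and class sizes."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise InvalidInputError("sensitivity and specificity must lie in [0, 1]")
    if n_pos > n or n_pos < 0:
        raise InvalidInputError("need 0 <= n_pos <= n")
    tp = sensitivity * n_pos
    tn = specificity * (n - n_pos)
    return ConfusionMatrix(tp=tp, fp=(n - n_pos) - tn, tn=tn, fn=n_pos - tp)


@dataclass
class MetricsReport:
    """Threshold metrics plus (optionally) AUC with its 95% CI.

    Ratios whose denominator vanishes are reported as None ("undefined")
    rather than propagated as NaN.
    """

    accuracy: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    ppv: Optional[float] = None
    npv: Optional[float] = None
    mcc: Optional[float] = None
    lr_plus: Optional[float] = None
    lr_minus: Optional[float] = None
    auc: Optional[float] = None
    auc_ci_low: Optional[float] = None
    auc_ci_high: Optional[float] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Standard confusion-matrix diagnostics.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn));
    LR+ = sens / (1 - spec); LR- = (1 - sens) / spec.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    lr_plus = None
    if sens is not None and spec is not None:
        lr_plus = sens / (1 - spec) if spec < 1 else None
    lr_minus = None
    if sens is not None and spec is not None:
        lr_minus = (1 - sens) / spec if spec > 0 else None
    return MetricsReport(
        accuracy=_ratio(tp + tn, cm.total),
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        mcc=mcc,
        lr_plus=lr_plus,
        lr_minus=lr_minus,
    )


# ---------------------------------------------------------------------------
# AUC and confidence intervals
# ---------------------------------------------------------------------------


def _validate_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise InvalidInputError("scores and labels must be 1-d and congruent")
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("AUC needs both classes present")
    return s, y


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance probability with tie correction.

    Computed from midranks: AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg),
    where R_pos is the midrank sum of the positive scores.
    """
    s, y = _validate_scores(scores, labels)
    ranks = stats.rankdata(s)  # midranks
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    r_pos = float(np.sum(ranks[y == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance via the structural components V10/V01."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    auc = (np.sum(all_ranks[:m]) - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # P(score_neg < pos_i), ties half
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_with_ci(
    scores,
    labels,
    method: str = "delong",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """AUC with a 95% (by default) confidence interval.

    ``method="delong"`` uses the DeLong asymptotic variance (Wald interval,
    clipped to [0, 1]); ``method="bootstrap"`` uses a seeded stratified
    percentile bootstrap.
    """
    s, y = _validate_scores(scores, labels)
    if method == "delong":
        auc, var = _delong_variance(s, y)
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * math.sqrt(max(var, 0.0))
        return auc, (max(0.0, auc - half), min(1.0, auc + half))
    if method == "bootstrap":
        auc = auc_mann_whitney(s, y)
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        draws = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate(
                [rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
            )
            draws[b] = auc_mann_whitney(s[idx], y[idx])
        lo, hi = np.quantile(draws, [(1 - level) / 2, 0.5 + level / 2])
        return auc, (float(lo), float(hi))
    raise InvalidInputError(f"unknown CI method {method!r}")


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve as an array of (fpr, tpr, threshold) rows, exportable as CSV."""
    from sklearn.metrics import roc_curve

    s, y = _validate_scores(scores, labels)
    fpr, tpr, thr = roc_curve(y, s)
    return np.column_stack([fpr, tpr, thr])


def evaluate_scores(
    scores, labels, threshold: float = 0.5, ci_method: str = "delong", seed: int = 0
) -> MetricsReport:
    """Full report: threshold metrics at ``threshold`` plus AUC with CI."""
    s, y = _validate_scores(scores, labels)
    cm = ConfusionMatrix.from_predictions(y, (s >= threshold).astype(int))
    report = compute_metrics(cm)
    auc, (lo, hi) = auc_with_ci(s, y, method=ci_method, seed=seed)
    report.auc, report.auc_ci_low, report.auc_ci_high = auc, lo, hi
    return report
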