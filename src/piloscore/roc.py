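"""ROC curve, AUC with confidence interval, optimal cutoff and 2x2 metrics.

Orientation is fixed throughout: higher score means positive, and the
classification rule at a threshold t is ``score >= t``.  The trapezoidal
AUC over the tie-aware staircase equals the pairwise concordance
(Mann-Whitney) estimator exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError

logger = logging.getLogger(__name__)

YOUDEN = "youden"
CLOSEST_TOPLEFT = "closest_topleft"

HANLEY_MCNEIL = "hanley_mcneil"
DELONG = "delong"


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    one_minus_specificity: float

    @property
    def specificity(self) -> float:
        return 1.0 - self.one_minus_specificity


@dataclass
class RocCurve:
    """Staircase of operating points, ordered by increasing threshold.

    The first point (threshold at the minimum score) is (1, 1) and a
    sentinel threshold of +inf contributes the (0, 0) endpoint.
    """

    points: list[RocPoint]
    n_pos: int
    n_neg: int

    def __iter__(self):
        return iter(self.points)


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise DegenerateDataError("scores and labels must be 1-d and the same length")
    if not np.isfinite(s).all():
        raise DegenerateDataError("scores must be finite")
    if y.all() or not y.any():
        raise DegenerateDataError("labels must contain both classes")
    return s, y


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """One operating point per distinct score, plus the (0, 0) sentinel."""
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    thresholds = np.unique(s)  # ascending
    points = []
    for t in thresholds:
        pred = s >= t
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        points.append(RocPoint(float(t), tp / n_pos, fp / n_neg))
    points.append(RocPoint(float("inf"), 0.0, 0.0))
    return RocCurve(points=points, n_pos=n_pos, n_neg=n_neg)


@dataclass
class AucEstimate:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    method: str
    p_value: float  # two-sided, against AUC = 0.5

    def as_dict(self) -> dict:
        return {"auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "se": self.se, "method": self.method, "p_value": self.p_value}


def trapezoid_auc(curve: RocCurve) -> float:
    """Area under the staircase by the trapezoidal rule."""
    # points run from (1,1) down to (0,0); reverse so (fpr, tpr) pairs are
    # jointly ascending — plain x-sorting would break vertical segments
    fpr = np.array([p.one_minus_specificity for p in curve.points])[::-1]
    tpr = np.array([p.sensitivity for p in curve.points])[::-1]
    return float(np.trapezoid(tpr, fpr))


def _hanley_mcneil_se(a: float, n_pos: int, n_neg: int) -> float:
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a))
    return float(np.sqrt(max(var, 0.0) / (n_pos * n_neg)))


def _delong_se(s: np.ndarray, y: np.ndarray) -> float:
    pos = s[y]
    neg = s[~y]
    m, n = pos.size, neg.size
    # placement values via midranks
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n          # P(neg < pos_i) with half ties
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # P(pos > neg_j) complement form
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def auc(scores: Sequence[float], labels: Sequence[bool],
        method: str = HANLEY_MCNEIL) -> AucEstimate:
    """Trapezoidal AUC with a normal-approximation CI, clipped to [0, 1].

    ``method`` selects the standard error: Hanley-McNeil (default) or
    DeLong.  The p-value tests AUC = 0.5 with the same SE.
    """
    s, y = _check_scores_labels(scores, labels)
    curve = roc_curve(s, y)
    a = trapezoid_auc(curve)
    if method == HANLEY_MCNEIL:
        se = _hanley_mcneil_se(a, curve.n_pos, curve.n_neg)
    elif method == DELONG:
        se = _delong_se(s, y)
    else:
        raise DegenerateDataError(f"unknown CI method {method!r}")
    if se > 0:
        z = sps.norm.ppf(0.975)
        lo, hi = a - z * se, a + z * se
        p = float(2 * sps.norm.sf(abs(a - 0.5) / se))
    else:
        lo = hi = a
        p = 1.0 if a == 0.5 else 0.0
    return AucEstimate(auc=a, ci_low=float(max(0.0, lo)), ci_high=float(min(1.0, hi)),
                       se=se, method=method, p_value=p)


def youden_cutoff(curve: RocCurve, criterion: str = YOUDEN) -> tuple[float, float, float]:
    """Optimal threshold and its (sensitivity, specificity).

    ``youden`` maximises J = sensitivity + specificity - 1; ties are broken
    toward higher specificity, then higher threshold.  ``closest_topleft``
    minimises the Euclidean distance to (0, 1) with the same tie-breaking.
    """
    finite = [p for p in curve.points if np.isfinite(p.threshold)]
    if not finite:
        raise DegenerateDataError("curve has no finite thresholds")
    if criterion == YOUDEN:
        def key(p):
            return (p.sensitivity + p.specificity - 1.0, p.specificity, p.threshold)
    elif criterion == CLOSEST_TOPLEFT:
        def key(p):
            d = np.hypot(p.one_minus_specificity, 1.0 - p.sensitivity)
            return (-d, p.specificity, p.threshold)
    else:
        raise DegenerateDataError(f"unknown cutoff criterion {criterion!r}")
    best = max(finite, key=key)
    if best.sensitivity + best.specificity - 1.0 <= 0:
        logger.warning("degenerate ROC: best Youden index is %.3f",
                       best.sensitivity + best.specificity - 1.0)
    return best.threshold, best.sensitivity, best.specificity


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    cutoff: float

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


def confusion_at(scores: Sequence[float], labels: Sequence[bool],
                 cutoff: float) -> ConfusionMatrix:
    """Counts under the rule ``score >= cutoff`` => predicted positive."""
    s, y = _check_scores_labels(scores, labels)
    pred = s >= cutoff
    return ConfusionMatrix(tp=int((pred & y).sum()), fp=int((pred & ~y).sum()),
                           fn=int((~pred & y).sum()), tn=int((~pred & ~y).sum()),
                           cutoff=float(cutoff))


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DiagnosticMetrics:
    """Exact fractions; percentages only materialise at the reporting layer."""

    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]

    def as_percentages(self) -> dict:
        """Rounded half-up: 2 decimals for sens/spec, 1 for PPV/NPV."""
        return {
            "sensitivity": _round_half_up(100 * self.sensitivity, 2),
            "specificity": _round_half_up(100 * self.specificity, 2),
            "ppv": None if self.ppv is None else _round_half_up(100 * self.ppv, 1),
            "npv": None if self.npv is None else _round_half_up(100 * self.npv, 1),
        }


def diagnostic_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV from a confusion matrix.

    PPV (NPV) is undefined — reported as ``None`` — when no positive
    (negative) calls were made.
    """
    if cm.n_pos == 0 or cm.n_neg == 0:
        raise DegenerateDataError("confusion matrix needs both classes present")
    sens = cm.tp / cm.n_pos
    spec = cm.tn / cm.n_neg
    ppv = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    npv = cm.tn / (cm.tn + cm.fn) if (cm.tn + cm.fn) > 0 else None
    return DiagnosticMetrics(sensitivity=sens, specificity=spec, ppv=ppv, npv=npv)
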