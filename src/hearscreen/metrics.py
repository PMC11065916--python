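"""Validation statistics for screening calls against the PTA reference.

Covers the 2x2 confusion matrix and its predictive values, Cohen's kappa,
an ROC analysis tailored to integer cumulative risk scores (candidate
cutoffs are midpoints between consecutive observed scores, the convention
under which an optimal cutoff of 3.5 yields the operational threshold 4),
Spearman rank correlation, and an exhaustive reconstructor that recovers
integer 2x2 matrices from published rounded percentages.

Percentages are displayed rounded half-up to one decimal, matching the
reporting precision of screening-validation literature; fractions are kept
at full precision alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MatrixMetrics",
    "ROCPoint",
    "ROCCurve",
    "confusion",
    "matrix_metrics",
    "cohen_kappa",
    "roc_curve",
    "youden_threshold_to_operational",
    "spearman_rho",
    "reconstruct_matrix",
    "round_half_up",
    "pct",
]


def round_half_up(x: float, digits: int = 1) -> float:
    """Round with ties away from zero (half-up), e.g. 0.25 -> 0.3 at 1 digit.

    Published screening metrics use this convention, unlike Python's
    banker's rounding.
    """
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(fraction: Optional[float], digits: int = 1) -> Optional[float]:
    """Fraction -> percentage rounded half-up; passes None through."""
    if fraction is None:
        return None
    return round_half_up(100.0 * fraction, digits)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Screen call (pred) vs reference standard (truth) counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MatrixMetrics:
    """Fractions (None where the denominator is zero) and display percentages."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]

    @property
    def sensitivity_pct(self) -> Optional[float]:
        return pct(self.sensitivity)

    @property
    def specificity_pct(self) -> Optional[float]:
        return pct(self.specificity)

    @property
    def ppv_pct(self) -> Optional[float]:
        return pct(self.ppv)

    @property
    def npv_pct(self) -> Optional[float]:
        return pct(self.npv)

    @property
    def accuracy_pct(self) -> Optional[float]:
        return pct(self.accuracy)


def confusion(pred: Sequence[bool], truth: Sequence[bool]) -> ConfusionMatrix:
    """Cross-tabulate screen calls against the reference standard.

    ``truth`` True means the reference condition (hearing loss) is present.
    """
    if len(pred) != len(truth):
        raise ValueError(
            f"pred and truth lengths differ: {len(pred)} vs {len(truth)}"
        )
    if len(pred) == 0:
        raise ValueError("empty prediction/truth vectors")
    tp = fp = fn = tn = 0
    for p, t in zip(pred, truth):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def matrix_metrics(m: ConfusionMatrix) -> MatrixMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy of a 2x2 matrix.

    Metrics with a zero denominator are returned as None (explicitly
    undefined) rather than NaN.
    """
    if m.total == 0:
        raise ValueError("empty confusion matrix")
    return MatrixMetrics(
        sensitivity=_ratio(m.tp, m.tp + m.fn),
        specificity=_ratio(m.tn, m.tn + m.fp),
        ppv=_ratio(m.tp, m.tp + m.fp),
        npv=_ratio(m.tn, m.tn + m.fn),
        accuracy=_ratio(m.tp + m.tn, m.total),
    )


def cohen_kappa(m: ConfusionMatrix) -> Optional[float]:
    """Chance-corrected agreement (po - pe) / (1 - pe).

    po is observed agreement; pe the agreement expected from the marginals.
    Returns None when pe = 1 (both raters degenerate), where kappa is
    undefined.
    """
    n = m.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = (m.tp + m.tn) / n
    pe = ((m.tp + m.fp) * (m.tp + m.fn) + (m.fn + m.tn) * (m.fp + m.tn)) / (n * n)
    if pe >= 1.0:
        return None
    return (po - pe) / (1.0 - pe)


@dataclass(frozen=True)
class ROCPoint:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class ROCCurve:
    points: tuple[ROCPoint, ...]
    auc: float
    optimal_cutoff: float
    optimal_j: float


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> ROCCurve:
    """ROC analysis of an integer (or ordinal) score against binary truth.

    Higher scores indicate higher risk.  Candidate cutoffs are the
    midpoints between consecutive distinct observed scores plus sentinels
    half a unit below the minimum and above the maximum; a subject is
    called positive when score > cutoff.  AUC is the trapezoidal area over
    (1 - specificity, sensitivity); the optimal cutoff maximises Youden's
    J = sensitivity + specificity - 1, ties broken toward the smallest
    cutoff (the most sensitive operating point).
    """
    if len(scores) != len(labels):
        raise ValueError("scores and labels lengths differ")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")

    distinct = np.unique(s)
    cutoffs = np.concatenate(
        (
            [distinct[0] - 0.5],
            (distinct[:-1] + distinct[1:]) / 2.0,
            [distinct[-1] + 0.5],
        )
    )
    points = []
    for c in cutoffs:
        called = s > c
        sens = float((called & y).sum() / n_pos)
        spec = float((~called & ~y).sum() / n_neg)
        points.append(ROCPoint(cutoff=float(c), sensitivity=sens, specificity=spec))

    fpr = np.array([1.0 - p.specificity for p in points])
    tpr = np.array([p.sensitivity for p in points])
    # sort by (FPR, TPR): ties in FPR must run bottom-up or vertical steps
    # would be traversed downwards and their preceding area cancelled
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))

    best = max(points, key=lambda p: (p.youden_j, -p.cutoff))
    return ROCCurve(
        points=tuple(points),
        auc=auc,
        optimal_cutoff=best.cutoff,
        optimal_j=best.youden_j,
    )


def youden_threshold_to_operational(cutoff: float) -> int:
    """Smallest integer score classified positive at a midpoint cutoff.

    E.g. the ROC-optimal midpoint 3.5 corresponds to the operational rule
    "score >= 4 is high risk".
    """
    doubled = 2.0 * cutoff
    if abs(doubled - round(doubled)) > 1e-9 or round(doubled) % 2 == 0:
        raise ValueError(
            f"cutoff must be a midpoint between integers (x.5), got {cutoff}"
        )
    return math.ceil(cutoff)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Spearman rank correlation with average ranks for ties.

    Returns None (undefined) when either vector is constant.
    """
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return None
    rho = stats.spearmanr(xa, ya).statistic
    return float(rho)


def _rounds_to(num: int, den: int, target_pct: float) -> bool:
    if den == 0:
        return False
    return round_half_up(100.0 * num / den, 1) == round_half_up(target_pct, 1)


def reconstruct_matrix(
    n: int,
    sensitivity_pct: Optional[float] = None,
    specificity_pct: Optional[float] = None,
    ppv_pct: Optional[float] = None,
    npv_pct: Optional[float] = None,
) -> list[ConfusionMatrix]:
    """All integer 2x2 matrices with total ``n`` matching rounded metrics.

    Exhaustively enumerates every non-negative (tp, fp, fn, tn) summing to
    ``n`` and keeps those whose requested metrics round (half-up, one
    decimal, percent) to the given values.  A None constraint is ignored.
    Returns the full solution list — empty when the constraints are
    contradictory, a singleton when the published numbers pin the matrix
    down uniquely.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    for name, v in (
        ("sensitivity_pct", sensitivity_pct),
        ("specificity_pct", specificity_pct),
        ("ppv_pct", ppv_pct),
        ("npv_pct", npv_pct),
    ):
        if v is not None and not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {v}")

    solutions: list[ConfusionMatrix] = []
    for tp in range(n + 1):
        for fp in range(n - tp + 1):
            if ppv_pct is not None and tp + fp > 0 and not _rounds_to(tp, tp + fp, ppv_pct):
                continue
            for fn in range(n - tp - fp + 1):
                tn = n - tp - fp - fn
                if ppv_pct is not None and tp + fp == 0:
                    continue  # PPV undefined, cannot match a printed value
                if sensitivity_pct is not None and not _rounds_to(tp, tp + fn, sensitivity_pct):
                    continue
                if specificity_pct is not None and not _rounds_to(tn, tn + fp, specificity_pct):
                    continue
                if npv_pct is not None and not _rounds_to(tn, tn + fn, npv_pct):
                    continue
                solutions.append(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
    return solutions
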