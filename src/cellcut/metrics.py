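"""Pixel-level segmentation evaluation: confusion counts, accuracy index,
precision/recall/F1, ROC/AUC over a lambda sweep, and a Welch two-sample
t-test on per-image F1 scores.

Two aggregation dialects exist for multi-image batches: pooled counts (sum
the confusion counts, then apply the formulas) and per-image means.  Helpers
for both are provided; single-image evaluation uses pooled trivially.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_image import BinaryMask
from .errors import ContractError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "TTestResult",
    "confusion",
    "report",
    "roc_points",
    "auc",
    "t_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ContractError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricsReport:
    ai: float
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Cross-tabulate predicted vs ground-truth labels pixel by pixel."""
    if pred.shape != truth.shape:
        raise ContractError(f"prediction shape {pred.shape} != truth shape {truth.shape}")
    p = pred.as_bool()
    g = truth.as_bool()
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def report(c: ConfusionCounts) -> MetricsReport:
    """Accuracy index (TP+TN)/total, precision, recall and their harmonic
    mean F1.  Zero-denominator precision/recall is reported as 0 with a
    warning so batch evaluation never aborts."""
    if c.total == 0:
        raise ContractError("cannot report metrics on zero evaluated pixels")
    ai = (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        warnings.warn("no predicted foreground pixels; precision defined as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        warnings.warn("no true foreground pixels; recall defined as 0", stacklevel=2)
        recall = 0.0
    else:
        recall = c.tp / (c.tp + c.fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricsReport(ai=ai, precision=precision, recall=recall, f1=f1)


def roc_points(image, seeds, mode, truth: BinaryMask, lambda_grid) -> list[tuple[float, float]]:
    """One (FPR, TPR) operating point per lambda in the grid.

    The sweep variable is lambda — the only decision variable the method
    exposes; points come back in grid order, un-augmented.
    """
    from .segmenter import segment  # local import: metrics must not cycle at load

    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ContractError("lambda grid must be non-empty")
    pts = []
    for lam in lambda_grid:
        result = segment(image, seeds, mode=mode, lambda1=lam)
        c = confusion(result.mask, truth)
        fpr = c.fp / (c.fp + c.tn) if c.fp + c.tn else 0.0
        tpr = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
        pts.append((fpr, tpr))
    return pts


def auc(points) -> float:
    """Trapezoidal area under the ROC points, augmented with (0,0) and (1,1)."""
    points = list(points)
    if not points:
        raise ContractError("need at least one ROC point")
    pts = sorted({(float(f), float(t)) for f, t in points} | {(0.0, 0.0), (1.0, 1.0)})
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    if (fpr < 0).any() or (fpr > 1).any() or (tpr < 0).any() or (tpr > 1).any():
        raise ContractError("ROC points must lie in the unit square")
    return float(np.trapezoid(tpr, fpr))


def t_test(f1_a, f1_b) -> TTestResult:
    """Welch two-sample t-test on equal-length per-image F1 lists.

    t = (M2 - M1) / sqrt(SD2^2/N + SD1^2/N) with Welch-Satterthwaite degrees
    of freedom and a two-tailed p-value.  Identical lists give t=0, p=1.
    """
    a = np.asarray(f1_a, dtype=np.float64)
    b = np.asarray(f1_b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or len(a) != len(b):
        raise ContractError("samples must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ContractError("need at least 2 observations per group")
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n + v2 / n
    if se2 == 0:
        if m1 == m2:
            return TTestResult(t=0.0, p=1.0, n=n)
        return TTestResult(t=float(np.sign(m2 - m1)) * np.inf, p=0.0, n=n)
    t = (m2 - m1) / np.sqrt(se2)
    df = se2**2 / ((v1 / n) ** 2 / (n - 1) + (v2 / n) ** 2 / (n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), p=float(p), n=n)


def pooled_report(counts) -> MetricsReport:
    """Sum confusion counts over images, then apply the formulas."""
    counts = list(counts)
    if not counts:
        raise ContractError("need at least one confusion record")
    total = counts[0]
    for c in counts[1:]:
        total = total + c
    return report(total)


def per_image_f1(counts) -> tuple[float, float]:
    """Mean and std (ddof=1 when possible) of per-image F1 scores."""
    scores = [report(c).f1 for c in counts]
    arr = np.asarray(scores)
    return float(arr.mean()), float(arr.std(ddof=1) if len(arr) > 1 else 0.0)
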