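"""Confusion matrices and the five map-evaluation statistics.

Given a binary delimitation map and ground truth (labelled points or a
reference map), this module builds 2x2 confusion counts and derives:

* sensitivity  = TP / (TP + FN)   (true positive rate)
* specificity  = TN / (TN + FP)   (true negative rate)
* Cohen's kappa = (p_o - p_e) / (1 - p_e), with observed agreement
  p_o = (TP + TN) / n and chance agreement from the marginal products
  p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / n²
* underprediction = FN / (FN + TN) — the share of predicted-absence
  evaluation units that actually belong to the focal biome (false-omission
  rate)
* overprediction  = FP / (FP + TP) — the share of predicted-presence units
  that do not belong to it (false-discovery rate)

Counts are always carried alongside derived statistics so every reported
number is auditable.  Display rounding is half-up to 2 decimals; undefined
statistics (zero denominator, p_e = 1) are NaN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .grids import BinaryMap, LabelledPoint

__all__ = [
    "ConfusionCounts",
    "ValidationMetrics",
    "confusion_from_points",
    "compute_metrics",
    "map_agreement_kappa",
    "compare_models_wilcoxon",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.005 -> 0.01), unlike banker's rounding."""
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n < 1:
            raise ValueError("confusion matrix must contain at least one unit")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def scaled(self, k: int) -> "ConfusionCounts":
        return ConfusionCounts(self.tp * k, self.fp * k, self.tn * k, self.fn * k)


@dataclass(frozen=True)
class ValidationMetrics:
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    kappa: float
    underprediction: float
    overprediction: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {
            "sensitivity": round_half_up(self.sensitivity, ndigits),
            "specificity": round_half_up(self.specificity, ndigits),
            "kappa": round_half_up(self.kappa, ndigits),
            "underprediction": round_half_up(self.underprediction, ndigits),
            "overprediction": round_half_up(self.overprediction, ndigits),
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionCounts) -> ValidationMetrics:
    """Derive the five evaluation statistics from a 2x2 confusion matrix."""
    n = c.n
    p_o = (c.tp + c.tn) / n
    p_e = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / (n * n)
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else math.nan
    if math.isnan(kappa):
        warnings.warn("kappa undefined: chance agreement p_e = 1", stacklevel=2)
    return ValidationMetrics(
        counts=c,
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        kappa=kappa,
        underprediction=_ratio(c.fn, c.fn + c.tn),
        overprediction=_ratio(c.fp, c.fp + c.tp),
    )


def confusion_from_points(
    points: list[LabelledPoint],
    positive_label: str,
    bmap: BinaryMap,
) -> tuple[ConfusionCounts, int]:
    """Cross-tabulate labelled points against a binary map.

    Positive-label points on 1-cells are TP, on 0-cells FN; all other labels
    on 1-cells are FP, on 0-cells TN.  Points outside the extent or on
    no-data cells are excluded; their count is returned for logging.
    """
    if not any(p.label == positive_label for p in points):
        raise ValueError(f"no points carry the positive label {positive_label!r}")
    xs = np.array([p.x for p in points])
    ys = np.array([p.y for p in points])
    pos = np.array([p.label == positive_label for p in points])
    rr, cc, inside = bmap.grid.points_to_cells(xs, ys)
    vals = np.full(len(points), np.nan)
    vals[inside] = bmap.values[rr[inside], cc[inside]]
    usable = ~np.isnan(vals)
    pred = vals == 1.0
    tp = int((pos & pred & usable).sum())
    fn = int((pos & ~pred & usable).sum())
    fp = int((~pos & pred & usable).sum())
    tn = int((~pos & ~pred & usable).sum())
    return ConfusionCounts(tp, fp, tn, fn), int((~usable).sum())


def _cross_tab(a: np.ndarray, b: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(((a == 1) & (b == 1)).sum()),
        fp=int(((a == 1) & (b == 0)).sum()),
        tn=int(((a == 0) & (b == 0)).sum()),
        fn=int(((a == 0) & (b == 1)).sum()),
    )


def map_agreement_kappa(map_a: BinaryMap, map_b: BinaryMap) -> float:
    """Cohen's kappa of two aligned binary maps over jointly valid cells.

    Symmetric in its arguments; NaN (with a warning) when either map shows a
    single class on the shared support, where chance agreement saturates.
    """
    if not map_a.grid.aligned(map_b.grid):
        raise ValueError("maps are not on the same grid")
    joint = map_a.valid & map_b.valid
    if not joint.any():
        raise ValueError("maps share no valid cells")
    a = map_a.values[joint]
    b = map_b.values[joint]
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        warnings.warn("kappa undefined: a map is single-class", stacklevel=2)
        return math.nan
    return compute_metrics(_cross_tab(a, b)).kappa


def compare_models_wilcoxon(
    scores_a: np.ndarray, scores_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two score samples.

    Intended use: per-point agreement indicators (1 = validation point
    correctly classified) from two delimitation maps over the same points.
    Returns the rank-sum statistic W of the first sample (W = U1 +
    n1(n1+1)/2) and the p-value, tie-corrected with a normal approximation
    for large samples.  When every value across both samples is tied the
    test carries no information: W is still returned but p = 1, with a
    warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score samples must be non-empty")
    n1 = a.size
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied across both samples; p set to 1", stacklevel=2)
        w = n1 * (n1 + 1) / 2 + n1 * b.size / 2  # mid-rank sum under total ties
        return float(w), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    w = float(res.statistic) + n1 * (n1 + 1) / 2
    return w, float(res.pvalue)
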