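"""Screening thresholds, confusion-matrix diagnostics and ROC analysis.

The NCIT screening threshold is constructed from the referent fever cut and
the offset model as T*_IR = T* + Δμ + δT, where δT ranges over ±LOA: at
δT = 0 the threshold sits at the expected NCIT reading of a subject exactly
at the fever cut; pushing δT to +LOA trades sensitivity for specificity and
−LOA the reverse.  A subject is condition-positive when the reference
temperature is at or above T* and screen-positive when the test reading is
at or above T*_IR (both inclusive, matching the "greater than or equal to"
fever definition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import OffsetModel, round_display

__all__ = [
    "ScreeningThreshold",
    "ConfusionMetrics",
    "RocCurve",
    "screening_threshold",
    "classify",
    "specificity_sweep",
    "roc_curve",
    "equal_error_threshold",
    "DegenerateRocError",
    "NoCrossingError",
]


class DegenerateRocError(ValueError):
    """ROC requested on a cohort with only one condition class."""


class NoCrossingError(ValueError):
    """Sensitivity and specificity never cross on the supplied grid."""


@dataclass(frozen=True)
class ScreeningThreshold:
    """An NCIT screening threshold T*_IR = T* + Δμ + δT (all °F)."""

    t_star: float
    delta_mu: float
    delta_t: float
    t_star_ir: float

    @property
    def display(self) -> float:
        return round_display(self.t_star_ir, 1)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and derived rates (rates in percent)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    fpr: float
    fnr: float
    ppv: float
    npv: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RocCurve:
    """ROC points (threshold, sensitivity %, specificity %) plus trapezoid AUC."""

    points: tuple[tuple[float, float, float], ...]
    auc: float


def screening_threshold(t_star: float, model: OffsetModel, delta_t: float = 0.0,
                        *, strict: bool = True) -> ScreeningThreshold:
    """Build T*_IR from the fever cut and the offset model.

    ``delta_t`` must lie within ±LOA (the plausible device-offset envelope);
    pass ``strict=False`` to allow values outside it.
    """
    if strict and abs(delta_t) > model.loa_halfwidth + 1e-9:
        raise ValueError(
            f"delta_t {delta_t} outside the agreement envelope "
            f"±{model.loa_halfwidth:.3f} °F"
        )
    return ScreeningThreshold(
        t_star=t_star,
        delta_mu=model.delta_mu,
        delta_t=delta_t,
        t_star_ir=t_star + model.delta_mu + delta_t,
    )


def _rates(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    pos, neg = tp + fn, tn + fp
    se = 100.0 * tp / pos if pos else float("nan")
    sp = 100.0 * tn / neg if neg else float("nan")
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=se,
        specificity=sp,
        fpr=100.0 - sp if neg else float("nan"),
        fnr=100.0 - se if pos else float("nan"),
        ppv=100.0 * tp / (tp + fp) if tp + fp else float("nan"),
        npv=100.0 * tn / (tn + fn) if tn + fn else float("nan"),
    )


def classify(ref_temps: Sequence[float], test_temps: Sequence[float],
             t_star: float, t_star_ir: float) -> ConfusionMetrics:
    """Confusion matrix for screening paired (reference, test) temperatures.

    Condition positive iff reference ≥ t_star; screen positive iff test
    ≥ t_star_ir.  Rates are percentages; SE + FNR = SP + FPR = 100 exactly.
    """
    ref = np.asarray(ref_temps, dtype=float)
    test = np.asarray(test_temps, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(
            f"reference and test lengths differ: {ref.shape} vs {test.shape}"
        )
    cond = ref >= t_star
    screen = test >= t_star_ir
    tp = int(np.count_nonzero(cond & screen))
    fn = int(np.count_nonzero(cond & ~screen))
    fp = int(np.count_nonzero(~cond & screen))
    tn = int(np.count_nonzero(~cond & ~screen))
    return _rates(tp, fp, tn, fn)


def specificity_sweep(afebrile_test_temps: Sequence[float],
                      grid: Sequence[float]) -> list[tuple[float, float]]:
    """Specificity at each threshold for condition-negative subjects only."""
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    x = np.asarray(afebrile_test_temps, dtype=float)
    return [
        (float(t), float(100.0 * np.count_nonzero(x < t) / x.size)) for t in grid
    ]


def default_roc_grid(test_temps: Sequence[float], step: float = 0.1) -> np.ndarray:
    """0.1 °F grid spanning [min − 1, max + 1] of the test readings."""
    x = np.asarray(test_temps, dtype=float)
    lo, hi = float(x.min()) - 1.0, float(x.max()) + 1.0
    return np.arange(lo, hi + step / 2, step)


def roc_curve(ref_temps: Sequence[float], test_temps: Sequence[float],
              t_star: float, grid: Sequence[float] | None = None) -> RocCurve:
    """ROC over a threshold grid; AUC by trapezoid on (FPR, SE) fractions."""
    ref = np.asarray(ref_temps, dtype=float)
    test = np.asarray(test_temps, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("reference and test lengths differ")
    cond = ref >= t_star
    n_pos = int(cond.sum())
    n_neg = int(ref.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        missing = "condition-positive" if n_pos == 0 else "condition-negative"
        raise DegenerateRocError(f"cohort contains no {missing} subjects")
    if grid is None:
        grid = default_roc_grid(test)
    grid = np.sort(np.asarray(grid, dtype=float))
    pos_sorted = np.sort(test[cond])
    neg_sorted = np.sort(test[~cond])
    # count of readings >= threshold via searchsorted on the sorted values
    se = 100.0 * (n_pos - np.searchsorted(pos_sorted, grid, side="left")) / n_pos
    fp = n_neg - np.searchsorted(neg_sorted, grid, side="left")
    sp = 100.0 * (n_neg - fp) / n_neg
    points = tuple(
        (float(t), float(s), float(p)) for t, s, p in zip(grid, se, sp)
    )
    # Trapezoid over (FPR, SE) as fractions, anchored at (0,0) and (1,1),
    # sorted by FPR with ties broken toward higher sensitivity.
    fpr = np.concatenate([[0.0], (100.0 - sp) / 100.0, [1.0]])
    tpr = np.concatenate([[0.0], se / 100.0, [1.0]])
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocCurve(points=points, auc=auc)


def equal_error_threshold(curve: RocCurve) -> tuple[float, float]:
    """Threshold where sensitivity equals specificity, by linear interpolation.

    Returns (threshold °F, common rate %).  Raises :class:`NoCrossingError`
    when SE − SP never changes sign across the grid.
    """
    pts = sorted(curve.points)
    if len(pts) < 2:
        raise NoCrossingError("need at least 2 ROC points")
    gaps = [se - sp for _, se, sp in pts]
    for (t0, se0, sp0), (t1, se1, sp1), g0, g1 in zip(
        pts, pts[1:], gaps, gaps[1:]
    ):
        if g0 == 0:
            return t0, se0
        if g0 * g1 < 0:
            w = g0 / (g0 - g1)
            thr = t0 + w * (t1 - t0)
            rate = se0 + w * (se1 - se0)
            return float(thr), float(rate)
    if gaps[-1] == 0:
        return pts[-1][0], pts[-1][1]
    raise NoCrossingError("sensitivity and specificity do not cross on the grid")
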