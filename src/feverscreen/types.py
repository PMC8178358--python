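"""Shared domain types for the fever-screening validation pipeline.

All temperatures are degrees Fahrenheit end to end; Kelvin appears only in
:mod:`feverscreen.device` for radiometric calculations.  Display rounding is
round-half-away-from-zero (1 decimal for temperatures, 2 for derived model
parameters); every computation runs at full precision and rounds only when a
number is *reported*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

__all__ = [
    "PairedRecord",
    "Cohort",
    "ConfidenceSpec",
    "RunConfig",
    "OffsetModel",
    "round_display",
    "ScaleError",
    "InsufficientDataError",
]

#: Operating range of the temporal-artery reference thermometer, °F.
TAT_RANGE_F = (61.0, 110.0)

#: CDC referent fever definition: temperature greater than or equal to this, °F.
DEFAULT_FEVER_CUT_F = 100.0


class ScaleError(ValueError):
    """A cohort operation was applied on the wrong temperature scale."""


class InsufficientDataError(ValueError):
    """Fewer observations than the statistic requires."""


def round_display(x: float, decimals: int = 1) -> float:
    """Round half away from zero, as printed clinical tables do.

    Python's built-in ``round`` is banker's rounding (93.85 → 93.8); clinical
    reporting rounds 93.85 → 93.9.
    """
    if not math.isfinite(x):
        return x
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


@dataclass(frozen=True)
class PairedRecord:
    """One subject: reference (temporal-artery) temperature plus NCIT readings.

    Parameters
    ----------
    subject_id
        Opaque identifier.
    t_ref
        Reference temperature (T_TAT), °F; must fall within the reference
        device's operating range.
    t_ncit
        Mapping from distance label (e.g. ``"1ft"``) to the NCIT reading at
        that distance, °F.
    age, sex
        Optional demographics; ``None`` / ``"unreported"`` when absent.
    """

    subject_id: str
    t_ref: float
    t_ncit: Mapping[str, float]
    age: int | None = None
    sex: str = "unreported"

    def __post_init__(self) -> None:
        lo, hi = TAT_RANGE_F
        if not (lo <= self.t_ref <= hi):
            raise ValueError(
                f"reference temperature {self.t_ref} °F outside device range "
                f"[{lo}, {hi}] °F (subject {self.subject_id})"
            )
        for label, value in self.t_ncit.items():
            if not math.isfinite(value):
                raise ValueError(
                    f"non-finite NCIT reading at {label} for subject {self.subject_id}"
                )
        if self.sex not in ("F", "M", "unreported"):
            raise ValueError(f"sex must be F, M or unreported, got {self.sex!r}")


@dataclass
class Cohort:
    """A single-method cohort of body temperatures on a stated scale.

    ``source_scale`` records whether the temperatures are oral readings or on
    the temporal-artery (TAT) scale; the oral→TAT adjustment in
    :func:`feverscreen.synth.oral_to_tat` flips it exactly once.
    """

    temps: Sequence[float]
    source_scale: str = "tat"
    febrile_cut: float = DEFAULT_FEVER_CUT_F

    def __post_init__(self) -> None:
        if len(self.temps) < 1:
            raise InsufficientDataError("cohort must contain at least one temperature")
        if self.source_scale not in ("oral", "tat"):
            raise ValueError(f"source_scale must be 'oral' or 'tat', got {self.source_scale!r}")

    @property
    def n(self) -> int:
        return len(self.temps)

    @property
    def febrile_count(self) -> int:
        """Number of temperatures at or above the febrile cut (inclusive)."""
        return int(sum(1 for t in self.temps if t >= self.febrile_cut))


@dataclass(frozen=True)
class ConfidenceSpec:
    """Confidence level plus the Student-t multiplier it implies.

    The multiplier is the two-sided critical value t_{1-(1-level)/2, df};
    for the 51-subject study (df = 50, level 0.95) it is 2.009.
    """

    level: float = 0.95
    df: int = 50
    t_multiplier: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("confidence level must be in (0, 1)")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        expected = float(stats.t.ppf(1.0 - (1.0 - self.level) / 2.0, self.df))
        if self.t_multiplier is None:
            object.__setattr__(self, "t_multiplier", expected)
        elif abs(self.t_multiplier - expected) > 1e-3:
            raise ValueError(
                f"t_multiplier {self.t_multiplier} inconsistent with "
                f"t({self.df}) at level {self.level} (expected {expected:.4f})"
            )


@dataclass(frozen=True)
class OffsetModel:
    """Normal measurement-difference model ΔT ~ N(Δμ, ρ²).

    ``delta_mu`` is the Bland–Altman bias (test minus reference) and ``rho``
    the SD of the differences, equal to the limits-of-agreement half-width
    divided by 1.96.  Defaults are the published 1-ft Fluke 561 vs TAT values.
    """

    delta_mu: float = -6.15
    rho: float = 1.45
    loa_halfwidth: float | None = None

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        if self.loa_halfwidth is None:
            object.__setattr__(self, "loa_halfwidth", 1.96 * self.rho)
        elif abs(self.rho - self.loa_halfwidth / 1.96) > 5e-3:
            raise ValueError(
                f"rho {self.rho} inconsistent with loa_halfwidth/1.96 = "
                f"{self.loa_halfwidth / 1.96:.4f}"
            )


@dataclass
class RunConfig:
    """Run-level configuration echoed into every report."""

    seed: int = 0
    fever_cut_ref: float = DEFAULT_FEVER_CUT_F
    distances: Mapping[str, float] = field(
        default_factory=lambda: {"1ft": 1.0, "3ft": 3.0, "6ft": 6.0}
    )
    rounding_temp: int = 1
    rounding_param: int = 2
    mc_reps: int = 5000

    def __post_init__(self) -> None:
        if self.mc_reps < 1000:
            raise ValueError("mc_reps must be >= 1000 for stable Monte-Carlo p-values")
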