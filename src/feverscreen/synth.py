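"""Synthetic study and cohort generators plus the offset-model transformation.

The paired-study generator emulates a 51-subject healthy-worker comparison of
a noncontact infrared thermometer (NCIT) against a temporal-artery reference:
reference temperatures come from a bounded normal, each distance's NCIT
reading is the reference plus a (possibly skewed) difference term, truncated
to the published per-distance range by rejection so the in-range shape is
preserved.  The cohort generator emulates a large outpatient reference
population (mean 98.8 °F on the TAT scale, SD 0.7 °F) whose febrile tail
drives sensitivity estimates.  ``simulate_ncit`` applies the measurement
model ΔT ~ N(Δμ, ρ²) to turn reference temperatures into simulated NCIT
readings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .types import Cohort, OffsetModel, PairedRecord, ScaleError

__all__ = [
    "DistanceProfile",
    "StudyGenSpec",
    "CohortGenSpec",
    "generate_paired_study",
    "generate_reference_cohort",
    "oral_to_tat",
    "simulate_ncit",
    "DegenerateSpecError",
]

#: Default oral→temporal-artery scale adjustment, °F.
ORAL_TO_TAT_ADJUSTMENT_F = 0.8


class DegenerateSpecError(ValueError):
    """Truncation bounds exclude essentially all of the distribution's mass."""


@dataclass(frozen=True)
class DistanceProfile:
    """Difference-term model for one NCIT distance.

    ``bias`` and ``sd`` are the mean and SD of the difference (NCIT − reference)
    before truncation; ``bounds`` clip the resulting *reading*; ``skew`` is a
    skew-normal shape parameter (0 = symmetric normal).
    """

    bias: float
    sd: float
    bounds: tuple[float, float]
    skew: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds min must be < max")

    def _skewnorm_params(self) -> tuple[float, float, float]:
        """(shape, loc, scale) giving exactly mean=bias, sd=sd."""
        a = self.skew
        delta = a / math.sqrt(1.0 + a * a)
        adj = math.sqrt(max(1.0 - 2.0 * delta * delta / math.pi, 1e-12))
        scale = self.sd / adj if self.sd > 0 else 0.0
        loc = self.bias - scale * delta * math.sqrt(2.0 / math.pi)
        return a, loc, scale


def _default_profiles() -> Mapping[str, DistanceProfile]:
    # Per-distance parameters match the published healthy-worker summary:
    # 1 ft carries the Bland-Altman difference model (bias -6.15, SD 2.84/1.96);
    # 3/6 ft biases are the group-mean offsets from the 98.4 reference mean with
    # the published SDs and min/max, skewed so they fail normality at n = 51.
    return {
        "1ft": DistanceProfile(bias=-6.15, sd=2.84 / 1.96, bounds=(88.9, 95.3), skew=0.0),
        "3ft": DistanceProfile(bias=-7.1, sd=1.72, bounds=(87.4, 94.2), skew=-20.0),
        "6ft": DistanceProfile(bias=-8.8, sd=1.68, bounds=(86.6, 92.9), skew=-20.0),
    }


@dataclass(frozen=True)
class StudyGenSpec:
    """Generator parameters for the paired healthy-worker study."""

    n: int = 51
    ref_mean: float = 98.4
    ref_sd: float = 0.59
    ref_bounds: tuple[float, float] = (97.1, 99.6)
    profiles: Mapping[str, DistanceProfile] = field(default_factory=_default_profiles)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.ref_sd < 0:
            raise ValueError("ref_sd must be nonnegative")
        if self.ref_bounds[0] >= self.ref_bounds[1]:
            raise ValueError("ref_bounds min must be < max")


@dataclass(frozen=True)
class CohortGenSpec:
    """Generator parameters for the large reference cohort (TAT scale)."""

    n: int = 578_522
    mean: float = 98.8
    sd: float = 0.7
    febrile_cut: float = 100.0
    tail_mode: str = "plain_normal"
    target_prevalence: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.tail_mode not in ("plain_normal", "calibrated_mixture"):
            raise ValueError(f"unknown tail_mode {self.tail_mode!r}")
        if self.tail_mode == "calibrated_mixture":
            if self.target_prevalence is None:
                raise ValueError("calibrated_mixture requires target_prevalence")
            if not (0.0 < self.target_prevalence < 0.5):
                raise ValueError("target_prevalence must lie in (0, 0.5)")


def _mass_in_bounds(dist, lo: float, hi: float) -> float:
    return float(dist.cdf(hi) - dist.cdf(lo))


def _rejection_sample(dist, n: int, lo: float, hi: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw n variates from ``dist`` conditioned on [lo, hi] by rejection."""
    mass = _mass_in_bounds(dist, lo, hi)
    if mass < 1e-3:
        raise DegenerateSpecError(
            f"bounds [{lo}, {hi}] retain only {mass:.2e} of the distribution's mass"
        )
    out = np.empty(0)
    while out.size < n:
        batch = max(int((n - out.size) / mass * 1.2) + 16, 32)
        draws = dist.rvs(size=batch, random_state=rng)
        out = np.concatenate([out, draws[(draws >= lo) & (draws <= hi)]])
    return out[:n]


def generate_paired_study(spec: StudyGenSpec) -> list[PairedRecord]:
    """Generate one synthetic paired study; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    if spec.ref_sd == 0:
        lo, hi = spec.ref_bounds
        if not (lo <= spec.ref_mean <= hi):
            raise DegenerateSpecError("ref_mean outside ref_bounds with zero spread")
        t_ref = np.full(spec.n, spec.ref_mean)
    else:
        t_ref = _rejection_sample(
            stats.norm(spec.ref_mean, spec.ref_sd), spec.n, *spec.ref_bounds, rng=rng
        )

    readings: dict[str, np.ndarray] = {}
    for label, prof in spec.profiles.items():
        lo, hi = prof.bounds
        if prof.sd == 0:
            vals = t_ref + prof.bias
            if np.any((vals < lo) | (vals > hi)):
                raise DegenerateSpecError(
                    f"zero-spread profile {label!r} lands outside bounds [{lo}, {hi}]"
                )
        else:
            a, dloc, dscale = prof._skewnorm_params()
            vals = np.empty(spec.n)
            todo = np.arange(spec.n)
            # Reading-level truncation: redraw the difference term per subject
            # until t_ref + d lands in bounds, preserving in-range shape.
            diff_dist = stats.skewnorm(a, loc=dloc, scale=dscale)
            centre_mass = _mass_in_bounds(
                stats.skewnorm(a, loc=dloc + float(np.mean(t_ref)), scale=dscale), lo, hi
            )
            if centre_mass < 1e-3:
                raise DegenerateSpecError(
                    f"profile {label!r} bounds [{lo}, {hi}] retain only "
                    f"{centre_mass:.2e} of the reading distribution's mass"
                )
            for _ in range(10_000):
                if todo.size == 0:
                    break
                d = diff_dist.rvs(size=todo.size, random_state=rng)
                cand = t_ref[todo] + d
                ok = (cand >= lo) & (cand <= hi)
                vals[todo[ok]] = cand[ok]
                todo = todo[~ok]
            else:
                raise DegenerateSpecError(
                    f"rejection sampling for profile {label!r} failed to converge"
                )
        readings[label] = vals

    return [
        PairedRecord(
            subject_id=f"S{i + 1:03d}",
            t_ref=float(t_ref[i]),
            t_ncit={label: float(readings[label][i]) for label in spec.profiles},
        )
        for i in range(spec.n)
    ]


def generate_reference_cohort(spec: CohortGenSpec) -> Cohort:
    """Generate a synthetic reference cohort; deterministic given ``spec.seed``.

    ``plain_normal`` draws everyone from N(mean, sd²).  ``calibrated_mixture``
    fixes the febrile prevalence: each subject is febrile with probability
    ``target_prevalence`` and drawn from the same normal truncated above the
    cut, otherwise from it truncated below.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.tail_mode == "plain_normal":
        temps = rng.normal(spec.mean, spec.sd, size=spec.n)
    else:
        a_cut = (spec.febrile_cut - spec.mean) / spec.sd
        febrile = rng.random(spec.n) < spec.target_prevalence
        temps = np.empty(spec.n)
        below = stats.truncnorm(-np.inf, a_cut, loc=spec.mean, scale=spec.sd)
        above = stats.truncnorm(a_cut, np.inf, loc=spec.mean, scale=spec.sd)
        n_feb = int(febrile.sum())
        temps[~febrile] = below.rvs(size=spec.n - n_feb, random_state=rng)
        temps[febrile] = above.rvs(size=n_feb, random_state=rng)
    return Cohort(temps=temps, source_scale="tat", febrile_cut=spec.febrile_cut)


def oral_to_tat(cohort: Cohort, adjustment: float = ORAL_TO_TAT_ADJUSTMENT_F) -> Cohort:
    """Shift an oral-scale cohort onto the temporal-artery scale.

    Oral thermometry reads systematically below the temporal-artery reference;
    the published adjustment is +0.8 °F.  Applying it to a cohort already on
    the TAT scale raises :class:`ScaleError`.
    """
    if cohort.source_scale != "oral":
        raise ScaleError("oral_to_tat requires an oral-scale cohort")
    temps = np.asarray(cohort.temps, dtype=float) + adjustment
    return Cohort(temps=temps, source_scale="tat", febrile_cut=cohort.febrile_cut)


def simulate_ncit(
    ref_temps: Sequence[float],
    model: OffsetModel,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate NCIT readings: reference plus independent N(Δμ, ρ²) offsets.

    Order and length match the input; deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = np.asarray(ref_temps, dtype=float)
    if model.rho == 0:
        return ref + model.delta_mu
    return ref + rng.normal(model.delta_mu, model.rho, size=ref.shape)
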