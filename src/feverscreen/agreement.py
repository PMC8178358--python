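"""Descriptive statistics, normality screening and Bland–Altman comparison.

The Bland–Altman analysis quantifies agreement between two measurement
methods by the per-subject differences d_i = test_i − reference_i: the bias
is mean(d), the 95% limits of agreement (LOA) are bias ± 1.96·SD(d), and
confidence intervals use the Student-t multiplier at n − 1 degrees of
freedom (bias CI half-width t·s/√n, each LOA CI half-width t·s·√(3/n), the
classical large-sample form).  The fitted offset model ΔT ~ N(Δμ, ρ²) with
Δμ = bias and ρ = SD(d) = LOA/1.96 feeds the screening simulation.

Normality is screened two ways, both valid when the mean and SD are
estimated from the sample: a Lilliefors (Kolmogorov–Smirnov with estimated
parameters) statistic whose p-value comes from a seeded Monte-Carlo null,
and an Anderson–Darling A² with the usual small-sample adjustment
A*² = A²(1 + 0.75/n + 2.25/n²) and the case-3 piecewise p-value
approximation of D'Agostino & Stephens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ConfidenceSpec, InsufficientDataError, OffsetModel, PairedRecord

__all__ = [
    "SummaryStats",
    "HistogramSpec",
    "NormalityResult",
    "AgreementResult",
    "summarize",
    "t_multiplier",
    "scott_bin_width",
    "build_histogram",
    "lilliefors_statistic",
    "lilliefors_null_distribution",
    "lilliefors_test",
    "anderson_darling_test",
    "bland_altman",
    "fit_offset_model",
]

ALPHA = 0.05


@dataclass(frozen=True)
class SummaryStats:
    """Central tendency and dispersion with confidence intervals (°F)."""

    n: int
    mean: float
    sd: float
    median: float
    range: float
    iqr: float
    min: float
    max: float
    ci_mean: tuple[float, float]
    ci_sd: tuple[float, float]


@dataclass(frozen=True)
class HistogramSpec:
    """Histogram layout using the Scott-style bin width 3.49·σ/n^(1/3)."""

    bin_width: float
    edges: tuple[float, ...]
    counts: tuple[int, ...]


@dataclass(frozen=True)
class NormalityResult:
    test: str
    statistic: float
    p_value: float
    reject_at_5pct: bool


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman agreement between a test method and the reference."""

    n: int
    bias: float
    sd_diff: float
    loa_halfwidth: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    pair_means: tuple[float, ...]
    pair_diffs: tuple[float, ...]


def t_multiplier(df: int, level: float = 0.95) -> float:
    """Two-sided Student-t critical value; 2.009 at df = 50, level 0.95."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    return float(stats.t.ppf(1.0 - (1.0 - level) / 2.0, df))


def scott_bin_width(sd: float, n: int) -> float:
    """Histogram bin width 3.49·σ/n^(1/3)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    return 3.49 * sd / n ** (1.0 / 3.0)


def summarize(sample, conf: ConfidenceSpec | None = None) -> SummaryStats:
    """Descriptive statistics with CIs for the mean (t) and SD (chi-square).

    SD is the n−1 sample estimator; quartiles use linear interpolation
    between order statistics.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError("summarize requires at least 2 observations")
    if conf is None:
        conf = ConfidenceSpec(df=n - 1)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    tcrit = t_multiplier(n - 1, conf.level)
    half = tcrit * sd / np.sqrt(n)
    alpha = 1.0 - conf.level
    # Chi-square interval for the SD of a normal sample.
    chi_lo = stats.chi2.ppf(1.0 - alpha / 2.0, n - 1)
    chi_hi = stats.chi2.ppf(alpha / 2.0, n - 1)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return SummaryStats(
        n=n,
        mean=mean,
        sd=sd,
        median=float(med),
        range=float(np.max(x) - np.min(x)),
        iqr=float(q3 - q1),
        min=float(np.min(x)),
        max=float(np.max(x)),
        ci_mean=(mean - half, mean + half),
        ci_sd=(
            float(np.sqrt((n - 1) * sd**2 / chi_lo)),
            float(np.sqrt((n - 1) * sd**2 / chi_hi)),
        ),
    )


def build_histogram(sample) -> HistogramSpec:
    x = np.asarray(sample, dtype=float)
    sd = float(np.std(x, ddof=1))
    w = scott_bin_width(sd, x.size)
    if w == 0:
        edges = np.array([x.min() - 0.5, x.max() + 0.5])
    else:
        lo, hi = float(x.min()), float(x.max())
        nbins = max(int(np.ceil((hi - lo) / w)), 1)
        edges = lo + w * np.arange(nbins + 1)
        if edges[-1] <= hi:  # right-closed last bin must cover the max
            edges = np.append(edges, edges[-1] + w)
    counts, edges = np.histogram(x, bins=edges)
    return HistogramSpec(bin_width=w, edges=tuple(edges), counts=tuple(int(c) for c in counts))


def lilliefors_statistic(sample) -> float:
    """Sup-distance between the empirical CDF and N(x̄, s²) fitted to it."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    s = np.std(x, ddof=1)
    if s == 0:
        return 0.0  # constant sample: degenerate normal limit, no evidence
    z = stats.norm.cdf((x - np.mean(x)) / s)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - z, z - (i - 1) / n)))


def lilliefors_null_distribution(n: int, reps: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo null statistics: ``reps`` standard-normal samples of size n."""
    draws = rng.standard_normal((reps, n))
    draws.sort(axis=1)
    means = draws.mean(axis=1, keepdims=True)
    sds = draws.std(axis=1, ddof=1, keepdims=True)
    z = stats.norm.cdf((draws - means) / sds)
    i = np.arange(1, n + 1)
    return np.max(np.maximum(i / n - z, z - (i - 1) / n), axis=1)


def lilliefors_test(sample, mc_reps: int = 5000, seed: int = 0) -> NormalityResult:
    """Lilliefors normality test with a seeded Monte-Carlo p-value.

    The p-value is (1 + #{null ≥ observed}) / (mc_reps + 1), the standard
    add-one Monte-Carlo estimator, so it is never exactly zero and is
    reproducible given the seed.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("lilliefors_test requires at least 4 observations")
    stat = lilliefors_statistic(x)
    rng = np.random.default_rng(seed)
    null = lilliefors_null_distribution(x.size, mc_reps, rng)
    p = (1.0 + np.count_nonzero(null >= stat)) / (mc_reps + 1.0)
    return NormalityResult("lilliefors", stat, float(p), bool(p < ALPHA))


def anderson_darling_test(sample) -> NormalityResult:
    """Anderson–Darling normality test with estimated mean and SD."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 8:
        raise InsufficientDataError("anderson_darling_test requires at least 8 observations")
    s = np.std(x, ddof=1)
    if s == 0:
        # constant sample: the degenerate normal limit; no evidence against
        return NormalityResult("anderson_darling", 0.0, 1.0, False)
    z = stats.norm.cdf((x - np.mean(x)) / s)
    z = np.clip(z, 1e-15, 1.0 - 1e-15)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1])))
    a2_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2_star >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star**2)
    elif a2_star >= 0.34:
        p = np.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star**2)
    elif a2_star >= 0.2:
        p = 1.0 - np.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star**2)
    else:
        p = 1.0 - np.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star**2)
    p = float(np.clip(p, 0.0, 1.0))
    return NormalityResult("anderson_darling", float(a2_star), p, bool(p < ALPHA))


def bland_altman(records: list[PairedRecord], distance: str,
                 conf: ConfidenceSpec | None = None) -> AgreementResult:
    """Bland–Altman agreement for one NCIT distance against the reference.

    Differences are test minus reference (NCIT − TAT), so a device reading
    low gives a negative bias.  The LOA multiplier is fixed at 1.96.
    """
    missing = [r.subject_id for r in records if distance not in r.t_ncit]
    if missing:
        raise KeyError(f"records lacking distance {distance!r}: {missing[:5]}")
    n = len(records)
    if n < 3:
        raise InsufficientDataError("bland_altman requires at least 3 pairs")
    if conf is None:
        conf = ConfidenceSpec(df=n - 1)
    test = np.array([r.t_ncit[distance] for r in records])
    ref = np.array([r.t_ref for r in records])
    diffs = test - ref
    means = (test + ref) / 2.0
    bias = float(np.mean(diffs))
    s = float(np.std(diffs, ddof=1))
    loa_half = 1.96 * s
    tcrit = t_multiplier(n - 1, conf.level)
    h_bias = tcrit * s / np.sqrt(n)
    h_loa = tcrit * s * np.sqrt(3.0 / n)
    lo, hi = bias - loa_half, bias + loa_half
    return AgreementResult(
        n=n,
        bias=bias,
        sd_diff=s,
        loa_halfwidth=loa_half,
        loa_lower=lo,
        loa_upper=hi,
        ci_bias=(bias - h_bias, bias + h_bias),
        ci_loa_lower=(lo - h_loa, lo + h_loa),
        ci_loa_upper=(hi - h_loa, hi + h_loa),
        pair_means=tuple(float(m) for m in means),
        pair_diffs=tuple(float(d) for d in diffs),
    )


def fit_offset_model(result: AgreementResult) -> OffsetModel:
    """Offset model from the agreement analysis: Δμ = bias, ρ = LOA/1.96."""
    return OffsetModel(
        delta_mu=result.bias,
        rho=result.loa_halfwidth / 1.96,
        loa_halfwidth=result.loa_halfwidth,
    )
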