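"""Standardized mean differences for paired and independent designs.

The accuracy comparisons at the heart of the inner-crowd analysis are paired:
each participant contributes an MSE under two scoring rules (e.g. single guess
vs. averaged guess), and the effect of interest is Cohen's d_z, the mean paired
difference divided by the standard deviation of the differences,

    d_z = (mu_X - mu_Y) / sqrt(sd_X^2 + sd_Y^2 - 2 sd_X sd_Y rho_XY),

estimable from a paired t-statistic as d_z = t / sqrt(n).  For planning, effect
sizes from several studies are combined by fixed-effect inverse-variance
pooling, where the sampling variance of an estimated d_z is

    v = (1/n + d_z^2 / (2n)) * 2 * (1 - r),

with r the correlation between the paired observations.  Between-condition
comparisons use the ordinary independent-groups d with a pooled-SD
standardizer.  Confidence intervals use a normal approximation on the
variance 1/n + d^2/(2n) (paired) or (n1+n2)/(n1 n2) + d^2/(2(n1+n2))
(independent); a noncentral-t inversion is available as an optional mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DegeneratePairError",
    "EffectSizeEstimate",
    "IncompleteEstimateError",
    "IndependentSummary",
    "InfiniteWeightError",
    "InvalidSampleSizeError",
    "PairedSummary",
    "PooledEffect",
    "StudyEffect",
    "TestResult",
    "d_independent_from_summary",
    "d_independent_from_t",
    "dz_from_summary",
    "dz_from_t",
    "effect_ci",
    "independent_t",
    "independent_summary_from_data",
    "paired_t",
    "pool_effects",
    "var_dz",
]


class DegeneratePairError(ValueError):
    """Paired data whose difference has zero variance (no defined d_z or t)."""


class InvalidSampleSizeError(ValueError):
    """Sample size too small for the requested statistic."""


class InfiniteWeightError(ValueError):
    """A pooled study has zero sampling variance (r_xy = 1), i.e. infinite weight."""


class IncompleteEstimateError(ValueError):
    """An effect-size estimate is missing fields needed for the operation."""


def _check_n(n: int, minimum: int = 2, name: str = "n") -> int:
    if not float(n).is_integer() or int(n) < minimum:
        raise InvalidSampleSizeError(f"{name} must be an integer >= {minimum}, got {n!r}")
    return int(n)


@dataclass(frozen=True)
class PairedSummary:
    """Summary statistics of two paired measurement series.

    Means and SDs are in the measurement's own units (squared-percent for MSE
    series); ``r_xy`` is the correlation between the paired observations and
    ``n`` the number of pairs.
    """

    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    r_xy: float
    n: int

    def __post_init__(self) -> None:
        if self.sd_x <= 0 or self.sd_y <= 0:
            raise ValueError(f"standard deviations must be positive, got sd_x={self.sd_x}, sd_y={self.sd_y}")
        if not -1.0 <= self.r_xy <= 1.0:
            raise ValueError(f"r_xy must lie in [-1, 1], got {self.r_xy}")
        _check_n(self.n)

    @property
    def sd_diff(self) -> float:
        """SD of the paired differences X - Y."""
        s2 = self.sd_x**2 + self.sd_y**2 - 2.0 * self.sd_x * self.sd_y * self.r_xy
        return math.sqrt(max(s2, 0.0))


@dataclass(frozen=True)
class IndependentSummary:
    """Summary statistics of two independent groups."""

    mean_1: float
    mean_2: float
    sd_1: float
    sd_2: float
    n_1: int
    n_2: int

    def __post_init__(self) -> None:
        if self.sd_1 <= 0 or self.sd_2 <= 0:
            raise ValueError(f"standard deviations must be positive, got sd_1={self.sd_1}, sd_2={self.sd_2}")
        _check_n(self.n_1, name="n_1")
        _check_n(self.n_2, name="n_2")

    @property
    def pooled_sd(self) -> float:
        n1, n2 = self.n_1, self.n_2
        return math.sqrt(((n1 - 1) * self.sd_1**2 + (n2 - 1) * self.sd_2**2) / (n1 + n2 - 2))


@dataclass(frozen=True)
class EffectSizeEstimate:
    """A standardized mean difference with its design, sample size and CI.

    ``n`` is the number of pairs for a paired design and an ``(n_1, n_2)``
    tuple for an independent design.  ``variance`` is the pooling variance
    (paired designs only, when the pair correlation is known); the CI has its
    own variance formula, see :func:`effect_ci`.
    """

    value: float
    design: Literal["paired", "independent"]
    n: int | tuple[int, int]
    variance: float | None = None
    ci_level: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.design not in ("paired", "independent"):
            raise ValueError(f"design must be 'paired' or 'independent', got {self.design!r}")
        if self.variance is not None and self.variance < 0:
            raise ValueError(f"variance must be nonnegative, got {self.variance}")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.value <= self.ci_high:
                raise ValueError(
                    f"confidence interval [{self.ci_low}, {self.ci_high}] does not contain the estimate {self.value}"
                )


@dataclass(frozen=True)
class StudyEffect:
    """One study's paired effect size, sample size and pair correlation, for pooling."""

    label: str
    d_z: float
    n: int
    r_xy: float

    def __post_init__(self) -> None:
        _check_n(self.n)
        if not -1.0 <= self.r_xy <= 1.0:
            raise ValueError(f"r_xy must lie in [-1, 1], got {self.r_xy}")

    @classmethod
    def from_t(cls, label: str, t: float, n: int, r_xy: float) -> "StudyEffect":
        return cls(label=label, d_z=dz_from_t(t, n), n=n, r_xy=r_xy)


@dataclass(frozen=True)
class PooledEffect:
    """Fixed-effect inverse-variance pooled standardized mean difference."""

    value: float
    k: int
    weights: tuple[float, ...]
    total_weight: float

    def __post_init__(self) -> None:
        if self.k < 1 or len(self.weights) != self.k:
            raise ValueError("k must be >= 1 and match the number of weights")
        if any(w <= 0 for w in self.weights) or self.total_weight <= 0:
            raise ValueError("pooling weights must be positive")


@dataclass(frozen=True)
class TestResult:
    """A t-test outcome: statistic, degrees of freedom, two-tailed p, raw mean difference."""

    t: float
    df: int
    p_two_tailed: float
    mean_diff: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p_two_tailed}")


def dz_from_summary(s: PairedSummary) -> EffectSizeEstimate:
    """Cohen's d_z from the five paired summary numbers.

    Raises :class:`DegeneratePairError` when the difference SD is zero
    (identical SDs with perfect positive correlation).
    """
    sd_diff = s.sd_diff
    if sd_diff <= 0.0:
        raise DegeneratePairError(
            f"paired difference has zero SD (sd_x={s.sd_x}, sd_y={s.sd_y}, r_xy={s.r_xy}); d_z undefined"
        )
    value = (s.mean_x - s.mean_y) / sd_diff
    return EffectSizeEstimate(
        value=value, design="paired", n=s.n, variance=var_dz(value, s.n, s.r_xy)
    )


def dz_from_t(t: float, n: int) -> float:
    """Estimate Cohen's d_z from a paired t-statistic: d_z = t / sqrt(n)."""
    n = _check_n(n)
    return float(t) / math.sqrt(n)


def var_dz(d_z: float, n: int, r_xy: float) -> float:
    """Sampling variance of an estimated d_z: (1/n + d_z^2/(2n)) * 2 * (1 - r_xy).

    The reciprocal is the study's fixed-effect pooling weight.  ``r_xy = 1``
    yields 0, which :func:`pool_effects` rejects as an infinite weight.
    """
    n = _check_n(n)
    if not -1.0 <= r_xy <= 1.0:
        raise ValueError(f"r_xy must lie in [-1, 1], got {r_xy}")
    return (1.0 / n + d_z**2 / (2.0 * n)) * 2.0 * (1.0 - r_xy)


def pool_effects(studies: Sequence[StudyEffect]) -> PooledEffect:
    """Fixed-effect inverse-variance pooling of paired effect sizes."""
    if len(studies) == 0:
        raise ValueError("pool_effects requires at least one study")
    weights = []
    for s in studies:
        v = var_dz(s.d_z, s.n, s.r_xy)
        if v <= 0.0:
            raise InfiniteWeightError(
                f"study {s.label!r} has zero sampling variance (r_xy={s.r_xy}); its pooling weight is infinite"
            )
        weights.append(1.0 / v)
    total = math.fsum(weights)
    value = math.fsum(w * s.d_z for w, s in zip(weights, studies)) / total
    return PooledEffect(value=value, k=len(studies), weights=tuple(weights), total_weight=total)


def d_independent_from_summary(s: IndependentSummary) -> EffectSizeEstimate:
    """Independent-groups Cohen's d with a pooled-SD standardizer."""
    if s.n_1 + s.n_2 < 3:
        raise InvalidSampleSizeError("independent d requires n_1 + n_2 >= 3")
    sp = s.pooled_sd
    if sp <= 0.0:
        raise DegeneratePairError("pooled SD is zero; independent d undefined")
    return EffectSizeEstimate(value=(s.mean_1 - s.mean_2) / sp, design="independent", n=(s.n_1, s.n_2))


def d_independent_from_t(t: float, n_1: int, n_2: int) -> float:
    """Independent-groups d from a pooled-variance t: d = t * sqrt(1/n_1 + 1/n_2)."""
    n_1 = _check_n(n_1, name="n_1")
    n_2 = _check_n(n_2, name="n_2")
    return float(t) * math.sqrt(1.0 / n_1 + 1.0 / n_2)


def _ci_variance(value: float, design: str, n: int | tuple[int, int]) -> float:
    if design == "paired":
        n = _check_n(n)  # type: ignore[arg-type]
        return 1.0 / n + value**2 / (2.0 * n)
    n1, n2 = n  # type: ignore[misc]
    return (n1 + n2) / (n1 * n2) + value**2 / (2.0 * (n1 + n2))


def _noncentral_ci(value: float, design: str, n, level: float) -> tuple[float, float]:
    # invert the noncentral-t CDF in the noncentrality parameter
    if design == "paired":
        scale = math.sqrt(n)
        df = n - 1
    else:
        n1, n2 = n
        scale = 1.0 / math.sqrt(1.0 / n1 + 1.0 / n2)
        df = n1 + n2 - 2
    t_obs = value * scale
    lo_p, hi_p = (1.0 + level) / 2.0, (1.0 - level) / 2.0

    def solve(target: float) -> float:
        def f(nc: float) -> float:
            c = stats.nct.cdf(t_obs, df, nc)
            return (c if np.isfinite(c) else (0.0 if nc > t_obs else 1.0)) - target

        lo, hi = t_obs - 1.0, t_obs + 1.0
        while f(lo) < 0.0:
            lo -= 2.0
        while f(hi) > 0.0:
            hi += 2.0
        return optimize.brentq(f, lo, hi, xtol=1e-10)

    return solve(lo_p) / scale, solve(hi_p) / scale


def effect_ci(
    e: EffectSizeEstimate, level: float = 0.95, method: Literal["normal", "noncentral"] = "normal"
) -> EffectSizeEstimate:
    """Attach a confidence interval to an effect-size estimate.

    The default is the normal approximation d -/+ z * sqrt(V) with
    V = 1/n + d^2/(2n) for paired designs and
    V = (n1+n2)/(n1 n2) + d^2/(2(n1+n2)) for independent ones.
    ``method='noncentral'`` instead inverts the noncentral-t distribution of
    the corresponding t-statistic.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    if e.n is None:
        raise IncompleteEstimateError("effect-size estimate has no sample size; cannot form a CI")
    if method == "noncentral":
        low, high = _noncentral_ci(e.value, e.design, e.n, level)
    else:
        z = stats.norm.ppf((1.0 + level) / 2.0)
        half = z * math.sqrt(_ci_variance(e.value, e.design, e.n))
        low, high = e.value - half, e.value + half
    return replace(e, ci_level=level, ci_low=low, ci_high=high)


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed t-test for paired observations (positive t when mean(x) > mean(y))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"paired vectors must be 1-D and equal length, got shapes {x.shape} and {y.shape}")
    n = x.size
    _check_n(n)
    diff = x - y
    if np.std(diff, ddof=1) == 0.0:
        raise DegeneratePairError("paired differences have zero variance; t undefined")
    res = stats.ttest_rel(x, y)
    return TestResult(
        t=float(res.statistic), df=n - 1, p_two_tailed=float(res.pvalue), mean_diff=float(diff.mean())
    )


def independent_summary_from_data(g1: Sequence[float], g2: Sequence[float]) -> IndependentSummary:
    """Summarize two independent samples (group 1 first)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    return IndependentSummary(
        mean_1=float(g1.mean()),
        mean_2=float(g2.mean()),
        sd_1=float(g1.std(ddof=1)),
        sd_2=float(g2.std(ddof=1)),
        n_1=g1.size,
        n_2=g2.size,
    )


def independent_t(s: IndependentSummary) -> TestResult:
    """Two-tailed pooled-variance Student t-test from group summaries (df = n_1 + n_2 - 2)."""
    if s.pooled_sd <= 0.0:
        raise DegeneratePairError("pooled variance is zero; t undefined")
    res = stats.ttest_ind_from_stats(
        mean1=s.mean_1, std1=s.sd_1, nobs1=s.n_1,
        mean2=s.mean_2, std2=s.sd_2, nobs2=s.n_2,
        equal_var=True,
    )
    return TestResult(
        t=float(res.statistic),
        df=s.n_1 + s.n_2 - 2,
        p_two_tailed=float(res.pvalue),
        mean_diff=s.mean_1 - s.mean_2,
    )
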