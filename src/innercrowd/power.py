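"""Exact power for the paired t-test, sample-size planning, and detectable effects.

Under a true standardized effect d_z, the paired t-statistic with n pairs
follows a noncentral t distribution with df = n - 1 and noncentrality
delta = d_z * sqrt(n).  Power is the noncentral-t mass beyond the central-t
rejection bounds; no normal approximation is used, so small planned samples
are handled exactly.  ``detectable_effect`` inverts the power function in d
and yields, at target power 0.33, the d_33% benchmark used by the
detectability criterion for judging replications: the smallest effect the
original study would have detected with 33% power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy import optimize, stats

from .effects import InvalidSampleSizeError, _check_n

__all__ = ["PowerSpec", "detectable_effect", "paired_t_power", "required_n"]


@dataclass(frozen=True)
class PowerSpec:
    """Error rates for a power calculation: alpha, tails, and the planning target."""

    alpha: float = 0.05
    tails: Literal["two", "one"] = "two"
    target_power: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError(f"target_power must lie in (0, 1), got {self.target_power}")
        if self.tails not in ("two", "one"):
            raise ValueError(f"tails must be 'two' or 'one', got {self.tails!r}")


def _tail_prob(p: float) -> float:
    # scipy's noncentral-t CDF/SF underflow to NaN deep in a tail; that mass is 0
    return p if math.isfinite(p) else 0.0


def paired_t_power(d_z: float, n: int, spec: PowerSpec = PowerSpec()) -> float:
    """Exact power of the paired t-test at true effect ``d_z`` with ``n`` pairs.

    Two-tailed tests sum both rejection tails; one-tailed tests reject in the
    direction of positive effects.
    """
    n = _check_n(n)
    df = n - 1
    nc = d_z * math.sqrt(n)
    if spec.tails == "two":
        t_crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
        power = _tail_prob(stats.nct.sf(t_crit, df, nc)) + _tail_prob(stats.nct.cdf(-t_crit, df, nc))
    else:
        t_crit = stats.t.ppf(1.0 - spec.alpha, df)
        power = _tail_prob(stats.nct.sf(t_crit, df, nc))
    return min(power, 1.0)


def required_n(d_z: float, spec: PowerSpec = PowerSpec()) -> int:
    """Smallest n >= 2 whose exact paired-t power reaches ``spec.target_power``."""
    if d_z == 0.0:
        raise InvalidSampleSizeError("d_z = 0 can never attain the target power")
    if paired_t_power(d_z, 2, spec) >= spec.target_power:
        return 2
    # exponential bracket then bisection; power is monotone in n
    lo, hi = 2, 4
    while paired_t_power(d_z, hi, spec) < spec.target_power:
        lo, hi = hi, hi * 2
        if hi > 10_000_000:
            raise InvalidSampleSizeError(f"required n exceeds 1e7 for d_z={d_z}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if paired_t_power(d_z, mid, spec) >= spec.target_power:
            hi = mid
        else:
            lo = mid
    return hi


def detectable_effect(n: int, spec: PowerSpec = PowerSpec(target_power=0.33)) -> float:
    """The positive effect size whose exact power equals ``spec.target_power`` at ``n``.

    With target power 0.33 this is d_33%.  The attainable floor is the power at
    d = 0 (alpha for a two-tailed test); at the floor the root is 0.
    """
    n = _check_n(n)
    floor = paired_t_power(0.0, n, spec)
    if spec.target_power < floor - 1e-12:
        raise ValueError(
            f"target power {spec.target_power} is below the null rejection rate {floor:.4g}; no root"
        )
    if spec.target_power <= floor + 1e-12:
        return 0.0
    hi = 0.5
    while paired_t_power(hi, n, spec) < spec.target_power:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("no detectable effect found below d = 1e4")
    return float(
        optimize.brentq(lambda d: paired_t_power(d, n, spec) - spec.target_power, 0.0, hi, xtol=1e-10)
    )
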