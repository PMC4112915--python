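"""JZS (Jeffreys-Zellner-Siow) default Bayes factors for t-tests.

The alternative hypothesis places a zero-centered Cauchy prior with scale
``r`` on the standardized effect delta; the error variance carries the
improper Jeffreys prior, which integrates out analytically.  What remains is a
one-dimensional integral over the mixing variable g of the Cauchy's
normal-scale-mixture representation (delta | g ~ N(0, g), g ~
InverseGamma(1/2, r^2/2)):

    BF10 = integral_0^inf  (1 + N g)^(-1/2)
           * (1 + t^2 / ((1 + N g) nu))^(-(nu+1)/2)
           * r / sqrt(2 pi) * g^(-3/2) * exp(-r^2 / (2 g))  dg
           / (1 + t^2 / nu)^(-(nu+1)/2),

with effective sample size N = n and nu = n - 1 for the one-sample (paired)
test, and N = n1 n2 / (n1 + n2), nu = n1 + n2 - 2 for the two-sample test.
The integral is mapped onto (0, 1) by g = u / (1 - u) and evaluated in
log-space by adaptive quadrature.  Results are reported as BF01 = 1 / BF10,
evidence in favor of the null of no difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy import integrate

from .effects import _check_n

__all__ = ["BayesFactorResult", "IntegrationError", "jzs_bf01_one_sample", "jzs_bf01_two_sample"]

_REL_TOL = 1e-6


class IntegrationError(RuntimeError):
    """Quadrature failed to reach the required relative error."""


@dataclass(frozen=True)
class BayesFactorResult:
    """A JZS Bayes factor in favor of the null, with its prior scale and design."""

    bf01: float
    scale_r: float
    design: Literal["one_sample", "two_sample"]
    integration_error: float

    def __post_init__(self) -> None:
        if self.bf01 <= 0:
            raise ValueError(f"bf01 must be positive, got {self.bf01}")

    @property
    def bf10(self) -> float:
        """Evidence for the alternative over the null (reciprocal of bf01)."""
        return 1.0 / self.bf01


def _bf01(t: float, eff_n: float, df: int, scale_r: float, design: str) -> BayesFactorResult:
    if not math.isfinite(t):
        raise ValueError(f"t must be finite, got {t}")
    if scale_r <= 0:
        raise ValueError(f"scale_r must be positive, got {scale_r}")
    t2 = float(t) ** 2
    log_null = -(df + 1) / 2.0 * math.log1p(t2 / df)

    def integrand(u: float) -> float:
        g = u / (1.0 - u)
        # marginal likelihood under the alternative at mixing value g, divided
        # by the null likelihood (keeps the integrand O(1) for huge df)
        log_ratio = (
            -0.5 * math.log1p(eff_n * g)
            - (df + 1) / 2.0 * math.log1p(t2 / ((1.0 + eff_n * g) * df))
            - log_null
        )
        log_prior = (
            math.log(scale_r)
            - 0.5 * math.log(2.0 * math.pi)
            - 1.5 * math.log(g)
            - scale_r**2 / (2.0 * g)
        )
        return math.exp(log_ratio + log_prior) / (1.0 - u) ** 2

    inv_bf01, abserr = integrate.quad(integrand, 0.0, 1.0, epsabs=0.0, epsrel=1e-10, limit=500)
    rel_err = abserr / inv_bf01 if inv_bf01 > 0 else math.inf
    if not math.isfinite(inv_bf01) or inv_bf01 <= 0 or rel_err > _REL_TOL:
        raise IntegrationError(
            f"JZS quadrature failed (t={t}, N={eff_n}, df={df}): achieved relative error {rel_err:.3g}"
        )
    return BayesFactorResult(
        bf01=1.0 / inv_bf01, scale_r=scale_r, design=design, integration_error=rel_err
    )


def jzs_bf01_one_sample(t: float, n: int, scale_r: float = 1.0) -> BayesFactorResult:
    """JZS BF01 for a one-sample (or paired) t-statistic with n observations (pairs)."""
    n = _check_n(n)
    return _bf01(t, float(n), n - 1, scale_r, "one_sample")


def jzs_bf01_two_sample(t: float, n_1: int, n_2: int, scale_r: float = 1.0) -> BayesFactorResult:
    """JZS BF01 for a two-sample t-statistic with group sizes n_1 and n_2.

    Uses the effective sample size N = n_1 n_2 / (n_1 + n_2) and
    nu = n_1 + n_2 - 2.
    """
    n_1 = _check_n(n_1, name="n_1")
    n_2 = _check_n(n_2, name="n_2")
    eff_n = n_1 * n_2 / (n_1 + n_2)
    return _bf01(t, eff_n, n_1 + n_2 - 2, scale_r, "two_sample")
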