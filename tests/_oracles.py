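"""Independent brute-force / Monte-Carlo oracles used to check the package.

These deliberately avoid the library's own code paths: the paired t is the
textbook formula evaluated directly, power comes from simulating raw paired
data, and the Bayes factor comes from Monte-Carlo integration over the prior
mixing variable rather than deterministic quadrature.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def brute_force_paired_t(x, y) -> tuple[float, int, float]:
    """Textbook paired t: mean difference over its standard error."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    d = x - y
    n = d.size
    sd = math.sqrt(sum((v - d.mean()) ** 2 for v in d) / (n - 1))
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return t, n - 1, p


def mc_paired_t_power(d: float, n: int, alpha: float, reps: int, rng: np.random.Generator) -> tuple[float, float]:
    """Simulate `reps` paired samples of size n with true effect d (unit SD);
    return the two-tailed rejection rate and its binomial standard error."""
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    rejections = 0
    chunk = max(1, min(reps, 50_000_000 // n))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        data = rng.standard_normal((m, n)) + d
        t = data.mean(axis=1) / (data.std(axis=1, ddof=1) / math.sqrt(n))
        rejections += int((np.abs(t) > t_crit).sum())
        done += m
    p = rejections / reps
    return p, math.sqrt(max(p * (1 - p), 1e-12) / reps)


def mc_bf01(t: float, eff_n: float, df: int, scale_r: float, n_samples: int, rng: np.random.Generator) -> float:
    """JZS BF01 by Monte-Carlo over the prior mixing variable g ~ InvGamma(1/2, r^2/2)."""
    g = (scale_r**2 / 2.0) / rng.gamma(0.5, 1.0, size=n_samples)
    log_null = -(df + 1) / 2.0 * np.log1p(t**2 / df)
    log_ratio = (
        -0.5 * np.log1p(eff_n * g)
        - (df + 1) / 2.0 * np.log1p(t**2 / ((1.0 + eff_n * g) * df))
        - log_null
    )
    return 1.0 / float(np.exp(log_ratio).mean())


def brute_force_mse(guess1, guess2, truths) -> tuple[float, float, float]:
    """Per-question recomputation of the three MSEs for one participant."""
    se1, se2, sea, k = 0.0, 0.0, 0.0, 0
    for g1, g2, tr in zip(guess1, guess2, truths):
        if math.isnan(g1) or math.isnan(g2):
            continue
        se1 += (g1 - tr) ** 2
        se2 += (g2 - tr) ** 2
        sea += ((g1 + g2) / 2.0 - tr) ** 2
        k += 1
    return se1 / k, se2 / k, sea / k
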