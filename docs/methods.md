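# Methods

## The analysis model

A crowd-within study elicits two guesses per participant on K = 8
percentage-scale questions, in an *immediate* condition (second guess right
after the first) and a *delayed* condition (second guess three weeks later,
increasing the independence of the two guesses). Accuracy per participant is
the mean squared error (MSE) over the retained questions; the average guess
is scored average-then-score — the per-question mean of the two guesses is
formed first and the MSE of that mean is computed — which by convexity
satisfies MSE_avg ≤ (MSE_g1 + MSE_g2)/2, with equality only when the two
guesses coincide on every retained question.

The confirmatory claims are paired comparisons across participants: the MSE
of guess 1 (and of guess 2) against the MSE of the average, with the sign
convention t > 0 when the single guess is worse. Effect sizes are Cohen's
d_z (mean paired difference over the SD of the differences), estimated from
the t-statistic as d̂_z = t/√n. The delayed-vs-immediate contrast uses the
per-participant averaging benefit, MSE(reference guess) − MSE(average), in a
pooled-variance Student t-test with df = n₁ + n₂ − 2 and a pooled-SD
independent-groups d; Welch's test is deliberately not used, because the
pipeline is meant to mirror a pooled-variance analysis whose printed degrees
of freedom (609, 426) it reproduces.

### Confidence intervals

The construction behind the study's printed intervals is not stated
anywhere; a normal approximation with variance

* paired: V = 1/n + d²/(2n)
* independent: V = (n₁+n₂)/(n₁ n₂) + d²/(2(n₁+n₂))

reproduces every printed interval to 2 dp, so it is the default. A
noncentral-t inversion (solving for the noncentrality parameters whose CDF
at the observed t equals the tail probabilities) is available as
`effect_ci(..., method="noncentral")` for users who prefer an exact
interval; at the study's sample sizes the two agree to about 0.01.

### Pooling and planning

Fixed-effect inverse-variance pooling weights each study's d̂_z by the
reciprocal of v = (1/n + d̂_z²/(2n))·2(1 − r), with r the correlation
between the paired observations. Random-effects models, heterogeneity
statistics and Hedges' small-sample correction are out of scope. Studies
with r = 1 have zero variance and are rejected rather than allowed to
dominate silently.

Power is exact noncentral-t: with true effect d and n pairs the t-statistic
is noncentral-t with df = n − 1 and noncentrality d√n; power is the
noncentral mass beyond the central-t critical values (both tails summed for
two-tailed tests). `required_n` returns the smallest n whose exact power
reaches the target (ceiling convention); `detectable_effect` inverts power
in d by bracketed root finding (xtol 1e-10) and yields d₃₃% at target power
0.33. Note that the planning sizes printed in the replication literature for
these inputs (31, 48, 13, and 439 for the pooled guess-1 effect) do not
agree with this exact calculation (which gives 44, 61, 26 and 452); the
settings of the planning software behind them are unknown, so the package's
planner is validated against a Monte-Carlo simulation oracle and its
definitional round trip instead of those numbers.

### Replication verdicts

*Traditional*: both single-vs-average tests positive and significant at
α (two-tailed). *Detectability*: additionally, neither effect estimate may
be significantly below d₃₃% computed at the **original** study's sample
size. The criterion is stated only verbally in the replication literature;
it is operationalized here as a one-sided z-test at α using the same normal
SE as the CI construction, √(1/n + d²/(2n)). Without an original sample
size the verdict is reported as unavailable (an explicit marker in the JSON,
not a silent null).

### Bayes factors

JZS default Bayes factors: Cauchy(0, r) prior on the standardized effect
(default scale r = 1), Jeffreys prior on the variance. The variance
integrates out analytically; the remaining one-dimensional integral over
the Cauchy's inverse-gamma mixing variable g is mapped onto (0, 1) via
g = u/(1−u) and evaluated in log space by adaptive quadrature (relative
tolerance 1e-10, checked against 1e-6; failure raises with the achieved
error). Two-sample tests use the effective sample size n₁n₂/(n₁+n₂) with
df = n₁ + n₂ − 2. BF01 > 1 favors the null. One caution for users comparing
against published tables: Bayes factors are sensitive to the third digit of
t, so a BF recomputed from a t-statistic printed to 2 dp can differ from
one computed from the unrounded statistic in the third decimal (e.g. at
t = −2.25, n = 471 the exact integral gives 2.2097, while values between
2.185 and 2.234 are consistent with the printed t).

## Cleaning

Participant-level exclusions are applied in the fixed precedence
incomplete → defocused → looked-up, each participant counted once under the
first matching rule; this precedence reproduces the replication's
accounting (484 → 471 immediate after 11 incomplete + 2 look-ups;
171 → 140 delayed after 9 incomplete, 21 defocused, 1 look-up). The
question-level rule removes **both** guesses of any question with a blank
or impossible (outside [0, 100]) answer, so each participant's MSEs are
re-averaged over their retained questions. Cleaning never fails and is
idempotent.

## The synthetic generator

The generator operationalizes the internal-sampling account: participant i's
guess k on question q is

    guess_kiq = truth_q + b_iq + e_kiq,

with bias b ~ N(0, τ²) and noise (e₁, e₂) bivariate normal with SDs σ and
σ(1 + λ) and correlation ρ. Defaults, fixed once from the magnitudes the
replication reports and not revisited:

| parameter | default | role |
|---|---|---|
| τ² | 450 %² | stable participant-question bias |
| σ² | 150 %² | per-guess sampling noise |
| ρ (immediate) | 0.36 | noise correlation; benefit σ²(1−ρ)/2 = 48 %² |
| ρ (delayed) | 0.10 | delay decorrelates the guesses |
| λ (guess-2 inflation) | 0.08 | second guesses ≈ 26 %² worse |
| truths | the 8 study answers | percentages in [0, 100] |

This puts the single-guess MSE expectation at τ² + σ² = 600 %², the
between-participant MSE SD near 300 %², and the single-vs-average MSE
correlation in the high 0.8s — the ranges the replication observed. With
clipping off the closed forms E[MSE single] = τ² + σ²,
E[MSE avg] = τ² + (σ₁² + σ₂² + 2ρσ₁σ₂)/4 hold exactly and `expected_mse`
returns them (it refuses clipped parameter sets). `study_mimic_cohort`
clamps guesses to [0, 100], as the study's interface did, and assigns the
exact exclusion counts above to deterministic blocks.

By default the bias is drawn per participant-question, which makes the
between-participant MSE dispersion realistic. A `shared_bias` option draws
one bias per participant; that design is what makes (τ², σ², ρ) jointly
identifiable from a single cohort's error covariance structure
(cross-question covariances estimate τ² alone), and `estimate_params`
therefore requires it. With per-question bias, τ² and σ² enter every
available second moment only as a sum and cannot be separated.

What the generator does **not** emulate: question difficulty or anchoring
dynamics, heavy-tailed or rounded responses (people guess multiples of 5),
participant-level skill correlations across questions beyond the shared-bias
option, and any look-up behaviour (flags are independent Bernoulli draws).
Tests passing on synthetic cohorts therefore certify the pipeline's
statistical machinery and bookkeeping, not distributional claims about real
respondents.

## Problem sizes and determinism

Property tests use cohorts of 150–2000 participants and Monte-Carlo oracles
of 10⁵ replicates (power) and 10⁶ prior samples (Bayes factors) — sizes at
which the binomial/simulation error is far below the tolerances being
asserted. All simulation is seeded through `numpy.random.default_rng`;
identical inputs and configuration produce byte-identical JSON reports
(sorted keys, full-precision values plus display-rounded twins, schema
version stamp). The parameter-recovery check runs at n = 2000, where the 5%
band on τ² corresponds to roughly 1.6 standard errors of a sample variance
over 2000 participants — tight, and a known statistical limit of that test.

## Known limitations

* The CI method and the planning-software settings behind the published
  sample sizes are inferred/unknown respectively (see above).
* The cohort CSV reader targets this package's schema; external layouts are
  mapped via the `column_map` hook rather than auto-detected.
* d₃₃% and power cover paired (and, via pooling formulas, independent)
  t-designs only.
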