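"""Effect sizes, pooling, confidence intervals and t-tests."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from innercrowd.effects import (
    DegeneratePairError,
    EffectSizeEstimate,
    IncompleteEstimateError,
    IndependentSummary,
    InfiniteWeightError,
    InvalidSampleSizeError,
    PairedSummary,
    StudyEffect,
    d_independent_from_summary,
    d_independent_from_t,
    dz_from_summary,
    dz_from_t,
    effect_ci,
    independent_t,
    paired_t,
    pool_effects,
    var_dz,
)

from _oracles import brute_force_paired_t

# pooling inputs: (t, n, r) per study, for guess 1 and guess 2 respectively
GUESS1_STUDIES = [("vp", 4.41, 255, 0.88), ("hb", 2.15, 170, 0.91), ("bm", 1.71, 201, 0.95)]
GUESS2_STUDIES = [("vp", 9.90, 255, 0.83), ("hb", 7.89, 170, 0.87), ("bm", 7.03, 201, 0.92)]


class TestDzFromT:
    @pytest.mark.parametrize(
        "t, n, expected",
        [(4.41, 255, 0.28), (9.85, 173, 0.75), (8.69, 471, 0.40), (8.48, 140, 0.72), (0.0, 57, 0.0)],
    )
    def test_reference_values(self, t, n, expected):
        assert round(dz_from_t(t, n), 2) == expected

    def test_sign_preserved(self):
        assert dz_from_t(-2.25, 471) == -dz_from_t(2.25, 471)

    def test_small_n_rejected(self):
        with pytest.raises(InvalidSampleSizeError):
            dz_from_t(1.0, 1)


class TestDzFromSummary:
    def test_identical_means_give_zero(self):
        s = PairedSummary(500.0, 500.0, 300.0, 250.0, 0.4, 100)
        assert dz_from_summary(s).value == 0.0

    def test_equal_sds_half_correlation_denominator_collapses(self):
        # sd_x = sd_y = s and r = 0.5 make the difference SD equal s
        s = PairedSummary(510.0, 480.0, 60.0, 60.0, 0.5, 50)
        assert dz_from_summary(s).value == pytest.approx((510.0 - 480.0) / 60.0)

    def test_printed_summary_row(self):
        # published summary statistics; the printed 0.28 uses unrounded inputs
        s = PairedSummary(555.0, 508.0, 361.0, 305.0, 0.88, 255)
        est = dz_from_summary(s)
        assert est.value == pytest.approx(0.2734, abs=5e-4)
        assert abs(est.value - 0.28) < 0.01  # within input rounding of the printed value
        assert est.design == "paired"
        assert est.variance == pytest.approx(var_dz(est.value, 255, 0.88))

    def test_degenerate_pair_rejected(self):
        with pytest.raises(DegeneratePairError, match="sd_x"):
            dz_from_summary(PairedSummary(500.0, 490.0, 300.0, 300.0, 1.0, 100))

    @given(
        mu=st.floats(-50, 50),
        sd=st.floats(1, 100),
        r=st.floats(-0.99, 0.99),
        n=st.integers(2, 500),
    )
    def test_consistent_with_t_conversion(self, mu, sd, r, n):
        # d_z from the summary equals t/sqrt(n) for the t implied by that summary
        s = PairedSummary(500.0 + mu, 500.0, sd, sd * 1.3, r, n)
        d = dz_from_summary(s).value
        t = (s.mean_x - s.mean_y) / (s.sd_diff / math.sqrt(n))
        assert d == pytest.approx(dz_from_t(t, n), abs=1e-10)


class TestVarDz:
    def test_null_effect_collapses_to_one_over_n(self):
        assert var_dz(0.0, 100, 0.5) == pytest.approx(0.01)

    def test_reference_arithmetic(self):
        d = 4.41 / math.sqrt(255)
        assert var_dz(d, 255, 0.88) == pytest.approx(9.7707e-4, rel=1e-4)

    def test_perfect_correlation_gives_zero(self):
        assert var_dz(0.7, 50, 1.0) == 0.0

    def test_weight_increases_with_correlation(self):
        variances = [var_dz(0.3, 100, r) for r in (0.0, 0.5, 0.9, 0.99)]
        assert all(a > b for a, b in zip(variances, variances[1:]))


class TestPooling:
    def test_identical_studies_return_common_value(self):
        studies = [StudyEffect(f"s{i}", 0.42, 120, 0.8) for i in range(3)]
        assert pool_effects(studies).value == pytest.approx(0.42)

    @pytest.mark.parametrize(
        "rows, expected",
        [(GUESS1_STUDIES, 0.17), (GUESS2_STUDIES, 0.56)],
        ids=["guess1", "guess2"],
    )
    def test_published_pooled_effects(self, rows, expected):
        studies = [StudyEffect.from_t(lbl, t, n, r) for lbl, t, n, r in rows]
        assert round(pool_effects(studies).value, 2) == expected

    def test_order_invariant_and_bounded(self):
        studies = [StudyEffect.from_t(lbl, t, n, r) for lbl, t, n, r in GUESS2_STUDIES]
        pooled = pool_effects(studies)
        assert pool_effects(studies[::-1]).value == pytest.approx(pooled.value)
        values = [s.d_z for s in studies]
        assert min(values) <= pooled.value <= max(values)

    def test_infinite_weight_rejected(self):
        with pytest.raises(InfiniteWeightError, match="perfect"):
            pool_effects([StudyEffect("perfect", 0.4, 100, 1.0)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            pool_effects([])


class TestIndependentEffects:
    def test_equal_means_give_zero(self):
        s = IndependentSummary(10.0, 10.0, 5.0, 7.0, 30, 40)
        assert d_independent_from_summary(s).value == 0.0

    @pytest.mark.parametrize(
        "summary, expected",
        [
            (IndependentSummary(121.0, 73.0, 169.0, 155.0, 140, 471), 0.30),
            (IndependentSummary(164.0, 131.0, 218.0, 211.0, 173, 255), 0.15),
        ],
    )
    def test_published_benefit_comparisons(self, summary, expected):
        assert round(d_independent_from_summary(summary).value, 2) == expected

    @pytest.mark.parametrize(
        "t, n1, n2, expected", [(1.56, 255, 173, 0.15), (3.14, 471, 140, 0.30), (0.0, 10, 12, 0.0)]
    )
    def test_d_from_t(self, t, n1, n2, expected):
        assert round(d_independent_from_t(t, n1, n2), 2) == expected


class TestEffectCi:
    @pytest.mark.parametrize(
        "value, n, low, high",
        [(8.48 / math.sqrt(140), 140, 0.53, 0.90), (-2.25 / math.sqrt(471), 471, -0.19, -0.01)],
    )
    def test_published_paired_intervals(self, value, n, low, high):
        est = effect_ci(EffectSizeEstimate(value, "paired", n), 0.95)
        assert round(est.ci_low, 2) == low
        assert round(est.ci_high, 2) == high

    def test_zero_effect_interval_symmetric(self):
        est = effect_ci(EffectSizeEstimate(0.0, "paired", 80), 0.95)
        assert est.ci_low == pytest.approx(-est.ci_high)

    def test_width_shrinks_with_n(self):
        widths = [
            (lambda e: e.ci_high - e.ci_low)(effect_ci(EffectSizeEstimate(0.4, "paired", n)))
            for n in (20, 80, 320, 1280)
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_independent_interval_published(self):
        est = effect_ci(EffectSizeEstimate(0.3032, "independent", (140, 471)), 0.95)
        assert round(est.ci_low, 2) == 0.11
        assert round(est.ci_high, 2) == 0.49

    def test_noncentral_mode_close_to_normal_at_large_n(self):
        e = EffectSizeEstimate(0.4, "paired", 471)
        normal = effect_ci(e, 0.95)
        nct = effect_ci(e, 0.95, method="noncentral")
        assert nct.ci_low == pytest.approx(normal.ci_low, abs=0.01)
        assert nct.ci_high == pytest.approx(normal.ci_high, abs=0.01)

    def test_missing_n_rejected(self):
        with pytest.raises(IncompleteEstimateError):
            effect_ci(EffectSizeEstimate(0.4, "paired", None))  # type: ignore[arg-type]


class TestPairedT:
    def test_zero_variance_differences_rejected(self):
        x = np.array([3.0, 5.0, 9.0])
        with pytest.raises(DegeneratePairError):
            paired_t(x, x)

    def test_hand_calculation(self):
        # diffs (1, 1, 2): mean 4/3, SD 1/sqrt(3), t = (4/3)/(1/3) = 4
        res = paired_t([1.0, 2.0, 4.0], [0.0, 1.0, 2.0])
        assert res.t == pytest.approx(4.0)
        assert res.df == 2
        assert res.mean_diff == pytest.approx(4.0 / 3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(50, 10, 20)
        y = rng.normal(48, 12, 20)
        res = paired_t(x, y)
        t, df, p = brute_force_paired_t(x, y)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.df == df
        assert res.p_two_tailed == pytest.approx(p, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestIndependentT:
    def test_equal_means_give_zero(self):
        res = independent_t(IndependentSummary(5.0, 5.0, 2.0, 3.0, 10, 12))
        assert res.t == 0.0

    def test_pooled_df(self):
        res = independent_t(IndependentSummary(50.0, 48.0, 147.0, 119.0, 471, 140))
        assert res.df == 609

    def test_hand_calculation(self):
        # groups (1,2,3) vs (3,4,5): pooled SD 1, SE sqrt(2/3), t = -2/sqrt(2/3)
        res = independent_t(IndependentSummary(2.0, 4.0, 1.0, 1.0, 3, 3))
        assert res.t == pytest.approx(-math.sqrt(6.0), abs=1e-9)
        assert res.df == 4
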