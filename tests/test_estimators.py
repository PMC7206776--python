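"""Causal estimators: Wald ratio, IVW, medians, MR-Egger, heterogeneity."""

import numpy as np
import pytest
from scipy import stats

from twosample_mr.errors import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    ValidationError,
)
from twosample_mr.estimators import (
    MREstimate,
    heterogeneity,
    ivw_fixed,
    mr_egger,
    simple_median,
    to_or,
    wald_ratio,
    weighted_median,
)

from conftest import make_instrument, make_instruments


class TestWaldRatio:
    def test_direct_division(self):
        est = wald_ratio(make_instrument(0.05, -0.02, se_out=0.01))
        assert est.theta == pytest.approx(-0.4)
        assert est.se == pytest.approx(0.2)

    def test_allele_flip_symmetry(self):
        est = wald_ratio(make_instrument(-0.05, 0.02, se_out=0.01))
        assert est.theta == pytest.approx(-0.4)
        assert est.se == pytest.approx(0.2)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(make_instrument(0.0, 0.02, se_out=0.01))

    def test_second_order_se_matches_monte_carlo(self):
        """Delta-method SE vs the SD of 10^6 simulated ratio draws."""
        h = make_instrument(0.05, -0.02, se_out=0.01, se_exp=0.007)
        est = wald_ratio(h, second_order=True)
        expected = np.sqrt(0.01**2 / 0.05**2 + 0.02**2 * 0.007**2 / 0.05**4)
        assert est.theta == pytest.approx(-0.4)
        assert est.se == pytest.approx(expected)
        rng = np.random.default_rng(42)
        draws = rng.normal(-0.02, 0.01, 10**6) / rng.normal(0.05, 0.007, 10**6)
        assert est.se == pytest.approx(draws.std(), rel=0.05)

    def test_ci_brackets_point_estimate(self):
        est = wald_ratio(make_instrument(0.05, -0.02, se_out=0.01))
        assert est.ci_low < est.theta < est.ci_high


class TestIVW:
    def test_single_instrument_reduces_to_wald(self):
        h = make_instrument(0.05, -0.02, se_out=0.01)
        assert ivw_fixed([h]) == MREstimate(**{**vars(wald_ratio(h)), "method": "ivw_fe"})

    def test_equal_weights_symmetric_mean(self):
        hs = make_instruments([0.1, 0.1, 0.1], [0.05, 0.10, 0.15], se_out=[1, 1, 1])
        assert ivw_fixed(hs).theta == pytest.approx(1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw_fixed([])

    def test_zero_exposure_effect_names_the_snp(self):
        hs = make_instruments([0.1, 0.0], [0.05, 0.1])
        with pytest.raises(DegenerateInstrumentError, match="rs2"):
            ivw_fixed(hs)

    def test_matches_wls_through_origin(self, random_instances):
        """IVW equals the zero-intercept 1/se_out^2 weighted regression slope."""
        import statsmodels.api as sm

        for hs in random_instances[:20]:
            bx = np.array([h.beta_exp for h in hs])
            by = np.array([h.beta_out for h in hs])
            sy = np.array([h.se_out for h in hs])
            fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
            est = ivw_fixed(hs)
            assert est.theta == pytest.approx(fit.params[0], rel=1e-10)
            # fixed-effect SE is the unit-dispersion WLS SE
            assert est.se == pytest.approx(fit.bse[0] / np.sqrt(fit.mse_resid), rel=1e-10)

    def test_random_effects_never_shrinks_se(self):
        hs = make_instruments([0.1, 0.1, 0.1], [0.05, 0.10, 0.15], se_out=[0.001] * 3)
        fe, re = ivw_fixed(hs), ivw_fixed(hs, random_effects=True)
        assert re.se >= fe.se
        assert re.theta == fe.theta


class TestMedians:
    def test_simple_median_odd(self):
        hs = make_instruments([1, 1, 1], [1, 2, 9])
        assert simple_median(hs, n_boot=50, seed=1).theta == pytest.approx(2.0)

    def test_simple_median_even_averages_middle_pair(self):
        hs = make_instruments([1, 1, 1, 1], [1, 2, 3, 10])
        assert simple_median(hs, n_boot=50, seed=1).theta == pytest.approx(2.5)

    def test_insufficient_instruments(self):
        hs = make_instruments([1, 1], [1, 2])
        with pytest.raises(InsufficientInstrumentsError):
            simple_median(hs, n_boot=50, seed=1)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(hs, n_boot=50, seed=1)

    def test_weighted_median_interpolation_formula(self):
        # ratios {1,2,3}, weights {1,1,2}: p = {0.125, 0.375, 0.75},
        # theta = 2 + (3-2)*(0.5-0.375)/(0.75-0.375) = 7/3
        hs = make_instruments([1.0, 1.0, np.sqrt(2.0)], [1.0, 2.0, 3.0 * np.sqrt(2.0)])
        est = weighted_median(hs, n_boot=50, seed=1)
        assert est.theta == pytest.approx(7.0 / 3.0, rel=1e-12)

    def test_weighted_equals_simple_under_equal_weights(self):
        hs = make_instruments([1, 1, 1, 1, 1], [0.3, -0.1, 0.5, 0.2, 0.4])
        wm = weighted_median(hs, n_boot=50, seed=1).theta
        sm_ = simple_median(hs, n_boot=50, seed=1).theta
        assert wm == pytest.approx(sm_, rel=1e-12)

    def test_bootstrap_se_reproducible_and_stable(self):
        rng = np.random.default_rng(5)
        bx = rng.normal(0.05, 0.02, 5)
        by = rng.normal(0.3 * bx, 0.01)
        hs = make_instruments(bx, by, se_out=[0.01] * 5, se_exp=[0.005] * 5)
        a = simple_median(hs, n_boot=5000, seed=11)
        b = simple_median(hs, n_boot=5000, seed=11)
        assert a.se == b.se  # bit-exact under a fixed seed
        c = simple_median(hs, n_boot=10000, seed=11)
        assert abs(c.se - a.se) / a.se < 0.03

    def test_weighted_median_tolerates_minority_invalid_weight(self):
        """With <50% of weight on pleiotropic SNPs the weighted median stays near
        the truth while IVW is dragged outside the same error band."""
        theta_true = 0.3
        wm_ok = ivw_off = 0
        reps = 200
        rng = np.random.default_rng(99)
        for _ in range(reps):
            bx = rng.normal(0.1, 0.02, 10)
            se_out = np.full(10, 0.01)
            alpha = np.zeros(10)
            alpha[:3] = 0.15  # 3 of 10 SNPs, <50% of total weight
            by = rng.normal(theta_true * bx + alpha, se_out)
            hs = make_instruments(bx, by, se_out=se_out, se_exp=np.full(10, 0.005))
            wm = weighted_median(hs, n_boot=300, seed=int(rng.integers(2**31)))
            if abs(wm.theta - theta_true) <= 2 * wm.se:
                wm_ok += 1
            if abs(ivw_fixed(hs).theta - theta_true) > 2 * wm.se:
                ivw_off += 1
        assert wm_ok / reps > 0.8
        assert ivw_off / reps > 0.8


class TestEgger:
    def test_exact_line_recovered_with_unit_scale(self):
        bx = np.array([0.02, 0.05, 0.08, 0.11])
        by = 0.1 + 0.5 * bx
        res = mr_egger(make_instruments(bx, by, se_out=[0.01, 0.02, 0.03, 0.04]))
        assert res.intercept == pytest.approx(0.1, rel=1e-10)
        assert res.slope.theta == pytest.approx(0.5, rel=1e-10)
        assert res.scale_factor == 1.0

    def test_reorients_to_nonnegative_exposure_effects(self):
        bx = np.array([0.02, -0.05, 0.08, -0.11])
        by = 0.1 + 0.5 * bx
        by[1] += 0.2  # breaks the line only on the original orientation
        by_flipped = np.where(bx < 0, -by, by)
        res1 = mr_egger(make_instruments(bx, by, se_out=[0.01] * 4))
        res2 = mr_egger(make_instruments(np.abs(bx), by_flipped, se_out=[0.01] * 4))
        assert res1.slope.theta == pytest.approx(res2.slope.theta, rel=1e-12)
        assert res1.intercept == pytest.approx(res2.intercept, rel=1e-12)

    def test_matches_free_intercept_wls(self, random_instances):
        import statsmodels.api as sm

        for hs in random_instances[:20]:
            bx = np.abs(np.array([h.beta_exp for h in hs]))
            by = np.where(np.array([h.beta_exp for h in hs]) < 0, -1, 1) * np.array(
                [h.beta_out for h in hs]
            )
            sy = np.array([h.se_out for h in hs])
            fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
            res = mr_egger(hs)
            assert res.intercept == pytest.approx(fit.params[0], rel=1e-10)
            assert res.slope.theta == pytest.approx(fit.params[1], rel=1e-10)
            sigma = np.sqrt(fit.mse_resid)
            assert res.slope.se == pytest.approx(fit.bse[1] / sigma * max(1.0, sigma), rel=1e-10)

    def test_insufficient_and_collinear_inputs_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_instruments([0.1, 0.2], [0.0, 0.1]))
        with pytest.raises(ValidationError, match="collinear"):
            mr_egger(make_instruments([0.1, 0.1, 0.1], [0.0, 0.1, 0.2]))

    def test_balanced_pleiotropy_keeps_intercept_test_nominal(self):
        """Intercept-test rejection at 0.05 stays within Monte-Carlo error of
        nominal over 500 replicates under mean-zero pleiotropy."""
        reps, rejections = 500, 0
        rng = np.random.default_rng(2718)
        for _ in range(reps):
            bx = rng.normal(0.1, 0.03, 30)
            se_out = np.full(30, 0.01)
            alpha = rng.normal(0.0, 0.01, 30)
            by = rng.normal(0.3 * bx + alpha, se_out)
            res = mr_egger(make_instruments(bx, by, se_out=se_out))
            rejections += res.intercept_p < 0.05
        rate = rejections / reps
        band = 2 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= band

    def test_directional_pleiotropy_intercept_recovery(self):
        """Mean fitted intercept over 500 replicates within 10% of the true
        mean pleiotropic effect 0.05 (instruments oriented positive)."""
        reps = 500
        rng = np.random.default_rng(314)
        intercepts = []
        for _ in range(reps):
            bx = np.abs(rng.normal(0.1, 0.03, 30))
            se_out = np.full(30, 0.01)
            alpha = rng.normal(0.05, 0.01, 30)
            by = rng.normal(0.3 * bx + alpha, se_out)
            intercepts.append(mr_egger(make_instruments(bx, by, se_out=se_out)).intercept)
        assert abs(np.mean(intercepts) - 0.05) < 0.005


class TestHeterogeneity:
    def test_i2_formula(self):
        # five unit-weight ratios at sqrt(2) around 0: Q = 10, df = 4, I2 = 60
        hs = make_instruments([1] * 5, [np.sqrt(2)] * 5)
        res = heterogeneity(hs, theta_ref=0.0)
        assert res.Q == pytest.approx(10.0)
        assert res.df == 4
        assert res.I2 == pytest.approx(60.0)
        assert res.pvalue == pytest.approx(stats.chi2.sf(10, 4))

    def test_homogeneous_ratios_give_zero(self):
        hs = make_instruments([1, 2, 4], [0.5, 1.0, 2.0])
        res = heterogeneity(hs, theta_ref=0.5)
        assert res.Q == pytest.approx(0.0)
        assert res.I2 == 0.0

    def test_negative_i2_clamped(self):
        # Q = 3 < df = 4
        hs = make_instruments([1] * 5, [np.sqrt(0.6)] * 5)
        res = heterogeneity(hs, theta_ref=0.0)
        assert res.Q == pytest.approx(3.0)
        assert res.I2 == 0.0

    def test_needs_two_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            heterogeneity(make_instruments([1], [1]), 0.0)


class TestToOR:
    def test_null_effect_centres_at_one(self):
        est = MREstimate("ivw_fe", 0.0, 0.2, -0.39, 0.39, 1.0, 5)
        or_, lo, hi = to_or(est)
        assert or_ == 1.0
        assert lo < 1.0 < hi

    def test_published_vpa_cad_numbers(self):
        """exp(-0.431 +/- 1.96*0.166) prints as OR 0.65 (0.47-0.90)."""
        est = MREstimate("ivw_fe", -0.431, 0.166, 0, 0, 0.009, 5)
        or_, lo, hi = to_or(est)
        assert round(or_, 2) == 0.65
        assert round(lo, 2) == 0.47
        assert round(hi, 2) == 0.90

    def test_zero_se_rejected(self):
        with pytest.raises(ValidationError):
            to_or(MREstimate("ivw_fe", 1.0, 0.0, 1, 1, 0.5, 3))

    def test_continuous_outcome_rejected(self):
        with pytest.raises(TypeError):
            to_or(MREstimate("ivw_fe", 0.1, 0.05, 0, 0.2, 0.04, 3), outcome_type="continuous")
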