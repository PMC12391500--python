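"""Wald, IVW, Egger, heterogeneity, radial, leave-one-out, Steiger, OR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cismr import (
    EstimationError,
    MRResult,
    cochran_q,
    ivw_fixed,
    leave_one_out,
    mr_egger,
    radial_mr,
    steiger_test,
    to_or,
    wald_ratio,
    wald_table,
)

from conftest import make_harmonised


def wls_origin_oracle(bx, by, by_se):
    """Independent route: weighted least squares of by on bx through the
    origin with weights 1/by_se^2 (statsmodels)."""
    return sm.WLS(by, np.asarray(bx)[:, None], weights=1.0 / np.asarray(by_se) ** 2).fit()


def wls_intercept_oracle(bx, by, by_se):
    X = sm.add_constant(np.asarray(bx))
    return sm.WLS(by, X, weights=1.0 / np.asarray(by_se) ** 2).fit()


class TestWaldRatio:
    def test_arithmetic(self):
        v = {"snp_id": "rs1", "bx": 1.0, "bx_se": 0.01, "by": -1.4, "by_se": 0.5}
        w = wald_ratio(v)
        assert w.theta == pytest.approx(-1.4)
        assert w.theta_se == pytest.approx(0.5)

    def test_null_outcome_gives_zero(self):
        v = {"snp_id": "rs1", "bx": 0.3, "bx_se": 0.01, "by": 0.0, "by_se": 0.1}
        assert wald_ratio(v).theta == 0.0

    def test_zero_exposure_beta_names_snp(self):
        v = {"snp_id": "rsZ", "bx": 0.0, "bx_se": 0.01, "by": 1.0, "by_se": 0.1}
        with pytest.raises(EstimationError, match="rsZ"):
            wald_ratio(v)

    def test_derived_example_with_bootstrap_se(self, rng):
        """theta = -0.0735/0.05 = -1.47, first-order se = 0.0125/0.05 = 0.25;
        cross-checked against a parametric bootstrap of the ratio."""
        v = {"snp_id": "rs1", "bx": 0.05, "bx_se": 1e-6,
             "by": -0.0735, "by_se": 0.0125}
        w = wald_ratio(v)
        assert w.theta == pytest.approx(-1.47)
        assert w.theta_se == pytest.approx(0.25)
        boot = rng.normal(-0.0735, 0.0125, size=200_000) / 0.05
        assert np.std(boot) == pytest.approx(0.25, rel=0.02)

    def test_second_order_se_adds_exposure_uncertainty(self):
        v = {"snp_id": "rs1", "bx": 0.05, "bx_se": 0.01,
             "by": -0.0735, "by_se": 0.0125}
        first = wald_ratio(v).theta_se
        second = wald_ratio(v, second_order=True).theta_se
        expected = np.sqrt(0.0125**2 / 0.05**2
                           + 0.0735**2 * 0.01**2 / 0.05**4)
        assert second == pytest.approx(expected)
        assert second > first


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        h = make_harmonised([0.05], [-0.0735], [0.0125])
        res = ivw_fixed(h)
        assert res.beta == -0.0735 / 0.05
        assert res.se == 0.0125 / 0.05
        assert res.n_snps == 1

    def test_equal_weights_average_thetas(self):
        h = make_harmonised([1.0, 1.0], [-1.0, -2.0], [0.5, 0.5])
        assert ivw_fixed(h).beta == pytest.approx(-1.5)

    def test_matches_wls_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 30))
            bx = rng.normal(0.05, 0.02, n)
            bx[np.abs(bx) < 1e-3] = 0.05
            by = rng.normal(-1.5, 0.3) * bx + rng.normal(0, 0.02, n)
            by_se = rng.uniform(0.01, 0.1, n)
            res = ivw_fixed(make_harmonised(bx, by, by_se))
            fit = wls_origin_oracle(bx, by, by_se)
            assert res.beta == pytest.approx(fit.params[0], abs=1e-10)
            assert res.se == pytest.approx(
                np.sqrt(1.0 / np.sum(bx**2 / by_se**2)), abs=1e-12)

    def test_orientation_invariance(self, rng):
        bx = rng.normal(0.05, 0.01, 8)
        by = -1.5 * bx + rng.normal(0, 0.02, 8)
        by_se = rng.uniform(0.02, 0.05, 8)
        base = ivw_fixed(make_harmonised(bx, by, by_se)).beta
        bx2, by2 = bx.copy(), by.copy()
        bx2[3], by2[3] = -bx2[3], -by2[3]
        assert ivw_fixed(make_harmonised(bx2, by2, by_se)).beta == \
            pytest.approx(base, abs=1e-12)

    def test_removing_snp_never_decreases_se(self, rng):
        bx = rng.normal(0.05, 0.01, 10)
        by = -1.5 * bx
        by_se = rng.uniform(0.02, 0.05, 10)
        full = ivw_fixed(make_harmonised(bx, by, by_se)).se
        for i in range(10):
            keep = np.arange(10) != i
            sub = ivw_fixed(make_harmonised(bx[keep], by[keep], by_se[keep]))
            assert sub.se >= full

    def test_empty_set_fatal(self):
        h = make_harmonised([], [], [])
        with pytest.raises(EstimationError):
            ivw_fixed(h)


class TestEgger:
    def test_noiseless_fit_recovers_line(self):
        bx = np.array([0.02, 0.04, 0.06, 0.08])
        c, b = 0.013, -1.2
        by = c + b * bx
        e = mr_egger(make_harmonised(bx, by, np.full(4, 0.05)))
        assert e.intercept == pytest.approx(c, abs=1e-10)
        assert e.slope == pytest.approx(b, abs=1e-10)

    def test_identical_thetas_zero_intercept(self):
        bx = np.array([0.02, 0.04, 0.06, 0.08])
        by = -1.5 * bx
        e = mr_egger(make_harmonised(bx, by, np.full(4, 0.05)))
        assert e.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_wls_oracle_coefficients_ses_pvalues(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 25))
            bx = np.abs(rng.normal(0.05, 0.02, n)) + 1e-3
            by = 0.01 - 1.5 * bx + rng.normal(0, 0.05, n)
            by_se = rng.uniform(0.02, 0.08, n)
            e = mr_egger(make_harmonised(bx, by, by_se))
            fit = wls_intercept_oracle(bx, by, by_se)
            assert e.intercept == pytest.approx(fit.params[0], abs=1e-9)
            assert e.slope == pytest.approx(fit.params[1], abs=1e-9)
            assert e.intercept_se == pytest.approx(fit.bse[0], abs=1e-9)
            assert e.slope_se == pytest.approx(fit.bse[1], abs=1e-9)
            assert e.intercept_p == pytest.approx(fit.pvalues[0], abs=1e-9)

    def test_bx_orientation_rule_makes_result_invariant(self, rng):
        bx = rng.normal(0.0, 0.05, 12)
        bx[np.abs(bx) < 1e-3] = 0.02
        by = 0.01 - 1.5 * bx + rng.normal(0, 0.03, 12)
        by_se = rng.uniform(0.02, 0.05, 12)
        e1 = mr_egger(make_harmonised(bx, by, by_se))
        flip = rng.choice([1.0, -1.0], 12)
        e2 = mr_egger(make_harmonised(bx * flip, by * flip, by_se))
        assert e2.slope == pytest.approx(e1.slope, abs=1e-12)
        assert e2.intercept == pytest.approx(e1.intercept, abs=1e-12)

    def test_fewer_than_three_variants_fatal(self):
        with pytest.raises(EstimationError):
            mr_egger(make_harmonised([0.1, 0.2], [0.1, 0.2], [0.1, 0.1]))


class TestCochranQ:
    def test_homogeneous_set_q_zero_p_one(self):
        bx = np.array([0.02, 0.04, 0.06])
        h = make_harmonised(bx, -1.5 * bx, np.full(3, 0.05))
        het = cochran_q(h, ivw_fixed(h))
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.pval == pytest.approx(1.0)

    def test_two_snp_hand_arithmetic(self):
        # thetas -1 and -2 with weights w1 = 0.04/0.01 = 4, w2 = 4
        h = make_harmonised([0.2, 0.2], [-0.2, -0.4], [0.1, 0.1])
        pooled = ivw_fixed(h)
        assert pooled.beta == pytest.approx(-1.5)
        het = cochran_q(h, pooled)
        # per-SNP: 4 * (0.5)^2 = 1 each; Q = 2, df = 1
        assert het.per_snp_q.tolist() == pytest.approx([1.0, 1.0])
        assert het.q == pytest.approx(2.0)
        assert het.pval == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_q_equals_sum_of_contributions(self, rng):
        bx = rng.normal(0.05, 0.01, 9)
        by = -1.5 * bx + rng.normal(0, 0.05, 9)
        h = make_harmonised(bx, by, rng.uniform(0.02, 0.08, 9))
        het = cochran_q(h, ivw_fixed(h))
        assert het.q == pytest.approx(het.per_snp_q.sum(), abs=1e-9)


class TestRadial:
    def test_homogeneous_set_no_outliers(self):
        bx = np.linspace(0.02, 0.1, 6)
        h = make_harmonised(bx, -1.5 * bx, np.full(6, 0.05))
        rad = radial_mr(h)
        assert rad.outliers == []
        plain = ivw_fixed(h)
        assert rad.result.beta == pytest.approx(plain.beta)
        assert rad.result.se == pytest.approx(plain.se)

    def test_planted_outlier_is_flagged(self):
        """One SNP with a Wald ratio 10 SDs away: its Q contribution is about
        100 >> chi2_{1, 0.05/10} ~ 7.6, so exactly that SNP is removed."""
        m = 10
        bx = np.full(m, 0.05)
        by_se = np.full(m, 0.05)
        by = -1.5 * bx
        theta_se = by_se / bx  # = 1.0 per SNP
        by[4] = (-1.5 + 10 * theta_se[4]) * bx[4]
        rad = radial_mr(make_harmonised(bx, by, by_se))
        assert rad.outliers == ["rs5"]
        assert rad.result.n_snps == m - 1
        assert rad.result.beta == pytest.approx(-1.5, abs=0.3)

    def test_all_flagged_is_fatal(self):
        # three mutually incompatible, ultra-precise estimates
        bx = np.array([0.05, 0.05, 0.05])
        by = np.array([-5.0, 5.0, 10.0]) * 0.05
        by_se = np.full(3, 1e-4)
        with pytest.raises(EstimationError):
            radial_mr(make_harmonised(bx, by, by_se))


class TestLeaveOneOut:
    def test_two_snps_each_result_is_other_wald(self):
        h = make_harmonised([0.05, 0.1], [-0.05, -0.2], [0.02, 0.03])
        results = dict(leave_one_out(h))
        assert results["rs1"].beta == pytest.approx(-0.2 / 0.1)
        assert results["rs2"].beta == pytest.approx(-0.05 / 0.05)

    def test_matches_recomputed_wls_on_subsets(self, rng):
        bx = rng.normal(0.05, 0.01, 5)
        by = -1.5 * bx + rng.normal(0, 0.03, 5)
        by_se = rng.uniform(0.02, 0.05, 5)
        h = make_harmonised(bx, by, by_se)
        for i, (snp, res) in enumerate(leave_one_out(h)):
            keep = np.arange(5) != i
            fit = wls_origin_oracle(bx[keep], by[keep], by_se[keep])
            assert res.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_near_zero_weight_snp_changes_nothing(self):
        bx = np.array([0.05, 0.06, 0.07])
        by = -1.5 * bx
        h_all = make_harmonised(bx, by, np.array([0.02, 0.03, 1e6]))
        res = dict(leave_one_out(h_all))["rs3"]
        full = ivw_fixed(h_all)
        assert res.beta == pytest.approx(full.beta, abs=1e-9)


class TestSteiger:
    def _h(self, bx, bx_se, by, eaf=0.3):
        return make_harmonised(bx, by, np.full(len(bx), 0.1),
                               bx_se=bx_se, eaf=eaf)

    def test_dominant_exposure_r2_correct_direction(self):
        # z = 20 on n = 10,000 -> r2_exp ~ 0.038; tiny outcome log-OR
        h = self._h([0.2], [0.01], [0.001])
        res = steiger_test(h, n_exposure=10_000, ncase=5_000, ncontrol=5_000)
        assert res.direction_correct
        assert res.r2_exposure > 0.03
        assert res.r2_outcome < 1e-4
        assert res.pval < 1e-10

    def test_equal_r2_indeterminate(self):
        # construct outcome log-OR with identical implied r2
        n = 10_000
        bx, bx_se = 0.2, 0.01
        t = bx / bx_se
        r2 = t**2 / (t**2 + n - 2)
        eaf, phi = 0.3, 0.5
        by = np.sqrt(r2 / (2 * eaf * (1 - eaf) * phi * (1 - phi)))
        h = self._h([bx], [bx_se], [by], eaf=eaf)
        res = steiger_test(h, n_exposure=n, ncase=5_000, ncontrol=5_000)
        assert res.pval == pytest.approx(1.0, abs=1e-6)

    def test_missing_sample_sizes_fatal(self):
        h = self._h([0.2], [0.01], [0.001])
        with pytest.raises(EstimationError, match="sample size"):
            steiger_test(h, n_exposure=5, ncase=5_000, ncontrol=5_000)


class TestToOR:
    def test_null_beta_gives_or_one(self):
        r = MRResult(method="ivw_fe", beta=0.0, se=0.1, ci_low=-0.196,
                     ci_high=0.196, pval=1.0, n_snps=1)
        assert to_or(r).or_ == pytest.approx(1.0)

    def test_study_scale_example_rounds_to_printed_interval(self):
        """exp(-1.4697 +/- 1.96 x 0.2588) -> OR 0.23 (0.14-0.38)."""
        beta, se = -1.4697, 0.2588
        r = to_or(MRResult(method="ivw_fe", beta=beta, se=se,
                           ci_low=beta - 1.959964 * se,
                           ci_high=beta + 1.959964 * se,
                           pval=1e-8, n_snps=44))
        assert round(r.or_, 2) == 0.23
        assert round(r.or_low, 2) == 0.14
        assert round(r.or_high, 2) in (0.38, 0.39)
        assert r.or_low < r.or_ < r.or_high

    def test_log_or_inverse(self):
        r = MRResult(method="ivw_fe", beta=np.log(1.21), se=0.05,
                     ci_low=0.1, ci_high=0.3, pval=0.01, n_snps=3)
        assert to_or(r).or_ == pytest.approx(1.21)


@settings(derandomize=True, max_examples=100)
@given(
    n=st.integers(3, 20),
    data=st.data(),
)
def test_ivw_invariant_to_joint_reorientation_of_any_subset(n, data):
    """Negating (bx, by) jointly for an arbitrary subset of SNPs is a pure
    relabelling of effect alleles and leaves the IVW estimate unchanged."""
    finite = st.floats(-2.0, 2.0, allow_nan=False)
    bx = np.array(data.draw(st.lists(finite.filter(lambda v: abs(v) > 1e-3),
                                     min_size=n, max_size=n)))
    by = np.array(data.draw(st.lists(finite, min_size=n, max_size=n)))
    by_se = np.array(data.draw(st.lists(st.floats(0.01, 1.0), min_size=n,
                                        max_size=n)))
    signs = np.where(np.array(data.draw(
        st.lists(st.booleans(), min_size=n, max_size=n))), -1.0, 1.0)
    a = ivw_fixed(make_harmonised(bx, by, by_se))
    b = ivw_fixed(make_harmonised(bx * signs, by * signs, by_se))
    assert b.beta == pytest.approx(a.beta, rel=1e-9, abs=1e-12)
    assert b.se == pytest.approx(a.se, rel=1e-9)


def test_wald_table_shape_and_values():
    h = make_harmonised([0.05, 0.1], [-0.0735, -0.2], [0.0125, 0.03])
    t = wald_table(h)
    assert list(t.columns) == ["snp_id", "bx", "by", "theta", "theta_se"]
    assert t.loc[0, "theta"] == pytest.approx(-1.47)
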