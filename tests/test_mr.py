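"""Two-sample MR estimators, diagnostics, and reporting arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from targetmr.exceptions import UndefinedRatioError, ValidationError
from targetmr.mr import (
    MRModel,
    RatioEstimate,
    bh_fdr,
    cochran_q,
    ivw,
    leave_one_out,
    or_ci,
    p_from_or_ci,
    sign_concordant,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from targetmr.simulate import simulate_mr_pair
from targetmr.sumstats import HarmonizedPair


def make_pair(bx, by, sx=None, sy=None):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    k = len(bx)
    sx = np.full(k, 0.01) if sx is None else np.asarray(sx, float)
    sy = np.full(k, 0.05) if sy is None else np.asarray(sy, float)
    return HarmonizedPair("x", "y", [f"rs{i}" for i in range(k)], bx, sx, by, sy)


class TestWald:
    def test_forced_arithmetic(self):
        res = wald_ratio(make_pair([0.2], [0.1], sy=[0.05]))
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.25)

    def test_null_outcome(self):
        res = wald_ratio(make_pair([0.2], [0.0]))
        assert res.beta == 0.0
        assert res.pval == pytest.approx(1.0)

    def test_zero_exposure_beta_errors(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(make_pair([0.0], [0.1]))

    def test_single_instrument_recovery(self):
        """Mean Wald estimate within 0.05 of a true effect of 0.4."""
        ests = []
        for i in range(500):
            pair, _ = simulate_mr_pair(1, 0.4, seed=90_000 + i, se_y=0.02)
            ests.append(wald_ratio(pair).beta)
        assert np.mean(ests) == pytest.approx(0.4, abs=0.05)


class TestIVW:
    def test_hand_computed_weighted_mean(self):
        # ratios {0.5, 0.6, 0.45} with ratio ses {0.2, 0.1, 0.05}:
        # weights {25, 100, 400}; weighted mean 252.5/525
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.5, 0.6, 0.45])
        sy = np.array([0.2, 0.1, 0.05])
        res = ivw(make_pair(bx, by, sy=sy))
        assert res.beta == pytest.approx(252.5 / 525, abs=1e-9)
        assert res.beta == pytest.approx(0.4810, abs=5e-5)
        assert res.se_fixed == pytest.approx(525**-0.5, abs=1e-9)
        assert res.se_fixed == pytest.approx(0.04364, abs=5e-6)
        assert res.se >= res.se_fixed  # multiplicative RE never deflates

    def test_duplicated_snp_equals_wald(self):
        single = wald_ratio(make_pair([0.2], [0.1]))
        dup = ivw(make_pair([0.2, 0.2], [0.1, 0.1]))
        assert dup.beta == pytest.approx(single.beta)

    def test_ivw_on_single_ratio_equals_wald(self):
        pair = make_pair([0.2], [0.1])
        assert ivw(pair).beta == pytest.approx(wald_ratio(pair).beta)
        assert ivw(pair).se == pytest.approx(wald_ratio(pair).se)

    def test_coverage_under_balanced_pleiotropy(self):
        hits = 0
        for i in range(500):
            pair, _ = simulate_mr_pair(20, 0.3, seed=40_000 + i, pleiotropy_sd=0.05)
            r = MRModel(pair).fit("ivw")
            hits += r.ci_low <= np.exp(0.3) <= r.ci_high
        assert 0.90 <= hits / 500 <= 0.985


class TestEgger:
    def test_exact_linearity_recovers_slope_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        res = MRModel(make_pair(bx, 0.7 * bx)).fit("egger")
        assert res.beta == pytest.approx(0.7, abs=1e-9)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_directional_pleiotropy_intercept_recovery(self):
        icepts = []
        rng = np.random.default_rng(77)
        for i in range(500):
            a = rng.uniform(0.05, 0.2, 30)
            by = 0.3 * a + 0.02 + rng.normal(0, 0.02, 30)
            res = MRModel(make_pair(a, by, sy=np.full(30, 0.02))).fit("egger")
            icepts.append(res.egger_intercept)
        assert np.mean(icepts) == pytest.approx(0.02, abs=0.01)

    def test_equal_weights_matches_ols_oracle(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = np.array([0.15, 0.22, 0.35])
        res = MRModel(make_pair(bx, by, sy=np.full(3, 0.05))).fit("egger")
        slope, icpt = np.polyfit(bx, by, 1)
        assert res.beta == pytest.approx(slope, abs=1e-9)
        assert res.egger_intercept == pytest.approx(icpt, abs=1e-9)

    def test_requires_three_snps(self):
        with pytest.raises(ValidationError):
            MRModel(make_pair([0.1, 0.2], [0.1, 0.2])).fit("egger")


class TestWeightedMedian:
    def test_equal_weights_middle_element(self):
        res = weighted_median(make_pair([1, 1, 1], [0.1, 0.5, 0.9]), seed=1)
        assert res.beta == pytest.approx(0.5)

    def test_dominant_weight_returns_that_ratio(self):
        # first ratio's weight is ~96% of the total
        sy = np.array([0.01, 0.05, 0.05])
        res = weighted_median(make_pair([1, 1, 1], [0.1, 0.5, 0.9], sy=sy), seed=1)
        assert res.beta == pytest.approx(0.1)

    def test_matches_interpolation_oracle(self):
        rng = np.random.default_rng(5)
        ratios = rng.normal(0.4, 0.2, 7)
        sy = rng.uniform(0.04, 0.2, 7)
        res = weighted_median(make_pair(np.ones(7), ratios, sy=sy), seed=2)
        # independent oracle: sort, midpoint knots, np.interp at 0.5
        w = 1.0 / sy**2
        w = w / w.sum()
        order = np.argsort(ratios)
        r_s, w_s = ratios[order], w[order]
        knots = np.cumsum(w_s) - 0.5 * w_s
        assert res.beta == pytest.approx(float(np.interp(0.5, knots, r_s)), abs=1e-12)

    def test_bootstrap_se_reproducible(self):
        pair, _ = simulate_mr_pair(8, 0.2, seed=61)
        a = weighted_median(pair, seed=9)
        b = weighted_median(pair, seed=9)
        assert a.se == b.se


class TestWeightedMode:
    def test_degenerate_cluster(self):
        res = weighted_mode(make_pair([1, 1, 1], [0.3, 0.3, 0.3]), seed=3)
        assert res.beta == pytest.approx(0.3)
        assert res.se == 0.0

    def test_cluster_beats_outlier(self):
        bx = np.ones(6)
        by = np.array([0.29, 0.30, 0.31, 0.30, 0.30, 2.0])
        res = weighted_mode(make_pair(bx, by), seed=4)
        assert res.beta == pytest.approx(0.30, abs=0.05)

    def test_less_biased_than_ivw_with_invalid_instruments(self):
        """60% valid instruments: mode tracks the valid cluster better."""
        rng = np.random.default_rng(11)
        bias_ivw, bias_mode = [], []
        for _ in range(300):
            a = rng.uniform(0.08, 0.2, 10)
            by = 0.3 * a
            by[6:] += rng.uniform(0.05, 0.1, 4)  # 4 invalid, shared bias
            pair = make_pair(a, rng.normal(by, 0.01), sy=np.full(10, 0.01))
            m = MRModel(pair, n_boot=1, seed=1)
            bias_ivw.append(m.fit("ivw").beta - 0.3)
            bias_mode.append(m.fit("weighted_mode").beta - 0.3)
        assert abs(np.mean(bias_mode)) < abs(np.mean(bias_ivw))


class TestCochranQ:
    def test_identical_ratios(self):
        ratios = [RatioEstimate(f"rs{i}", 0.4, 0.1) for i in range(3)]
        q, p = cochran_q(ratios, 0.4)
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_evaluated(self):
        ratios = [RatioEstimate("a", 0.0, 0.5), RatioEstimate("b", 1.0, 0.5)]
        q, p = cochran_q(ratios, 0.5)
        assert q == pytest.approx(2.0)
        assert p == pytest.approx(sps.chi2.sf(2, 1), abs=1e-12)
        assert p == pytest.approx(0.157, abs=5e-4)

    def test_null_uniformity(self):
        """Q p-values under homogeneous instruments are uniform (KS)."""
        ps = []
        for i in range(2000):
            pair, _ = simulate_mr_pair(10, 0.3, seed=i)
            ps.append(MRModel(pair).fit("ivw").q_pval)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestLeaveOneOut:
    def test_identical_snps_leave_estimate_unchanged(self):
        res = leave_one_out(make_pair([0.2] * 3, [0.1] * 3))
        full = ivw(make_pair([0.2] * 3, [0.1] * 3))
        for row in res:
            assert row["result"].beta == pytest.approx(full.beta)
            assert not row["flagged"]

    def test_planted_outlier_flagged(self):
        bx = np.array([0.1, 0.12, 0.15, 0.2, 0.11])
        by = 0.3 * bx
        by[2] = 0.5  # gross outlier instrument
        res = leave_one_out(make_pair(bx, by, sy=np.full(5, 0.01)))
        assert res[2]["flagged"]

    def test_each_subset_matches_direct_ivw(self):
        pair, _ = simulate_mr_pair(5, 0.25, seed=8)
        res = leave_one_out(pair)
        for i, row in enumerate(res):
            keep = [j for j in range(5) if j != i]
            direct = ivw(pair.subset(keep))
            assert row["result"].beta == pytest.approx(direct.beta, abs=1e-12)


class TestFDRAndReporting:
    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_bh_constant_input(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_bh_dominates_raw_and_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        adj = bh_fdr(p)
        assert np.all(adj >= p)
        from statsmodels.stats.multitest import multipletests

        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, sm_adj, atol=1e-12)

    def test_or_ci_null_symmetric(self):
        o, lo, hi = or_ci(0.0, 0.1)
        assert o == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)

    def test_or_ci_reconstructs_printed_sparc_row(self):
        # printed OR 2.949 with 95% CI 1.653-5.26
        beta = np.log(2.949)
        se = (np.log(5.26) - np.log(1.653)) / 3.92
        o, lo, hi = or_ci(beta, se)
        assert lo == pytest.approx(1.653, rel=5e-4)
        assert hi == pytest.approx(5.26, rel=5e-4)

    def test_or_ci_reconstructs_printed_hypertension_row(self):
        beta = np.log(370.060)
        se = (np.log(2967.758) - np.log(46.144)) / (2 * 1.959964)
        o, lo, hi = or_ci(beta, se)
        assert lo == pytest.approx(46.144, rel=1e-3)
        assert hi == pytest.approx(2967.758, rel=1e-3)

    def test_p_from_or_ci_identity_and_printed_values(self):
        assert p_from_or_ci(1.0, 0.5, 2.0) == pytest.approx(1.0)
        assert p_from_or_ci(27.842, 1.042, 743.623) == pytest.approx(4.72e-2, rel=0.02)
        assert p_from_or_ci(2.933, 1.519, 5.664) == pytest.approx(1.35e-3, rel=0.02)
        with pytest.raises(ValidationError):
            p_from_or_ci(2.0, 2.5, 3.0)

    def test_or_ci_then_p_roundtrip(self):
        o, lo, hi = or_ci(0.4, 0.1)
        p_direct = float(2 * sps.norm.sf(4.0))
        assert p_from_or_ci(o, lo, hi) == pytest.approx(p_direct, rel=1e-9)


class TestEstimatorProperties:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(flip_seed=st.integers(0, 1000))
    def test_sign_flip_invariance(self, flip_seed):
        pair, _ = simulate_mr_pair(6, 0.3, seed=14)
        rng = np.random.default_rng(flip_seed)
        signs = rng.choice([-1.0, 1.0], size=6)
        flipped = HarmonizedPair(
            "x", "y", pair.snp_ids,
            pair.beta_x * signs, pair.se_x, pair.beta_y * signs, pair.se_y,
        )
        for method in ("ivw", "egger", "weighted_median"):
            a = MRModel(pair, seed=1, n_boot=50).fit(method)
            b = MRModel(flipped, seed=1, n_boot=50).fit(method)
            assert a.beta == pytest.approx(b.beta, abs=1e-9)

    def test_type_one_error_in_band(self):
        rej = {"ivw": 0, "egger": 0}
        reps = 500
        for i in range(reps):
            pair, _ = simulate_mr_pair(20, 0.0, seed=10_000 + i)
            m = MRModel(pair)
            for meth in rej:
                rej[meth] += m.fit(meth).pval < 0.05
        for meth, k in rej.items():
            assert 0.02 <= k / reps <= 0.09, (meth, k / reps)

    def test_sign_concordance_helper(self):
        pair, _ = simulate_mr_pair(6, 0.5, seed=15, se_y=0.005)
        res = MRModel(pair, seed=1, n_boot=50).fit_all()
        assert sign_concordant(res)
        res["fake"] = MRModel(pair, seed=1).fit("ivw")
        res["fake"].beta = -res["fake"].beta
        assert not sign_concordant(res)
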