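"""Formula-level checks of every richness estimator against independent
hand/script oracles, plus their structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import treerich as tr
from conftest import make_counts
from treerich.estimators import (
    AlphaUnboundedError,
    UndefinedCoverageError,
    _chao2_core,
)

REL = 1e-10

# frozen values from a 40-digit mpmath evaluation of the closed forms,
# written independently of the implementation under test
CI_ORACLE = {
    "var": 1.411875,
    "K": 16.84335120513178055722518634124585782531,
    "lower": 5.026716773551743989102083919665481684,
    "upper": 12.579508042309301250751333853560636021,
}
ALPHA_S1_N1000 = 0.1096716145691772236076947601821595023847
FISHER_GLOBAL_S = 62998.72814735708991321224620117753805254


class TestCoverage:
    def test_no_singletons_means_complete_coverage(self):
        c = make_counts(s_obs=10, T=None, q1=0, q2=3, n=100, mode="abundance")
        assert tr.sample_coverage(c).c_n == 1.0

    def test_hand_arithmetic_example(self):
        c = make_counts(s_obs=3, T=None, q1=2, q2=1, n=10, mode="abundance")
        assert tr.sample_coverage(c).c_n == pytest.approx(0.82, rel=REL)

    def test_all_singletons_zero_coverage(self):
        c = make_counts(s_obs=5, T=None, q1=5, q2=0, n=5, mode="abundance")
        assert tr.sample_coverage(c).c_n == 0.0

    def test_empty_sample_is_an_error(self):
        with pytest.raises(UndefinedCoverageError):
            tr.sample_coverage(make_counts(0, None, 0, 0, n=0, mode="abundance"))

    @given(st.integers(0, 50), st.integers(0, 50))
    def test_bounded_and_nonincreasing_in_singletons(self, f1, f2):
        n = 500
        c = tr.sample_coverage(make_counts(f1 + f2, None, f1, f2, n=n,
                                           mode="abundance")).c_n
        assert 0.0 <= c <= 1.0
        c_more = tr.sample_coverage(make_counts(f1 + f2 + 1, None, f1 + 1, f2,
                                                n=n, mode="abundance")).c_n
        assert c_more <= c + 1e-12


class TestChao2:
    def test_no_uniques_no_correction(self):
        c = make_counts(s_obs=7, T=10, q1=0, q2=3)
        assert tr.chao2(c).point == 7.0

    @pytest.mark.parametrize(
        "s,T,q1,q2,expected",
        [(5, 10, 2, 1, 5.45), (10, 100, 3, 0, 12.97)],
    )
    def test_hand_arithmetic_examples(self, s, T, q1, q2, expected):
        c = make_counts(s_obs=s, T=T, q1=q1, q2=q2)
        assert tr.chao2(c).point == pytest.approx(expected, rel=REL)

    def test_abundance_mode_rejected(self):
        with pytest.raises(ValueError, match="incidence"):
            tr.chao2(make_counts(5, None, 2, 1, mode="abundance"))

    @given(st.integers(1, 40), st.integers(0, 30), st.integers(0, 30),
           st.integers(2, 500))
    def test_lower_bound_property(self, extra, q1, q2, T):
        s_obs = q1 + q2 + extra
        est = tr.chao2(make_counts(s_obs=s_obs, T=T, q1=q1, q2=q2))
        assert est.point >= s_obs


class TestChao2CI:
    def test_degenerate_when_no_excess(self):
        est = tr.chao2_ci(tr.chao2(make_counts(s_obs=7, T=10, q1=0, q2=3)))
        assert est.ci_lower == est.ci_upper == 7.0

    def test_against_independent_script_oracle(self):
        est = tr.chao2_ci(tr.chao2(make_counts(s_obs=5, T=10, q1=2, q2=1)))
        assert est.variance == pytest.approx(CI_ORACLE["var"], rel=REL)
        assert est.K == pytest.approx(CI_ORACLE["K"], rel=REL)
        assert est.ci_lower == pytest.approx(CI_ORACLE["lower"], rel=REL)
        assert est.ci_upper == pytest.approx(CI_ORACLE["upper"], rel=REL)
        assert est.ci_lower >= est.s_obs

    def test_vanishing_variance_limit_collapses_to_point(self):
        # drive var -> 0 through the core with a tiny synthetic variance
        point, _ = _chao2_core(5, 10, 2, 1)
        E = point - 5
        for var in (1e-6, 1e-12):
            K = math.exp(1.959963984540054 * math.sqrt(math.log1p(var / E**2)))
            assert K == pytest.approx(1.0, abs=1e-2)
        est = tr.chao2_ci(tr.chao2(make_counts(s_obs=5, T=10, q1=2, q2=1)))
        assert est.ci_lower <= est.point <= est.ci_upper


class TestTrueUniques:
    def test_hand_arithmetic_primary_parse(self):
        c = make_counts(s_obs=100, T=100, q1=10, q2=30, q3=20, q4=10)
        q1_hat, fallback = tr.estimate_true_uniques(c)
        assert not fallback
        assert q1_hat == pytest.approx(37.05075, rel=REL)

    def test_squared_first_term_variant(self):
        c = make_counts(s_obs=100, T=100, q1=10, q2=30, q3=20, q4=10)
        q1_hat, _ = tr.estimate_true_uniques(c, squared_first_term=True)
        # A^2 * 2*30^2/(3*20) + 7.35075, A = 0.99
        assert q1_hat == pytest.approx(0.9801 * 30.0 + 7.35075, rel=REL)

    @pytest.mark.parametrize("q3,q4", [(0, 5), (5, 0), (0, 0)])
    def test_degenerate_tallies_fall_back_to_observed(self, q3, q4):
        c = make_counts(s_obs=50, T=40, q1=12, q2=8, q3=q3, q4=q4)
        q1_hat, fallback = tr.estimate_true_uniques(c)
        assert fallback and q1_hat == 12.0

    def test_negative_estimate_clamps_to_zero(self):
        # large Q3 relative to Q2/Q4 drives the second term strongly negative
        c = make_counts(s_obs=100, T=50, q1=5, q2=1, q3=40, q4=1)
        q1_hat, fallback = tr.estimate_true_uniques(c)
        assert not fallback and q1_hat == 0.0


class TestAdjustedChao2:
    def test_zero_true_uniques_returns_observed(self):
        c = make_counts(s_obs=8, T=20, q1=4, q2=2)
        assert tr.adjusted_chao2(c, 0.0).point == 8.0

    def test_hand_arithmetic_fractional_uniques(self):
        c = make_counts(s_obs=5, T=10, q1=2, q2=1)
        assert tr.adjusted_chao2(c, 1.2).point == pytest.approx(5.054, rel=REL)

    def test_reproduces_plain_chao2_bit_for_bit(self):
        c = make_counts(s_obs=50, T=80, q1=14, q2=6, q3=3, q4=2)
        raw = tr.chao2_ci(tr.chao2(c))
        adj = tr.adjusted_chao2(c, float(c.q1))
        assert adj.point == raw.point
        assert adj.variance == raw.variance
        assert adj.ci_lower == raw.ci_lower and adj.ci_upper == raw.ci_upper

    def test_uncapped_above_observed_uniques(self):
        c = make_counts(s_obs=50, T=80, q1=5, q2=6, q3=3, q4=2)
        raw = tr.chao2(c)
        adj = tr.adjusted_chao2(c, 12.0)
        assert adj.point > raw.point

    def test_negative_q1_hat_rejected(self):
        with pytest.raises(ValueError):
            tr.adjusted_chao2(make_counts(5, 10, 2, 1), -0.5)


class TestFisher:
    def test_self_consistency_of_fitted_alpha(self):
        rng = np.random.default_rng(5)
        counts = tr.sample_logseries_counts(20.0, 5_000, rng)
        fit = tr.fisher_alpha_fit(counts)
        assert abs(fit.s_obs - fit.alpha * math.log1p(fit.n / fit.alpha)) \
            <= 1e-6 * fit.s_obs

    def test_single_species_against_bisection_oracle(self):
        fit = tr.fisher_alpha_fit([1000])
        assert fit.alpha == pytest.approx(ALPHA_S1_N1000, rel=1e-8)

    def test_all_singletons_unbounded(self):
        with pytest.raises(AlphaUnboundedError):
            tr.fisher_alpha_fit([1, 1, 1])

    def test_richness_equation_collapses_at_e_minus_1(self):
        alpha = 7.5
        assert tr.fisher_richness(alpha, alpha * (math.e - 1)) == \
            pytest.approx(alpha, rel=REL)

    def test_richness_equation_saturates_to_n(self):
        n = 1000.0
        assert tr.fisher_richness(1e9 * n, n) == pytest.approx(n, rel=1e-6)

    def test_global_richness_against_extended_precision_oracle(self):
        assert tr.fisher_richness(3040.0, 3.04e12) == \
            pytest.approx(FISHER_GLOBAL_S, rel=REL)

    def test_bootstrap_ci_tracks_point_estimate(self):
        # resampling individuals loses singletons, so the replicate alphas
        # (and hence the percentile interval) sit slightly below the full-
        # sample fit; the interval must still be ordered and nearby
        rng = np.random.default_rng(9)
        counts = tr.sample_logseries_counts(30.0, 10_000, rng)
        fit = tr.fisher_alpha_fit(counts)
        lo, hi = tr.fisher_alpha_ci(counts, n_boot=100, seed=1)
        assert lo < hi
        assert abs(lo - fit.alpha) / fit.alpha < 0.25
        assert abs(hi - fit.alpha) / fit.alpha < 0.25


class TestLogseriesGoF:
    def test_null_data_accepted(self):
        rng = np.random.default_rng(2)
        counts = tr.sample_logseries_counts(50.0, 50_000, rng)
        d, p = tr.logseries_gof(counts)
        assert d < 0.1 and p > 0.05

    def test_conservative_rejection_rate_under_null(self):
        rejected = 0
        n_draws = 40
        for seed in range(n_draws):
            rng = np.random.default_rng(seed)
            counts = tr.sample_logseries_counts(50.0, 50_000, rng)
            _, p = tr.logseries_gof(counts)
            rejected += p < 0.05
        assert rejected / n_draws <= 0.10

    def test_geometric_abundances_fit_worse_than_null(self):
        rng = np.random.default_rng(3)
        null_counts = tr.sample_logseries_counts(50.0, 50_000, rng)
        d_null, _ = tr.logseries_gof(null_counts)
        geo = rng.geometric(0.2, size=len(null_counts))
        d_geo, _ = tr.logseries_gof(geo)
        assert d_geo > d_null

    def test_refuses_degenerate_input(self):
        with pytest.raises(ValueError, match="distinct"):
            tr.logseries_gof([1, 1, 2, 2])


def test_estimators_are_pure_functions_of_tallies():
    c = make_counts(s_obs=60, T=90, q1=20, q2=9, q3=4, q4=3)
    runs = [
        (tr.sample_coverage(c).c_n, tr.chao2_ci(tr.chao2(c)).ci_upper,
         tr.estimate_true_uniques(c)[0])
        for _ in range(3)
    ]
    assert runs[0] == runs[1] == runs[2]
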