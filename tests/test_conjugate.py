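import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from dhatrial.config import Direction, McmcSettings
from dhatrial.conjugate import (
    BetaPosterior,
    NormalSummary,
    fit_beta_binomial,
    impute_missing_binary,
    normal_prob_better,
    number_needed_to_treat,
    prob_better,
    prob_less_exact,
    summarize_rate,
)

FAST = McmcSettings(burn_in=100, keep=20_000, seed=7)


class TestConjugateUpdate:
    @pytest.mark.parametrize(
        "events,n,expected",
        [(9, 540, (10, 532)), (12, 492, (13, 481)), (0, 0, (1, 1))],
    )
    def test_flat_prior_update(self, events, n, expected):
        post = fit_beta_binomial(events, n)
        assert (post.alpha, post.beta) == expected

    def test_events_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_binomial(5, 4)

    @given(st.integers(0, 50), st.integers(0, 200))
    def test_pseudocounts_accumulate(self, events, extra):
        n = events + extra
        post = fit_beta_binomial(events, n)
        assert post.alpha + post.beta == pytest.approx(2 + n)


class TestProbBetter:
    @pytest.mark.parametrize(
        "a,b",
        [((1, 11), (6, 6)), ((10, 532), (13, 481)), ((3, 7), (2, 18)), ((51, 491), (59, 435))],
    )
    def test_quadrature_and_mc_match_exact_formula(self, a, b):
        pa, pb = BetaPosterior(*a), BetaPosterior(*b)
        exact = prob_less_exact(pa, pb)
        quad = prob_better(pa, pb, Direction.LOWER_IS_BETTER, method="quadrature")
        mc = prob_better(pa, pb, Direction.LOWER_IS_BETTER, method="monte_carlo", settings=FAST)
        assert quad == pytest.approx(exact, abs=1e-6)
        assert mc == pytest.approx(exact, abs=2e-3)

    def test_identical_posteriors_are_a_coin_flip(self):
        p = BetaPosterior(10, 532)
        for method in ("quadrature", "monte_carlo"):
            assert prob_better(p, p, method=method, settings=FAST) == pytest.approx(0.5, abs=1e-3)

    def test_complement_identity(self):
        a, b = BetaPosterior(10, 532), BetaPosterior(13, 481)
        fwd = prob_better(a, b, method="quadrature")
        rev = prob_better(b, a, method="quadrature")
        assert fwd + rev == pytest.approx(1.0, abs=1e-8)

    def test_monotone_in_high_arm_events(self):
        low = fit_beta_binomial(12, 492)
        pps = [
            prob_better(fit_beta_binomial(e, 540), low, method="quadrature")
            for e in (5, 9, 15, 25)
        ]
        assert all(x > y for x, y in zip(pps, pps[1:]))

    def test_mc_is_seed_reproducible(self):
        a, b = BetaPosterior(10, 532), BetaPosterior(13, 481)
        s = McmcSettings(keep=5000, seed=123)
        assert prob_better(a, b, method="monte_carlo", settings=s) == prob_better(
            a, b, method="monte_carlo", settings=s
        )


class TestSummaries:
    def test_uniform_prior_summary(self):
        s = summarize_rate(BetaPosterior(1, 1))
        assert s.post_mean == pytest.approx(50.0)
        assert s.cri_low == pytest.approx(2.5, abs=0.01)
        assert s.cri_high == pytest.approx(97.5, abs=0.01)

    @pytest.mark.parametrize(
        "post,mean_pct",
        [(BetaPosterior(10, 532), 1.845), (BetaPosterior(13, 481), 2.632)],
    )
    def test_epb_rate_summaries(self, post, mean_pct):
        s = summarize_rate(post)
        assert s.post_mean == pytest.approx(mean_pct, abs=0.005)
        d = stats.beta(post.alpha, post.beta)
        assert s.cri_low == pytest.approx(100 * d.ppf(0.025), abs=1e-6)
        assert s.cri_high == pytest.approx(100 * d.ppf(0.975), abs=1e-6)
        if post.alpha == 10:
            assert 0.5 < s.cri_low and s.cri_high < 3.5

    def test_interval_coverage_calibration(self):
        """Central 95% intervals cover a known rate ~95% of the time."""
        rng = np.random.default_rng(11)
        truth = 0.03
        hits = 0
        for _ in range(200):
            e = rng.binomial(500, truth)
            s = summarize_rate(fit_beta_binomial(e, 500))
            hits += s.cri_low <= 100 * truth <= s.cri_high
        assert abs(hits / 200 - 0.95) <= 0.04


class TestNormalModel:
    def test_identical_summaries_are_a_coin_flip(self):
        a = NormalSummary(100.0, 10.0, 50)
        res = normal_prob_better(a, a, settings=FAST)
        assert res.pp_high_better == pytest.approx(0.5, abs=0.01)

    def test_quadrature_matches_mc(self):
        hi = NormalSummary(3326, 542, 539)
        lo = NormalSummary(3264, 574, 489)
        q = normal_prob_better(hi, lo, method="quadrature", settings=FAST)
        m = normal_prob_better(hi, lo, method="monte_carlo", settings=FAST)
        assert m.pp_high_better == pytest.approx(q.pp_high_better, abs=2e-3)

    def test_large_n_matches_normal_approximation(self):
        hi = NormalSummary(271.8, 11.1, 540)
        lo = NormalSummary(269.9, 16.3, 492)
        res = normal_prob_better(hi, lo, settings=FAST)
        se = np.hypot(11.1 / np.sqrt(540), 16.3 / np.sqrt(492))
        approx = stats.norm.cdf((271.8 - 269.9) / se)
        assert res.pp_high_better == pytest.approx(approx, abs=0.005)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            NormalSummary(10.0, 1.0, 1)


class TestNnt:
    @pytest.mark.parametrize(
        "high,low,expected", [(1.7, 2.9, 83), (2.5, 4.8, 43), (1.4, 1.6, 500)]
    )
    def test_reported_arithmetic(self, high, low, expected):
        assert number_needed_to_treat(high, low) == expected

    def test_equal_rates_undefined(self):
        with pytest.raises(ZeroDivisionError):
            number_needed_to_treat(2.0, 2.0)

    def test_harm_direction_is_signed(self):
        assert number_needed_to_treat(4.0, 2.0) == -50


class TestImputation:
    def test_no_missing_reduces_to_conjugate(self):
        imp = impute_missing_binary(9, 540, 0, settings=FAST)
        assert imp.mean_rate() == pytest.approx(10 / 542)

    def test_imputation_is_mean_preserving(self):
        imp = impute_missing_binary(9, 540, 36, settings=McmcSettings(keep=50_000, seed=3))
        assert imp.mean_rate() == pytest.approx(10 / 542, abs=5e-4)

    def test_no_data_completed_counts_are_beta_binomial(self):
        imp = impute_missing_binary(0, 0, 10, settings=McmcSettings(keep=100_000, seed=5))
        pmf = imp.completed_event_pmf()
        oracle = stats.betabinom.pmf(np.arange(11), 10, 1, 1)
        assert np.allclose(pmf, oracle, atol=0.01)

    def test_pp_against_unimputed_arm(self):
        a = impute_missing_binary(9, 540, 36, settings=FAST)
        b = impute_missing_binary(12, 492, 32, settings=FAST)
        pp = a.prob_better_than(b, settings=FAST)
        # imputation is mean-preserving, so pp stays near the observed-data pp
        assert pp == pytest.approx(0.807, abs=0.03)
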