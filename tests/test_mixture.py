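import numpy as np
import pytest
from scipy import integrate, stats

from dhatrial.config import Direction, McmcSettings
from dhatrial.mixture import (
    DegenerateDataError,
    MixtureState,
    _log_likelihood,
    compare_arms_mixture,
    epb_rate_from_state,
    fit_mixture,
    fit_subgroups,
    save_draws,
)
from dhatrial.simulate import calibrate_mixture, sample_mixture
from dhatrial.trial_data import frame_from_records, ParticipantRecord

SMALL = McmcSettings(burn_in=400, keep=2000, seed=9, chains=2)


def mixture_cdf_at(state: MixtureState, x: float, arm: int = 0) -> float:
    """Numeric-integration oracle for P(GA < x) under a mixture state."""

    def pdf(t):
        return sum(
            w * stats.norm.pdf(t, m, s)
            for w, m, s in zip(state.w[arm], state.mu, state.sigma)
        )

    val, _ = integrate.quad(pdf, 50.0, x, limit=300)
    return val


class TestEpbRate:
    def test_component_centred_at_threshold_gives_half(self):
        st_ = MixtureState((238.0, 250.0, 260.0), (7.0, 5.0, 5.0), ((1.0, 0.0, 0.0),))
        assert epb_rate_from_state(st_) == pytest.approx(50.0)

    def test_two_sigma_below_threshold(self):
        st_ = MixtureState((224.0, 250.0, 260.0), (7.0, 5.0, 5.0), ((1.0, 0.0, 0.0),))
        assert epb_rate_from_state(st_) == pytest.approx(100 * stats.norm.cdf(2.0), abs=1e-9)

    def test_all_mass_far_above_threshold(self):
        st_ = MixtureState((280.0, 290.0, 300.0), (3.0, 3.0, 3.0),
                           ((0.2, 0.3, 0.5),))
        assert epb_rate_from_state(st_) < 1e-4

    @pytest.mark.parametrize("target", [0.01, 0.03, 0.10])
    def test_matches_numeric_cdf_oracle(self, target):
        st_ = calibrate_mixture(target)
        oracle = 100 * mixture_cdf_at(st_, st_.threshold_days)
        assert epb_rate_from_state(st_) == pytest.approx(oracle, abs=1e-6)

    def test_monotone_in_threshold(self):
        base = calibrate_mixture(0.03)
        rates = []
        for thr in (200, 238, 259, 280, 315):
            st_ = MixtureState(base.mu, base.sigma, base.w, threshold_days=thr)
            rates.append(epb_rate_from_state(st_))
        assert all(a <= b for a, b in zip(rates, rates[1:]))


class TestStateInvariants:
    def test_unordered_means_rejected(self):
        with pytest.raises(ValueError):
            MixtureState((250.0, 240.0, 260.0), (5.0, 5.0, 5.0), ((1.0, 0.0, 0.0),))

    def test_weights_must_be_simplex(self):
        with pytest.raises(ValueError):
            MixtureState((230.0, 250.0, 270.0), (5.0, 5.0, 5.0), ((0.5, 0.2, 0.2),))

    def test_density_integrates_to_one(self):
        st_ = calibrate_mixture(0.03)
        total = mixture_cdf_at(st_, 350.0)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_relabelling_leaves_likelihood_unchanged(self):
        rng = np.random.default_rng(2)
        y = rng.normal(260, 15, size=200)
        arm = np.zeros(200, dtype=int)
        mu = np.array([230.0, 255.0, 272.0])
        sigma = np.array([10.0, 8.0, 7.0])
        w = np.array([[0.1, 0.3, 0.6]])
        ll = _log_likelihood(y, arm, mu, sigma, w)
        perm = np.array([2, 0, 1])
        ll_perm = _log_likelihood(y, arm, mu[perm], sigma[perm], w[:, perm])
        assert ll_perm == pytest.approx(ll, rel=1e-12)


class TestFit:
    def test_degenerate_data_flagged(self):
        vals = np.full(100, 270.0)
        with pytest.raises(DegenerateDataError):
            fit_mixture((vals, vals), settings=SMALL)

    def test_undersized_arm_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DegenerateDataError):
            fit_mixture((rng.normal(270, 10, 10), rng.normal(270, 10, 100)), settings=SMALL)

    def test_single_component_data_dominant_weight(self):
        from dhatrial.mixture import MixturePriors

        rng = np.random.default_rng(4)
        a = rng.normal(273, 8, size=400)
        b = rng.normal(273, 8, size=400)
        # priors tight enough that the two empty components stay far from
        # the data instead of drifting in and splitting the term mass
        priors = MixturePriors(mean_scale=5.0, var_shape=4.0, var_scale=100.0)
        draws = fit_mixture((a, b), priors=priors, settings=SMALL)
        dominant = draws.w[:, 0, :].max(axis=1)
        assert dominant.mean() > 0.95

    def test_seed_reproducible(self):
        rng = np.random.default_rng(5)
        truth = calibrate_mixture(0.05)
        a = sample_mixture(truth, 200, rng)
        b = sample_mixture(truth, 200, rng)
        s = McmcSettings(burn_in=100, keep=400, seed=77, chains=1)
        d1 = fit_mixture((a, b), settings=s)
        d2 = fit_mixture((a, b), settings=s)
        assert np.array_equal(d1.mu, d2.mu) and np.array_equal(d1.w, d2.w)

    def test_ordered_means_in_every_draw(self):
        rng = np.random.default_rng(6)
        truth = calibrate_mixture(0.05)
        a = sample_mixture(truth, 300, rng)
        b = sample_mixture(truth, 300, rng)
        draws = fit_mixture((a, b), settings=SMALL)
        assert np.all(np.diff(draws.mu, axis=1) >= 0)

    def test_save_draws_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        truth = calibrate_mixture(0.05)
        a = sample_mixture(truth, 100, rng)
        draws = fit_mixture((a, a), settings=McmcSettings(burn_in=100, keep=200, seed=1, chains=1))
        out = tmp_path / "draws.csv"
        save_draws(draws, out)
        import pandas as pd

        back = pd.read_csv(out)
        assert len(back) == len(draws)
        assert np.allclose(back["mu1"], draws.mu[:, 0])


class TestArmComparison:
    def test_identical_arm_data_is_a_coin_flip(self):
        rng = np.random.default_rng(10)
        vals = sample_mixture(calibrate_mixture(0.03), 600, rng)
        draws = fit_mixture((vals, vals), settings=SMALL)
        res = compare_arms_mixture(draws)
        assert res["pp"] == pytest.approx(0.5, abs=0.05)

    def test_true_rate_difference_detected(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng([20, seed])
            lo = sample_mixture(calibrate_mixture(0.03), 550, rng)
            hi = sample_mixture(calibrate_mixture(0.01), 550, rng)
            draws = fit_mixture(
                (lo, hi), settings=McmcSettings(burn_in=400, keep=2000, seed=seed, chains=2)
            )
            hits += compare_arms_mixture(draws)["pp"] > 0.85
        assert hits >= 4

    def test_mixture_and_binomial_agree_on_direction(self):
        from dhatrial.conjugate import fit_beta_binomial, prob_better

        rng = np.random.default_rng(30)
        lo = sample_mixture(calibrate_mixture(0.04), 500, rng)
        hi = sample_mixture(calibrate_mixture(0.01), 500, rng)
        draws = fit_mixture((lo, hi), settings=SMALL)
        pp_mix = compare_arms_mixture(draws)["pp"]
        pp_bin = prob_better(
            fit_beta_binomial(int((hi < 238).sum()), 500),
            fit_beta_binomial(int((lo < 238).sum()), 500),
            method="quadrature",
        )
        assert (pp_mix - 0.5) * (pp_bin - 0.5) > 0


class TestSubgroups:
    @staticmethod
    def _cohort(seed, effect_in_low_only=True):
        rng = np.random.default_rng(seed)
        recs = []
        i = 0
        for stratum, dha in (("LOW", 4.5), ("HIGH", 8.0)):
            for arm in ("LOW_200", "HIGH_1000"):
                if stratum == "LOW":
                    rate = 0.04 if arm == "LOW_200" else (0.015 if effect_in_low_only else 0.04)
                else:
                    rate = 0.012
                ga = sample_mixture(calibrate_mixture(rate), 250, rng)
                for g in ga:
                    recs.append(ParticipantRecord(f"P{i:05d}", "A", arm, 0, dha, int(g)))
                    i += 1
        return frame_from_records(recs)

    def test_effect_confined_to_low_stratum(self):
        wins = 0
        for seed in range(3):
            df = self._cohort(seed)
            res = fit_subgroups(df, settings=McmcSettings(burn_in=300, keep=1500,
                                                          seed=seed, chains=2))
            wins += res["LOW"]["pp"] > res["HIGH"]["pp"]
        assert wins >= 2

    def test_undersized_stratum_warns_and_skips(self):
        df = self._cohort(0)
        tiny = df.head(40)  # both strata undersized
        with pytest.warns(UserWarning, match="skipped"):
            res = fit_subgroups(tiny, settings=SMALL)
        assert res == {}
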