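"""Three-component normal mixture model of gestational age at birth.

Gestational age in days is modelled as a mixture of three normals — a small
early component (the pathological left tail), a moderately preterm
component, and a dominant term component.  Component means and SDs are
shared across the two dose arms; the mixing weights are arm-specific.  The
fitted continuous distribution is dichotomised at 238 days (34 completed
weeks) to give a model-based early-preterm-birth (EPB) rate per arm,

    rate(arm) = sum_k w[arm, k] * Phi((threshold - mu_k) / sigma_k),

which borrows strength from the whole gestational-age distribution instead
of only counting events below the threshold.

Inference is a Gibbs sampler with latent component labels:

* labels  | rest   — categorical over components;
* mu_k    | rest   — conjugate normal (normal prior on each mean);
* sigma_k | rest   — conjugate inverse-gamma on the variance;
* weights | rest   — Dirichlet per arm.

Identifiability under label switching is enforced by re-ordering the
components by mean after every sweep (a pure relabelling, which leaves the
likelihood unchanged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import Direction, McmcSettings
from .conjugate import PosteriorSummary

EPB_THRESHOLD_DAYS = 238


class DegenerateDataError(ValueError):
    """Raised when the data cannot support a three-component fit."""


@dataclass(frozen=True)
class MixtureState:
    """One parameter configuration: 3 means/SDs (days), per-arm weights."""

    mu: tuple[float, float, float]
    sigma: tuple[float, float, float]
    w: tuple[tuple[float, float, float], ...]  # one 3-vector per arm
    threshold_days: int = EPB_THRESHOLD_DAYS

    def __post_init__(self) -> None:
        if not (self.mu[0] < self.mu[1] < self.mu[2]):
            raise ValueError("component means must be strictly increasing")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("component SDs must be positive")
        for wv in self.w:
            if any(x < -1e-12 for x in wv) or abs(sum(wv) - 1.0) > 1e-9:
                raise ValueError("each weight vector must be a simplex point")


@dataclass(frozen=True)
class MixturePriors:
    """Hyperparameters; defaults place the components at plausible early /
    moderately-preterm / term locations (days)."""

    mean_loc: tuple[float, float, float] = (180.0, 238.0, 273.0)
    mean_scale: float = 20.0
    var_shape: float = 2.0
    var_scale: float = 225.0  # prior mean of sigma^2 = scale/(shape-1) = 15^2
    weight_conc: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_scale <= 0 or self.var_shape <= 1 or self.var_scale <= 0:
            raise ValueError("prior hyperparameters must be positive (var_shape > 1)")
        if self.weight_conc <= 0:
            raise ValueError("weight_conc must be positive")


@dataclass
class MixtureDraws:
    """Retained posterior draws; arrays indexed [draw] (and [arm], [component])."""

    mu: np.ndarray  # (D, 3)
    sigma: np.ndarray  # (D, 3)
    w: np.ndarray  # (D, A, 3)
    loglik: np.ndarray  # (D,)
    threshold_days: int = EPB_THRESHOLD_DAYS
    n_chains: int = 1
    arm_names: tuple[str, ...] = ("LOW_200", "HIGH_1000")

    def __len__(self) -> int:
        return self.mu.shape[0]

    def states(self):
        for d in range(len(self)):
            yield MixtureState(
                mu=tuple(self.mu[d]),
                sigma=tuple(self.sigma[d]),
                w=tuple(tuple(v) for v in self.w[d]),
                threshold_days=self.threshold_days,
            )

    def epb_rates(self, arm_index: int) -> np.ndarray:
        """Per-draw model-based EPB rate (percent) for one arm."""
        z = (self.threshold_days - self.mu) / self.sigma
        return 100.0 * np.einsum("dk,dk->d", self.w[:, arm_index, :], stats.norm.cdf(z))

    def split_rhat(self) -> dict[str, float]:
        """Split-R-hat on mu and weights via arviz; diagnostic, not a gate."""
        import arviz as az

        if self.n_chains < 2 or len(self) < 4 * self.n_chains:
            return {}
        per = len(self) // self.n_chains
        out = {}
        for name, arr in (("mu", self.mu), ("w", self.w.reshape(len(self), -1))):
            shaped = arr[: per * self.n_chains].reshape(self.n_chains, per, -1)
            r = az.rhat(az.convert_to_dataset(shaped))
            out[name] = float(np.nanmax(r.to_array().values))
        return out


def epb_rate_from_state(state: MixtureState, arm_index: int = 0) -> float:
    """Dichotomise the fitted mixture: P(GA < threshold) x 100 for one arm."""
    w = np.asarray(state.w[arm_index])
    z = (state.threshold_days - np.asarray(state.mu)) / np.asarray(state.sigma)
    return float(100.0 * np.sum(w * stats.norm.cdf(z)))


def _log_likelihood(y, arm_idx, mu, sigma, w):
    dens = w[arm_idx, :] * stats.norm.pdf(y[:, None], mu[None, :], sigma[None, :])
    total = dens.sum(axis=1)
    return float(np.sum(np.log(np.maximum(total, 1e-300))))


def fit_mixture(
    ga_days_by_arm: tuple,
    priors: MixturePriors | None = None,
    settings: McmcSettings | None = None,
    threshold_days: int = EPB_THRESHOLD_DAYS,
    min_per_arm: int = 30,
) -> MixtureDraws:
    """Gibbs-sample the shared-component, arm-weighted three-normal mixture.

    Parameters
    ----------
    ga_days_by_arm
        Sequence of per-arm gestational-age collections (days); order fixes
        the arm index used everywhere downstream (0 = low dose by
        convention).
    """
    priors = priors or MixturePriors()
    settings = settings or McmcSettings()
    arms = [np.asarray(a, dtype=float) for a in ga_days_by_arm]
    for a in arms:
        if len(a) < min_per_arm:
            raise DegenerateDataError(f"need >= {min_per_arm} gestational ages per arm")
    y = np.concatenate(arms)
    arm_idx = np.concatenate([np.full(len(a), i, dtype=int) for i, a in enumerate(arms)])
    if len(np.unique(y)) < 3:
        raise DegenerateDataError("fewer than 3 distinct gestational ages; mixture degenerate")

    K, A, n = 3, len(arms), len(y)
    m0 = np.asarray(priors.mean_loc)
    s0sq = priors.mean_scale**2
    a0, b0 = priors.var_shape, priors.var_scale
    conc = priors.weight_conc

    draws_per_chain = settings.keep // settings.chains
    mu_out = np.empty((settings.chains * draws_per_chain, K))
    sig_out = np.empty_like(mu_out)
    w_out = np.empty((settings.chains * draws_per_chain, A, K))
    ll_out = np.empty(settings.chains * draws_per_chain)

    pos = 0
    for chain in range(settings.chains):
        rng = np.random.default_rng([settings.seed, chain])
        # init: spread means over prior locations with jitter; moderate SDs
        mu = np.sort(m0 + rng.normal(0, 5, size=K))
        sigma = np.full(K, 12.0) * rng.uniform(0.8, 1.2, size=K)
        w = np.full((A, K), 1.0 / K)
        burn_per_chain = max(settings.burn_in // settings.chains, 50)
        for it in range(burn_per_chain + draws_per_chain):
            # --- labels ---
            logp = (
                np.log(np.maximum(w[arm_idx, :], 1e-300))
                - 0.5 * ((y[:, None] - mu[None, :]) / sigma[None, :]) ** 2
                - np.log(sigma[None, :])
            )
            logp -= logp.max(axis=1, keepdims=True)
            p = np.exp(logp)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(n)[:, None]
            z = (u > np.cumsum(p, axis=1)).sum(axis=1)
            # --- component means/SDs ---
            for k in range(K):
                sel = z == k
                nk = int(sel.sum())
                if nk:
                    ybar = y[sel].mean()
                    prec = nk / sigma[k] ** 2 + 1.0 / s0sq
                    mean = (nk * ybar / sigma[k] ** 2 + m0[k] / s0sq) / prec
                    mu[k] = rng.normal(mean, 1.0 / np.sqrt(prec))
                    ssq = float(np.sum((y[sel] - mu[k]) ** 2))
                    var = stats.invgamma.rvs(a0 + nk / 2.0, scale=b0 + ssq / 2.0, random_state=rng)
                else:
                    mu[k] = rng.normal(m0[k], np.sqrt(s0sq))
                    var = stats.invgamma.rvs(a0, scale=b0, random_state=rng)
                sigma[k] = np.sqrt(var)
            # --- arm weights ---
            for a in range(A):
                counts = np.bincount(z[arm_idx == a], minlength=K)
                w[a] = rng.dirichlet(conc + counts)
            # --- relabel to ordered means (likelihood-invariant) ---
            order = np.argsort(mu)
            mu, sigma, w = mu[order], sigma[order], w[:, order]
            if it >= burn_per_chain:
                mu_out[pos] = mu
                sig_out[pos] = sigma
                w_out[pos] = w
                ll_out[pos] = _log_likelihood(y, arm_idx, mu, sigma, w)
                pos += 1

    return MixtureDraws(
        mu=mu_out,
        sigma=sig_out,
        w=w_out,
        loglik=ll_out,
        threshold_days=threshold_days,
        n_chains=settings.chains,
    )


def compare_arms_mixture(
    draws: MixtureDraws,
    direction: Direction = Direction.LOWER_IS_BETTER,
    high_index: int = 1,
    low_index: int = 0,
) -> dict:
    """Arm-wise model-based EPB summaries and the dose-superiority pp.

    Returns a dict with per-arm :class:`PosteriorSummary` objects (rates in
    percent) and ``pp`` = P(high-dose EPB rate < low-dose rate) over draws.
    """
    if len(draws) < 1000:
        warnings.warn("fewer than 1000 retained draws; pp estimate will be noisy")
    r_hi = draws.epb_rates(high_index)
    r_lo = draws.epb_rates(low_index)
    frac_less = float(np.mean(r_hi < r_lo))
    pp = frac_less if direction is Direction.LOWER_IS_BETTER else 1.0 - frac_less

    def summ(r):
        lo, hi = np.percentile(r, [2.5, 97.5])
        return PosteriorSummary(
            post_mean=float(np.mean(r)),
            cri_low=float(lo),
            cri_high=float(hi),
            pp_high_better=pp,
            direction=direction,
        )

    return {"high": summ(r_hi), "low": summ(r_lo), "pp": pp}


def fit_subgroups(
    df: pd.DataFrame,
    cutoff_pct: float = 6.0,
    priors: MixturePriors | None = None,
    settings: McmcSettings | None = None,
    threshold_days: int = EPB_THRESHOLD_DAYS,
    min_per_arm: int = 30,
) -> dict:
    """Independent mixture fits within each enrolment-DHA stratum.

    Expects a participant frame with ``arm``, ``enrolment_dha_pct`` and
    ``ga_days`` columns.  Strata with fewer than ``min_per_arm`` usable
    gestational ages in either arm are skipped with a warning rather than
    silently dropped.
    """
    from .trial_data import classify_dha_status

    settings = settings or McmcSettings()
    out: dict[str, dict] = {}
    dha = df["enrolment_dha_pct"].to_numpy(dtype=float, na_value=np.nan)
    status = np.array([classify_dha_status(v, cutoff_pct).value for v in dha])
    for stratum in ("LOW", "HIGH"):
        sub = df[status == stratum]
        arms = []
        ok = True
        for arm in ("LOW_200", "HIGH_1000"):
            ga = sub.loc[sub["arm"] == arm, "ga_days"].dropna().to_numpy(dtype=float)
            if len(ga) < min_per_arm:
                warnings.warn(
                    f"stratum {stratum}: only {len(ga)} gestational ages in arm {arm}; skipped"
                )
                ok = False
            arms.append(ga)
        if not ok:
            continue
        draws = fit_mixture(
            tuple(arms), priors=priors, settings=settings,
            threshold_days=threshold_days, min_per_arm=min_per_arm,
        )
        out[stratum] = compare_arms_mixture(draws)
        out[stratum]["draws"] = draws
    return out


def save_draws(draws: MixtureDraws, path) -> None:
    """Persist retained draws as a flat CSV (one row per draw)."""
    cols = {f"mu{k+1}": draws.mu[:, k] for k in range(3)}
    cols.update({f"sigma{k+1}": draws.sigma[:, k] for k in range(3)})
    for a in range(draws.w.shape[1]):
        for k in range(3):
            cols[f"w_arm{a}_{k+1}"] = draws.w[:, a, k]
    cols["loglik"] = draws.loglik
    pd.DataFrame(cols).to_csv(path, index=False)
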