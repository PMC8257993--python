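"""Multilevel binomial model for adverse-event safety monitoring.

Event counts are tallied by body-system category, separately for mothers
and neonates and separately for adverse vs serious adverse events.  For
each category j the two arms contribute binomial counts with

    logit P(event | low dose)  = theta_j
    logit P(event | high dose) = theta_j + delta_j,

and the category parameters are partially pooled through normal
hyperpriors: theta_j ~ N(mu_theta, tau_theta^2) and the log odds ratios
delta_j ~ N(mu_delta, tau_delta^2), with half-normal(1) priors on the
hyper-SDs.  Partial pooling shrinks noisy single-category signals toward
the population of categories — the behaviour that distinguishes this model
from running an unpooled binomial comparison per category.

Two pooled dose-comparison probabilities are reported: the hyper-level
P(mu_delta < 0), and the comparison of summed counts across categories via
the conjugate binomial model (both are plausible readings of a single
"pooled pp", so both are emitted).

The sampler is a seeded component-wise adaptive random-walk Metropolis:
proposal scales adapt during burn-in toward ~44% acceptance and are frozen
afterwards, keeping the retained chain a valid Markov chain.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import special

from .config import Direction, McmcSettings
from .conjugate import BetaPosterior, fit_beta_binomial, prob_better


class Population(str, enum.Enum):
    MATERNAL = "MATERNAL"
    NEONATAL = "NEONATAL"


class Severity(str, enum.Enum):
    AE = "AE"
    SAE = "SAE"


@dataclass(frozen=True)
class AeCategoryCount:
    population: Population
    category: str
    severity: Severity
    events_low: int
    n_low: int
    events_high: int
    n_high: int

    def __post_init__(self) -> None:
        if not (0 <= self.events_low <= self.n_low and 0 <= self.events_high <= self.n_high):
            raise ValueError("need 0 <= events <= n in each arm")


@dataclass
class AeFitResult:
    categories: list[str]
    pp_per_category: dict[str, float]  # P(fewer events on high dose), shrunken
    pp_pooled_hyper: float  # P(mu_delta < 0)
    pp_pooled_counts: float  # summed-count conjugate comparison
    delta_mean: dict[str, float]  # posterior mean log OR per category
    mu_delta_mean: float
    draws_delta: np.ndarray  # (D, J)
    draws_mu_delta: np.ndarray  # (D,)


def _log_posterior(params, el, nl, eh, nh):
    J = el.size
    theta = params[:J]
    delta = params[J : 2 * J]
    mu_t, mu_d, log_tau_t, log_tau_d = params[2 * J :]
    tau_t, tau_d = np.exp(log_tau_t), np.exp(log_tau_d)
    lp = 0.0
    # binomial likelihoods (log link via logaddexp for stability)
    lo = theta
    hi = theta + delta
    lp += np.sum(el * lo - nl * np.logaddexp(0.0, lo))
    lp += np.sum(eh * hi - nh * np.logaddexp(0.0, hi))
    # hierarchical priors
    lp += -0.5 * np.sum(((theta - mu_t) / tau_t) ** 2) - J * np.log(tau_t)
    lp += -0.5 * np.sum(((delta - mu_d) / tau_d) ** 2) - J * np.log(tau_d)
    # hyperpriors: mu_theta ~ N(-3, 2^2), mu_delta ~ N(0, 1), tau ~ HalfNormal(1)
    lp += -0.5 * ((mu_t + 3.0) / 2.0) ** 2
    lp += -0.5 * mu_d**2
    lp += -0.5 * tau_t**2 + log_tau_t  # half-normal + log-scale Jacobian
    lp += -0.5 * tau_d**2 + log_tau_d
    return lp


def fit_ae_model(
    counts: list[AeCategoryCount],
    settings: McmcSettings | None = None,
    thin: int = 5,
) -> AeFitResult:
    """Fit the partial-pooling safety model to one population x severity slice.

    ``counts`` must all belong to one population (the caller slices); at
    least two categories are required for the hierarchy to mean anything
    (with one category the fit reduces to an unpooled comparison).
    """
    if not counts:
        raise ValueError("empty category set")
    pops = {c.population for c in counts}
    if len(pops) > 1:
        raise ValueError("fit one population at a time")
    settings = settings or McmcSettings()
    J = len(counts)
    el = np.array([c.events_low for c in counts], dtype=float)
    nl = np.array([c.n_low for c in counts], dtype=float)
    eh = np.array([c.events_high for c in counts], dtype=float)
    nh = np.array([c.n_high for c in counts], dtype=float)

    # init at empirical logits (with continuity correction)
    t0 = special.logit((el + 0.5) / (nl + 1.0))
    d0 = special.logit((eh + 0.5) / (nh + 1.0)) - t0
    x = np.concatenate([t0, d0, [t0.mean(), d0.mean(), 0.0, 0.0]])
    ndim = x.size

    rng = np.random.default_rng(settings.seed)
    scales = np.full(ndim, 0.3)
    lp = _log_posterior(x, el, nl, eh, nh)

    n_iter = settings.burn_in + settings.keep
    kept = np.empty((settings.keep // thin, ndim))
    accept = np.zeros(ndim)
    window = np.zeros(ndim)
    pos = 0
    for it in range(n_iter):
        for d in range(ndim):
            prop = x.copy()
            prop[d] += scales[d] * rng.standard_normal()
            lp_prop = _log_posterior(prop, el, nl, eh, nh)
            if np.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                accept[d] += 1
            window[d] += 1
        # diminishing adaptation during burn-in only
        if it < settings.burn_in and (it + 1) % 50 == 0:
            rate = accept / window
            scales *= np.exp((rate - 0.44) * 0.5)
            accept[:] = 0
            window[:] = 0
        if it >= settings.burn_in and (it - settings.burn_in) % thin == 0 and pos < kept.shape[0]:
            kept[pos] = x
            pos += 1
    kept = kept[:pos]

    delta_draws = kept[:, J : 2 * J]
    mu_delta_draws = kept[:, 2 * J + 1]
    pp_cat = {
        counts[j].category: float(np.mean(delta_draws[:, j] < 0.0)) for j in range(J)
    }
    pp_hyper = float(np.mean(mu_delta_draws < 0.0))
    pooled = prob_better(
        fit_beta_binomial(int(eh.sum()), int(nh.sum())),
        fit_beta_binomial(int(el.sum()), int(nl.sum())),
        Direction.LOWER_IS_BETTER,
        method="quadrature",
    )
    return AeFitResult(
        categories=[c.category for c in counts],
        pp_per_category=pp_cat,
        pp_pooled_hyper=pp_hyper,
        pp_pooled_counts=float(pooled),
        delta_mean={counts[j].category: float(delta_draws[:, j].mean()) for j in range(J)},
        mu_delta_mean=float(mu_delta_draws.mean()),
        draws_delta=delta_draws,
        draws_mu_delta=mu_delta_draws,
    )


def unpooled_pp(count: AeCategoryCount) -> float:
    """Unpooled conjugate comparison for one category (shrinkage reference)."""
    return float(
        prob_better(
            fit_beta_binomial(count.events_high, count.n_high),
            fit_beta_binomial(count.events_low, count.n_low),
            Direction.LOWER_IS_BETTER,
            method="quadrature",
        )
    )
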