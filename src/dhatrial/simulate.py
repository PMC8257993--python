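"""Scenario-driven synthetic trial generator.

Emulates the cohort structure of the real trial so every analysis stage can
run without any download: ~1100 enrolments across three sites, enrolment
red-blood-cell DHA drawn from Normal(6.38, 1.77) percent of total fatty
acids, gestational ages from a left-skewed three-normal mixture whose early
component weight is calibrated so each arm's P(GA < 238 days) hits the
scenario's early-preterm-birth target exactly, ~6% missing outcomes, and
secondary outcomes at the arm-wise rates the trial reported.

The generating truth for every draw is returned alongside the table, so
parameter-recovery tests always know the answer.  The defaults are
synthetic stand-ins with a realistic shape; they are not estimates of the
unpublished participant-level trial data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .adverse_events import AeCategoryCount, Population, Severity
from .config import Arm
from .mixture import MixtureState
from .trial_data import COLUMNS, frame_from_records

#: default component locations/SDs (days) for the gestational-age truth:
#: early pathological tail, moderately preterm, term.
DEFAULT_MU = (224.0, 252.0, 273.0)
DEFAULT_SIGMA = (14.0, 10.0, 8.0)
#: share of the non-early mass sitting in the middle (moderately preterm)
#: component; the rest is term.
MID_SHARE = 0.10

#: arm-wise observed rates of the binary secondary outcomes (low, high dose)
DEFAULT_SECONDARY_RATES = {
    "gdm": (0.098, 0.126),
    "preeclampsia": (0.055, 0.072),
    "cesarean": (0.279, 0.267),
    "spontaneous_labor": (0.291, 0.263),
    "icu_admission": (0.118, 0.093),
}
#: arm-wise (mean, sd) for continuous anthropometrics (low, high dose)
DEFAULT_ANTHRO = {
    "birth_weight_g": ((3264.0, 574.0), (3326.0, 542.0)),
    "birth_length_cm": ((49.9, 4.4), (50.2, 3.6)),
    "head_circumference_cm": ((33.9, 2.3), (33.9, 2.5)),
}


@dataclass(frozen=True)
class AeScenario:
    """Per-category baseline event rates (low dose) and a common odds ratio."""

    categories: tuple[str, ...] = (
        "respiratory", "cardiac", "gastrointestinal", "genitourinary",
        "neurologic", "infection", "musculoskeletal", "feeding",
    )
    baseline_rates: tuple[float, ...] = (0.05, 0.02, 0.04, 0.03, 0.02, 0.06, 0.03, 0.05)
    odds_ratio: float = 0.8  # high vs low dose


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative truth for one simulated trial."""

    n_max: int = 1100
    weekly_rate: float = 5.86  # enrolments per week; ~1100 over ~188 weeks
    epb_low: float = 0.03  # design scenario: 3% on the standard dose
    epb_high: float = 0.01  # 1% on the high dose
    stratum_epb: dict | None = None  # {"LOW": (low, high), "HIGH": (low, high)}
    dha_mean: float = 6.38
    dha_sd: float = 1.77
    dha_cutoff: float = 6.0
    missing_fraction: float = 0.06
    informative_missing_or: float = 1.0  # >1: EPB births likelier to be missing
    site_probs: tuple[float, ...] = (0.23, 0.33, 0.44)
    secondary_rates: dict = field(default_factory=lambda: dict(DEFAULT_SECONDARY_RATES))
    anthro: dict = field(default_factory=lambda: dict(DEFAULT_ANTHRO))
    ae: AeScenario = field(default_factory=AeScenario)
    seed: int = 0

    @property
    def low_status_fraction(self) -> float:
        """Fraction below the 6% cutoff implied by the DHA normal truth."""
        return float(stats.norm.cdf((self.dha_cutoff - self.dha_mean) / self.dha_sd))


def calibrate_mixture(
    target_epb: float,
    mu: tuple = DEFAULT_MU,
    sigma: tuple = DEFAULT_SIGMA,
    threshold_days: int = 238,
    mid_share: float = MID_SHARE,
) -> MixtureState:
    """Tune the early-component weight so P(GA < threshold) = target_epb.

    The non-early mass keeps a fixed moderately-preterm : term split, so a
    single weight solves the calibration and attains the target within 1e-6.
    Targets below the default split's floor shrink the moderately-preterm
    share instead; a target above the early component's own rate (or below
    the term component's irreducible left-tail mass, ~1e-5) is infeasible
    and raises.
    """
    mu_a, sig_a = np.asarray(mu), np.asarray(sigma)
    phi = stats.norm.cdf((threshold_days - mu_a) / sig_a)

    def rate(w1, mid):
        w = np.array([w1, mid * (1 - w1), (1 - mid) * (1 - w1)])
        return float(np.dot(w, phi))

    hi = rate(1.0, mid_share)
    if target_epb > hi + 1e-12:
        raise ValueError(
            f"EPB target {target_epb:.4%} above attainable maximum {hi:.4%}"
        )
    if target_epb < phi[2] - 1e-12:
        raise ValueError(
            f"EPB target {target_epb:.4%} below the term component's "
            f"irreducible tail mass {phi[2]:.6%}"
        )
    lo = rate(0.0, mid_share)
    if target_epb >= lo:
        w1 = optimize.brentq(lambda x: rate(x, mid_share) - target_epb, 0.0, 1.0, xtol=1e-14)
        mid = mid_share
    else:  # drain the moderately-preterm component instead
        w1 = 0.0
        mid = optimize.brentq(lambda m: rate(0.0, m) - target_epb, 0.0, mid_share, xtol=1e-14)
    w = (w1, mid * (1 - w1), (1 - mid) * (1 - w1))
    return MixtureState(mu=tuple(mu), sigma=tuple(sigma), w=(w,), threshold_days=threshold_days)


def sample_mixture(state: MixtureState, size: int, rng, arm_index: int = 0) -> np.ndarray:
    """Integer gestational ages (days) from a mixture truth, clipped to [140, 315]."""
    w = np.asarray(state.w[arm_index])
    comp = rng.choice(3, size=size, p=w / w.sum())
    vals = rng.normal(np.asarray(state.mu)[comp], np.asarray(state.sigma)[comp])
    return np.clip(np.rint(vals), 140, 315).astype(int)


def generate_enrolment_calendar(scenario: ScenarioConfig, seed: int | None = None) -> np.ndarray:
    """Per-participant enrolment week from a Poisson arrival process."""
    if scenario.weekly_rate <= 0:
        raise ValueError("weekly_rate must be positive")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    weeks: list[int] = []
    week = 0
    while len(weeks) < scenario.n_max:
        k = rng.poisson(scenario.weekly_rate)
        weeks.extend([week] * k)
        week += 1
    return np.asarray(weeks[: scenario.n_max], dtype=int)


def interim_weeks(enrolment_weeks: np.ndarray, adaptation_start_n: int = 300,
                  period_weeks: int = 13) -> list[int]:
    """Calendar weeks of the adaptive interim analyses.

    The first interim falls one full period after the week the
    ``adaptation_start_n``-th participant enrolled, then every
    ``period_weeks`` until enrolment ends.
    """
    if len(enrolment_weeks) < adaptation_start_n:
        return []
    start = int(enrolment_weeks[adaptation_start_n - 1])
    end = int(enrolment_weeks[-1])
    return list(range(start + period_weeks, end + 1, period_weeks))


def _arm_truth(scenario: ScenarioConfig) -> dict:
    """Calibrated gestational-age truth per arm (and per stratum if set)."""
    out = {}
    if scenario.stratum_epb is None:
        out[("ALL", Arm.LOW_200.value)] = calibrate_mixture(scenario.epb_low)
        out[("ALL", Arm.HIGH_1000.value)] = calibrate_mixture(scenario.epb_high)
    else:
        for stratum, (low_rate, high_rate) in scenario.stratum_epb.items():
            out[(stratum, Arm.LOW_200.value)] = calibrate_mixture(low_rate)
            out[(stratum, Arm.HIGH_1000.value)] = calibrate_mixture(high_rate)
    return out


def generate_trial(
    scenario: ScenarioConfig, seed: int | None = None, arms: np.ndarray | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate one complete synthetic trial table plus its truth record.

    ``arms`` may supply pre-decided assignments (e.g. streamed from the
    adaptive engine); otherwise arms are blocked 1:1 within sites.
    Returns ``(table, truth)`` where ``truth`` records every generating
    parameter.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n_max
    weeks = generate_enrolment_calendar(scenario, seed=int(rng.integers(2**31)))
    sites = rng.choice(["A", "B", "C"], size=n, p=np.asarray(scenario.site_probs) /
                       np.sum(scenario.site_probs))
    if arms is None:
        arms = np.empty(n, dtype=object)
        for s in ("A", "B", "C"):
            idx = np.flatnonzero(sites == s)
            seq = []
            while len(seq) < len(idx):
                block = [Arm.LOW_200.value, Arm.LOW_200.value,
                         Arm.HIGH_1000.value, Arm.HIGH_1000.value]
                rng.shuffle(block)
                seq.extend(block)
            arms[idx] = seq[: len(idx)]
    else:
        arms = np.asarray(arms, dtype=object)

    dha = rng.normal(scenario.dha_mean, scenario.dha_sd, size=n)
    dha = np.clip(dha, 0.5, 24.5)
    status = np.where(dha < scenario.dha_cutoff, "LOW", "HIGH")

    truth_mixtures = _arm_truth(scenario)
    ga = np.empty(n, dtype=int)
    for (stratum, arm), state in truth_mixtures.items():
        sel = (arms == arm) if stratum == "ALL" else ((arms == arm) & (status == stratum))
        ga[sel] = sample_mixture(state, int(sel.sum()), rng)

    # missingness (missing-at-random by default; optional EPB-informative)
    base = scenario.missing_fraction
    if scenario.informative_missing_or != 1.0 and base > 0:
        odds = base / (1 - base) * np.where(ga < 238, scenario.informative_missing_or, 1.0)
        p_miss = odds / (1 + odds)
    else:
        p_miss = np.full(n, base)
    missing = rng.random(n) < p_miss

    arm_i = (arms == Arm.HIGH_1000.value).astype(int)
    df = pd.DataFrame({
        "participant_id": [f"P{i:05d}" for i in range(n)],
        "site": sites,
        "arm": arms,
        "enrolment_week": pd.array(weeks, dtype="Int64"),
        "enrolment_dha_pct": pd.array(np.round(dha, 2), dtype="Float64"),
        "ga_days": pd.array(ga, dtype="Int64"),
    })
    for col, ((m_lo, s_lo), (m_hi, s_hi)) in scenario.anthro.items():
        vals = rng.normal(np.where(arm_i, m_hi, m_lo), np.where(arm_i, s_hi, s_lo))
        if col == "birth_weight_g":
            vals = np.clip(vals, 300, 6500)
        df[col] = pd.array(np.round(vals, 1), dtype="Float64")
    for col, (r_lo, r_hi) in scenario.secondary_rates.items():
        p = np.where(arm_i, r_hi, r_lo)
        df[col] = pd.array(rng.binomial(1, p), dtype="Int64")
    df["withdrawn"] = missing
    # withdrawn / lost-to-follow-up participants have no outcome data
    outcome_cols = ["ga_days", "birth_weight_g", "birth_length_cm",
                    "head_circumference_cm"] + list(scenario.secondary_rates)
    for col in outcome_cols:
        df.loc[missing, col] = pd.NA
    df = df[COLUMNS]

    truth = {
        "scenario": scenario,
        "mixtures": truth_mixtures,
        "epb_targets": {"low": scenario.epb_low, "high": scenario.epb_high},
        "stratum_epb": scenario.stratum_epb,
        "missing_fraction": scenario.missing_fraction,
        "low_status_fraction": scenario.low_status_fraction,
    }
    return df, truth


def generate_ae_counts(
    scenario: ScenarioConfig,
    n_low: int,
    n_high: int,
    population: Population = Population.MATERNAL,
    severity: Severity = Severity.AE,
    seed: int | None = None,
) -> list[AeCategoryCount]:
    """Synthetic per-category adverse-event counts under a common odds ratio."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    out = []
    for cat, p_lo in zip(scenario.ae.categories, scenario.ae.baseline_rates):
        odds_hi = p_lo / (1 - p_lo) * scenario.ae.odds_ratio
        p_hi = odds_hi / (1 + odds_hi)
        out.append(
            AeCategoryCount(
                population=population,
                category=cat,
                severity=severity,
                events_low=int(rng.binomial(n_low, p_lo)),
                n_low=n_low,
                events_high=int(rng.binomial(n_high, p_hi)),
                n_high=n_high,
            )
        )
    return out
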