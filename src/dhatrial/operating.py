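"""Operating characteristics of the adaptive design.

Each replicate simulates one full trial: enrolments stream in on a Poisson
calendar, arms come from the per-site blocked allocation tables, gestational
ages are drawn from the scenario's calibrated mixture truth, interim
analyses every 13 weeks (once 300 are enrolled) re-target the allocation
from the running binomial posterior, an early-superiority stop is checked
from 800 enrolled at posterior probability 0.99, and the trial ends with a
final conjugate binomial analysis of all observed outcomes.

A replicate counts as a success when its decision-time posterior
probability that the high dose has the lower early-preterm-birth rate
exceeds the success threshold (default 0.95) — at the stop time if the
trial stopped early, otherwise at the final analysis.  Replicates are
seeded independently from ``(seed, replicate_index)``, so results are
independent of execution order or batching.

Outcome availability at an interim respects gestation: a participant's
early-preterm status enters the interim data only once her (simulated)
birth week has passed, taken as ``enrolment_week + ga_days/7 - 16`` (the
midpoint of the 12-20-week eligibility window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adaptive import (
    AllocationSegment,
    ArmCounts,
    allocation_target,
    check_early_stop,
    initial_allocation,
)
from .config import Arm, DesignConfig
from .simulate import ScenarioConfig, generate_enrolment_calendar, interim_weeks, _arm_truth, sample_mixture


@dataclass(frozen=True)
class ReplicateResult:
    final_pp: float
    decision_pp: float  # stop-time pp if stopped early, else final pp
    stopped_early: bool
    n_enrolled: int
    n_low: int
    n_high: int
    n_interims: int


@dataclass(frozen=True)
class OcResult:
    n_reps: int
    success_fraction: float
    mc_se: float
    mean_n_low: float
    mean_n_high: float
    early_stop_fraction: float
    success_threshold_used: float


def _trim_and_append(table, interim_index: int, target: float, block_size: int,
                     n_blocks: int, rng) -> None:
    """Drop the unissued tail, then append a fresh segment at ``target``.

    The issued prefix is never touched; trimming only removes assignments
    no participant has consumed, so the new target takes effect at the next
    enrolment.
    """
    from .adaptive import _blocks

    remaining = table.cursor
    new_segments = []
    for seg in table.segments:
        if remaining <= 0:
            break
        take = min(remaining, len(seg.assignments))
        new_segments.append(AllocationSegment(seg.interim_index, seg.target_prob_high,
                                              seg.assignments[:take]))
        remaining -= take
    table.segments = new_segments
    table.segments.append(
        AllocationSegment(interim_index, target, _blocks(target, n_blocks, block_size, rng))
    )


def simulate_adaptive_trial(
    scenario: ScenarioConfig,
    design: DesignConfig,
    seed: int,
    rep_index: int = 0,
) -> ReplicateResult:
    """Run one replicate of the full adaptive trial."""
    rng = np.random.default_rng([seed, rep_index])
    n = scenario.n_max
    weeks = generate_enrolment_calendar(scenario, seed=int(rng.integers(2**31)))
    sites = rng.choice(list(design.sites), size=n,
                       p=np.asarray(scenario.site_probs) / np.sum(scenario.site_probs))

    truth = _arm_truth(scenario)
    if scenario.stratum_epb is not None:
        raise NotImplementedError("operating characteristics use arm-level EPB truth")
    ga_low = sample_mixture(truth[("ALL", Arm.LOW_200.value)], n, rng)
    ga_high = sample_mixture(truth[("ALL", Arm.HIGH_1000.value)], n, rng)
    missing = rng.random(n) < scenario.missing_fraction

    blocks_per_seg = int(np.ceil(n / design.block_size)) + 2
    tables = initial_allocation(design, seed=int(rng.integers(2**31)),
                                n_blocks_per_site=blocks_per_seg)

    checkpoints = interim_weeks(weeks, design.adaptation_start_n, design.interim_period_weeks)
    arm_high = np.zeros(n, dtype=bool)
    ga = np.zeros(n, dtype=int)
    birth_week = np.zeros(n, dtype=float)

    stopped = False
    stop_pp = float("nan")
    n_enrolled = 0
    n_interims = 0
    ci = 0  # next checkpoint index

    for i in range(n):
        # run any interim analyses due before this enrolment
        while ci < len(checkpoints) and weeks[i] > checkpoints[ci]:
            t = checkpoints[ci]
            ci += 1
            n_interims += 1
            born = (np.arange(n) < n_enrolled) & (birth_week[:n] <= t) & ~missing
            counts = ArmCounts(
                events_high=int(np.sum(born & arm_high & (ga < 238))),
                n_high=int(np.sum(born & arm_high)),
                events_low=int(np.sum(born & ~arm_high & (ga < 238))),
                n_low=int(np.sum(born & ~arm_high)),
                n_enrolled=n_enrolled,
            )
            pp = counts.pp_high_better()
            target = (
                0.5
                if n_enrolled < design.adaptation_start_n
                else allocation_target(pp, design.exponent_at(n_enrolled), design.allocation_cap)
            )
            seg_rng = np.random.default_rng([seed, rep_index, 7, n_interims])
            for table in tables.values():
                _trim_and_append(table, n_interims, target, design.block_size,
                                 blocks_per_seg, seg_rng)
            decision = check_early_stop(counts, design)
            if decision.stop:
                stopped = True
                stop_pp = decision.pp_high_better
                break
        if stopped:
            break
        arm = tables[sites[i]].next_assignment()
        hi = arm == Arm.HIGH_1000.value
        arm_high[i] = hi
        ga[i] = ga_high[i] if hi else ga_low[i]
        birth_week[i] = weeks[i] + max(0.0, ga[i] / 7.0 - 16.0)
        n_enrolled += 1

    obs = (np.arange(n) < n_enrolled) & ~missing
    final_counts = ArmCounts(
        events_high=int(np.sum(obs & arm_high & (ga < 238))),
        n_high=int(np.sum(obs & arm_high)),
        events_low=int(np.sum(obs & ~arm_high & (ga < 238))),
        n_low=int(np.sum(obs & ~arm_high)),
        n_enrolled=n_enrolled,
    )
    final_pp = final_counts.pp_high_better()
    return ReplicateResult(
        final_pp=final_pp,
        decision_pp=stop_pp if stopped else final_pp,
        stopped_early=stopped,
        n_enrolled=n_enrolled,
        n_low=int(np.sum(arm_high[:n_enrolled] == False)),  # noqa: E712
        n_high=int(np.sum(arm_high[:n_enrolled])),
        n_interims=n_interims,
    )


def run_operating_characteristics(
    scenario: ScenarioConfig,
    design: DesignConfig,
    n_reps: int,
    seed: int,
    rep_offset: int = 0,
    success_threshold: float | None = None,
) -> tuple[OcResult, list[ReplicateResult]]:
    """Replicate the adaptive trial and tabulate its frequentist behaviour.

    ``rep_offset`` shifts the replicate indices, so two runs of 250 with
    offsets 0 and 250 pool to exactly the same estimate as one run of 500.
    """
    if n_reps < 100:
        raise ValueError("need at least 100 replicates for stable proportions")
    threshold = design.final_success_threshold if success_threshold is None else success_threshold
    reps = [
        simulate_adaptive_trial(scenario, design, seed, rep_index=rep_offset + r)
        for r in range(n_reps)
    ]
    return pool_replicates(reps, threshold), reps


def pool_replicates(reps: list[ReplicateResult], threshold: float) -> OcResult:
    n = len(reps)
    succ = np.array([r.decision_pp > threshold for r in reps])
    frac = float(succ.mean())
    return OcResult(
        n_reps=n,
        success_fraction=frac,
        mc_se=float(np.sqrt(max(frac * (1 - frac), 1e-12) / n)),
        mean_n_low=float(np.mean([r.n_low for r in reps])),
        mean_n_high=float(np.mean([r.n_high for r in reps])),
        early_stop_fraction=float(np.mean([r.stopped_early for r in reps])),
        success_threshold_used=threshold,
    )


def summarize_oc(reps: list[ReplicateResult], thresholds) -> pd.DataFrame:
    """Success fraction across a grid of final-success thresholds.

    Reuses the stored decision-time posterior probabilities, so the table
    is exact for the replicates given (no re-simulation) and success is
    monotone non-increasing in the threshold by construction.
    """
    rows = []
    for t in thresholds:
        oc = pool_replicates(reps, t)
        rows.append({
            "success_threshold": t,
            "success_fraction": oc.success_fraction,
            "mc_se": oc.mc_se,
            "early_stop_fraction": oc.early_stop_fraction,
            "mean_n_low": oc.mean_n_low,
            "mean_n_high": oc.mean_n_high,
            "n_reps": oc.n_reps,
        })
    return pd.DataFrame(rows)
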