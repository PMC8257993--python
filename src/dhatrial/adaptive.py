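"""Response-adaptive randomization engine.

Each site holds its own allocation table.  Enrolment starts 1:1 in blocks
of 4 (two high-dose, two low-dose assignments per block, order shuffled).
Once 300 participants are enrolled, an interim analysis every 13 weeks
recomputes the posterior probability (pp) that the high dose has the lower
early-preterm-birth rate, converts it to a target allocation probability

    target = pp^c / (pp^c + (1 - pp)^c),      c = n / (2 * n_max) by default,

clips it to the configured cap (default [0.1, 0.9]), and appends a freshly
generated block sequence at that target to every site's table.  Assignments
already issued are never rewritten.  Non-1:1 targets are realised within
blocks of 4 by randomised rounding of the expected high-dose count per
block, so the long-run frequency equals the target exactly.

The trial would stop early for superiority only once at least 800
participants are enrolled and max(pp, 1-pp) exceeds 0.99.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Arm, DesignConfig, Direction
from .conjugate import fit_beta_binomial, prob_better


@dataclass(frozen=True)
class ArmCounts:
    """Accumulated EPB events / outcome denominators, plus total enrolled."""

    events_high: int
    n_high: int
    events_low: int
    n_low: int
    n_enrolled: int

    def pp_high_better(self) -> float:
        post_high = fit_beta_binomial(self.events_high, self.n_high)
        post_low = fit_beta_binomial(self.events_low, self.n_low)
        # flat priors on integer counts admit the exact finite-sum formula,
        # which is much cheaper than quadrature inside simulation loops
        from .conjugate import prob_less_exact

        try:
            return prob_less_exact(post_high, post_low)
        except ValueError:
            return prob_better(post_high, post_low, Direction.LOWER_IS_BETTER,
                               method="quadrature")


@dataclass
class AllocationSegment:
    interim_index: int
    target_prob_high: float
    assignments: list[str]


@dataclass
class AllocationTable:
    site: str
    segments: list[AllocationSegment] = field(default_factory=list)
    cursor: int = 0  # number of assignments already issued

    @property
    def assignments(self) -> list[str]:
        return [a for seg in self.segments for a in seg.assignments]

    def next_assignment(self) -> str:
        pos = self.cursor
        for seg in self.segments:
            if pos < len(seg.assignments):
                self.cursor += 1
                return seg.assignments[pos]
            pos -= len(seg.assignments)
        raise IndexError(f"site {self.site}: allocation table exhausted")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        pos = 0
        for seg in self.segments:
            for a in seg.assignments:
                rows.append(
                    {
                        "site": self.site,
                        "position": pos,
                        "interim_index": seg.interim_index,
                        "target_prob_high": seg.target_prob_high,
                        "arm": a,
                    }
                )
                pos += 1
        return pd.DataFrame(rows)


def _blocks(target_prob_high: float, n_blocks: int, block_size: int, rng) -> list[str]:
    out: list[str] = []
    expected = block_size * target_prob_high
    base = int(np.floor(expected))
    frac = expected - base
    for _ in range(n_blocks):
        n_high = base + (1 if rng.random() < frac else 0)
        block = [Arm.HIGH_1000.value] * n_high + [Arm.LOW_200.value] * (block_size - n_high)
        rng.shuffle(block)
        out.extend(block)
    return out


def initial_allocation(
    config: DesignConfig, seed: int, n_blocks_per_site: int = 10
) -> dict[str, AllocationTable]:
    """Independent 1:1 blocked table per site (interim index 0)."""
    tables = {}
    for site in config.sites:
        rng = np.random.default_rng([seed, 0, _site_key(site)])
        seq = _blocks(0.5, n_blocks_per_site, config.block_size, rng)
        tables[site] = AllocationTable(
            site=site, segments=[AllocationSegment(0, 0.5, seq)]
        )
    return tables


def _site_key(site: str) -> int:
    return sum(ord(c) for c in str(site))


def allocation_target(pp: float, c: float, cap: tuple[float, float]) -> float:
    """Power-weighted allocation probability, clipped to the cap."""
    if c == 0:
        target = 0.5
    else:
        num = pp**c
        den = num + (1.0 - pp) ** c
        target = 0.5 if den == 0 else num / den
    return float(min(max(target, cap[0]), cap[1]))


def update_allocation(
    tables: dict[str, AllocationTable],
    accumulated: ArmCounts,
    config: DesignConfig,
    interim_index: int,
    seed: int,
    n_blocks_per_site: int = 10,
) -> dict[str, AllocationTable]:
    """Append a new segment per site from the current posterior; in place.

    Before ``adaptation_start_n`` enrolments the appended segment stays 1:1.
    Issued assignments are never modified (prefix immutability).
    """
    if accumulated.n_enrolled < config.adaptation_start_n:
        target = 0.5
    else:
        pp = accumulated.pp_high_better()
        c = config.exponent_at(accumulated.n_enrolled)
        target = allocation_target(pp, c, config.allocation_cap)
    for site, table in tables.items():
        rng = np.random.default_rng([seed, interim_index, _site_key(site)])
        seq = _blocks(target, n_blocks_per_site, config.block_size, rng)
        table.segments.append(AllocationSegment(interim_index, target, seq))
    return tables


@dataclass(frozen=True)
class StopDecision:
    stop: bool
    arm: str | None  # winning arm if stopped
    pp_high_better: float


def check_early_stop(accumulated: ArmCounts, config: DesignConfig) -> StopDecision:
    """Superiority stop: only at >= stop_check_n enrolled and pp beyond 0.99."""
    pp = accumulated.pp_high_better()
    if accumulated.n_enrolled >= config.stop_check_n:
        if pp > config.stop_pp_threshold:
            return StopDecision(True, Arm.HIGH_1000.value, pp)
        if 1.0 - pp > config.stop_pp_threshold:
            return StopDecision(True, Arm.LOW_200.value, pp)
    return StopDecision(False, None, pp)


def audit_allocations(planned: pd.DataFrame, dispensed: pd.DataFrame) -> pd.DataFrame:
    """Compare planned assignments against the dispensing log.

    Both frames need ``participant_id`` and ``arm`` columns.  Returns one
    row per discrepancy: mismatched arms, or ids present on one side only
    (``kind`` column says which).  Intention-to-treat analyses always keep
    the planned arm.
    """
    merged = planned[["participant_id", "arm"]].merge(
        dispensed[["participant_id", "arm"]],
        on="participant_id",
        how="outer",
        suffixes=("_planned", "_dispensed"),
        indicator=True,
    )
    rows = []
    for _, r in merged.iterrows():
        if r["_merge"] == "left_only":
            rows.append((r["participant_id"], r["arm_planned"], None, "missing_dispense"))
        elif r["_merge"] == "right_only":
            rows.append((r["participant_id"], None, r["arm_dispensed"], "unmatched_id"))
        elif r["arm_planned"] != r["arm_dispensed"]:
            rows.append((r["participant_id"], r["arm_planned"], r["arm_dispensed"], "arm_mismatch"))
    return pd.DataFrame(
        rows, columns=["participant_id", "arm_planned", "arm_dispensed", "kind"]
    )
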