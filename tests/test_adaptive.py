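import copy

import numpy as np
import pandas as pd
import pytest

from dhatrial.adaptive import (
    ArmCounts,
    allocation_target,
    audit_allocations,
    check_early_stop,
    initial_allocation,
    update_allocation,
)
from dhatrial.config import DesignConfig


def block_counts(assignments, block_size=4):
    out = []
    for i in range(0, len(assignments) - block_size + 1, block_size):
        block = assignments[i : i + block_size]
        out.append(sum(a == "HIGH_1000" for a in block))
    return out


class TestInitialAllocation:
    def test_every_block_is_one_to_one(self):
        for seed in (0, 1, 99):
            tables = initial_allocation(DesignConfig(), seed)
            for t in tables.values():
                assert all(c == 2 for c in block_counts(t.assignments))

    def test_same_seed_reproduces_different_seeds_differ(self):
        a = initial_allocation(DesignConfig(), 5)
        b = initial_allocation(DesignConfig(), 5)
        c = initial_allocation(DesignConfig(), 6)
        assert all(a[s].assignments == b[s].assignments for s in a)
        assert any(a[s].assignments != c[s].assignments for s in a)

    def test_sites_have_independent_tables(self):
        tables = initial_allocation(DesignConfig(), 3, n_blocks_per_site=30)
        seqs = [tuple(t.assignments) for t in tables.values()]
        assert len(set(seqs)) == 3


class TestAllocationTarget:
    def test_symmetric_fixed_point(self):
        for c in (0.0, 0.25, 0.5, 1.0):
            assert allocation_target(0.5, c, (0.1, 0.9)) == 0.5

    def test_cap_binds_at_certainty(self):
        assert allocation_target(1.0, 0.5, (0.1, 0.9)) == 0.9
        assert allocation_target(0.0, 0.5, (0.1, 0.9)) == pytest.approx(0.1)

    def test_power_rule_arithmetic(self):
        expected = np.sqrt(0.8) / (np.sqrt(0.8) + np.sqrt(0.2))
        assert allocation_target(0.8, 0.5, (0.1, 0.9)) == pytest.approx(expected)

    def test_zero_exponent_reduces_to_equal_allocation(self):
        for pp in (0.01, 0.3, 0.97):
            assert allocation_target(pp, 0.0, (0.1, 0.9)) == 0.5


class TestUpdateAllocation:
    def test_before_adaptation_start_stays_balanced(self):
        tables = initial_allocation(DesignConfig(), 0)
        counts = ArmCounts(0, 50, 5, 50, n_enrolled=100)
        update_allocation(tables, counts, DesignConfig(), interim_index=1, seed=0)
        for t in tables.values():
            assert t.segments[-1].target_prob_high == 0.5

    def test_prefix_immutability_across_interims(self):
        cfg = DesignConfig()
        tables = initial_allocation(cfg, 0)
        issued = [tables["A"].next_assignment() for _ in range(12)]
        before = copy.deepcopy(tables["A"].assignments[:12])
        counts = ArmCounts(3, 250, 12, 250, n_enrolled=520)
        update_allocation(tables, counts, cfg, interim_index=1, seed=1)
        update_allocation(tables, counts, cfg, interim_index=2, seed=2)
        assert tables["A"].assignments[:12] == before == issued

    def test_target_within_cap_and_arms_sum_to_one(self):
        cfg = DesignConfig()
        tables = initial_allocation(cfg, 0)
        counts = ArmCounts(0, 300, 30, 300, n_enrolled=700)  # overwhelming signal
        update_allocation(tables, counts, cfg, interim_index=1, seed=1)
        t = tables["A"].segments[-1].target_prob_high
        assert cfg.allocation_cap[0] <= t <= cfg.allocation_cap[1]
        # the low-dose probability is the exact complement by construction
        assert (1 - t) + t == 1.0

    def test_block_composition_tracks_target(self):
        cfg = DesignConfig()
        tables = initial_allocation(cfg, 0)
        counts = ArmCounts(4, 300, 12, 300, n_enrolled=640)
        update_allocation(tables, counts, cfg, interim_index=1, seed=4,
                          n_blocks_per_site=2000)
        seg = tables["A"].segments[-1]
        target = seg.target_prob_high
        counts_per_block = block_counts(seg.assignments)
        lo, hi = int(np.floor(4 * target)), int(np.ceil(4 * target))
        assert set(counts_per_block) <= {lo, hi}
        freq = np.mean([a == "HIGH_1000" for a in seg.assignments])
        assert freq == pytest.approx(target, abs=0.02)


class TestStoppingRule:
    def test_no_stop_before_800_even_at_near_certainty(self):
        counts = ArmCounts(0, 400, 20, 399, n_enrolled=799)  # pp ~ 1.0
        decision = check_early_stop(counts, DesignConfig())
        assert decision.pp_high_better > 0.999
        assert not decision.stop

    def test_stop_for_superiority_at_800(self):
        counts = ArmCounts(2, 400, 15, 400, n_enrolled=800)  # pp ~ 0.9994
        decision = check_early_stop(counts, DesignConfig())
        assert decision.stop and decision.arm == "HIGH_1000"

    def test_moderate_evidence_runs_to_full_enrolment(self):
        counts = ArmCounts(9, 540, 12, 492, n_enrolled=1100)  # pp ~ 0.81
        decision = check_early_stop(counts, DesignConfig())
        assert not decision.stop
        assert decision.pp_high_better == pytest.approx(0.81, abs=0.01)

    def test_stop_can_favor_low_dose(self):
        counts = ArmCounts(15, 400, 2, 400, n_enrolled=900)
        decision = check_early_stop(counts, DesignConfig())
        assert decision.stop and decision.arm == "LOW_200"


class TestAudit:
    @staticmethod
    def _log(n, rng=None):
        arms = ["LOW_200", "HIGH_1000"] * (n // 2 + 1)
        return pd.DataFrame(
            {"participant_id": [f"P{i:05d}" for i in range(n)], "arm": arms[:n]}
        )

    def test_identical_logs_clean(self):
        planned = self._log(50)
        assert len(audit_allocations(planned, planned.copy())) == 0

    def test_single_swap_reported(self):
        planned = self._log(50)
        dispensed = planned.copy()
        dispensed.loc[7, "arm"] = "HIGH_1000" if planned.loc[7, "arm"] == "LOW_200" else "LOW_200"
        report = audit_allocations(planned, dispensed)
        assert len(report) == 1
        assert report.iloc[0]["participant_id"] == "P00007"
        assert report.iloc[0]["kind"] == "arm_mismatch"

    def test_two_injected_errors_among_1100(self):
        planned = self._log(1100)
        dispensed = planned.copy()
        for idx in (101, 887):
            dispensed.loc[idx, "arm"] = (
                "HIGH_1000" if planned.loc[idx, "arm"] == "LOW_200" else "LOW_200"
            )
        report = audit_allocations(planned, dispensed)
        assert len(report) == 2
        assert set(report["participant_id"]) == {"P00101", "P00887"}

    def test_unknown_id_listed_as_unmatched(self):
        planned = self._log(10)
        dispensed = pd.concat(
            [planned, pd.DataFrame({"participant_id": ["PX9999"], "arm": ["LOW_200"]})]
        )
        report = audit_allocations(planned, dispensed)
        assert list(report["kind"]) == ["unmatched_id"]
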