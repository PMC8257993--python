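"""Shared configuration dataclasses and YAML/JSON round-trip helpers.

Every tunable the analysis or the simulator exposes lives here so that a
whole run is reproducible from one config file plus one integer seed.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class Direction(enum.Enum):
    """Which way the benefit points for an outcome."""

    LOWER_IS_BETTER = "lower_is_better"
    HIGHER_IS_BETTER = "higher_is_better"


class Arm(str, enum.Enum):
    LOW_200 = "LOW_200"
    HIGH_1000 = "HIGH_1000"


class Site(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"


@dataclass(frozen=True)
class McmcSettings:
    """Draw counts for samplers.

    burn_in and keep mirror the usual burn-in / inference split; the
    conjugate comparisons use only ``keep`` (they draw i.i.d. from closed-form
    posteriors, so there is nothing to burn).
    """

    burn_in: int = 10_000
    keep: int = 40_000
    seed: int = 0
    chains: int = 4

    def __post_init__(self) -> None:
        if self.burn_in <= 0 or self.keep <= 0:
            raise ValueError("burn_in and keep must be positive")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")


@dataclass(frozen=True)
class DesignConfig:
    """Constants of the adaptive design.

    Defaults are the trial's: 1100-participant cap, 1:1 blocks of 4 at the
    start, interim re-allocation every 13 weeks once 300 are enrolled, an
    early-stop check from 800 enrolled at posterior probability 0.99, and a
    final success threshold of 0.95 for operating characteristics.
    """

    n_max: int = 1100
    expected_dropout: float = 0.05
    block_size: int = 4
    interim_period_weeks: int = 13
    adaptation_start_n: int = 300
    stop_check_n: int = 800
    stop_pp_threshold: float = 0.99
    final_success_threshold: float = 0.95
    sites: tuple[str, ...] = ("A", "B", "C")
    allocation_exponent: float | None = None  # None -> n / (2 * n_max)
    allocation_cap: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        if not (0.0 < self.stop_pp_threshold < 1.0):
            raise ValueError("stop_pp_threshold must be in (0, 1)")
        if not (0.0 < self.final_success_threshold < 1.0):
            raise ValueError("final_success_threshold must be in (0, 1)")
        if not self.adaptation_start_n < self.stop_check_n <= self.n_max:
            raise ValueError("need adaptation_start_n < stop_check_n <= n_max")
        lo, hi = self.allocation_cap
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("allocation_cap must satisfy 0 <= lo < hi <= 1")

    def exponent_at(self, n_enrolled: int) -> float:
        """Allocation-tuning exponent c; default is the stabilised n/(2*n_max)."""
        if self.allocation_exponent is not None:
            return self.allocation_exponent
        return n_enrolled / (2.0 * self.n_max)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the analysis pipeline (cutoffs, priors, conventions)."""

    dha_cutoff_pct: float = 6.0
    epb_threshold_days: int = 238  # 34 weeks
    preterm_threshold_days: int = 259  # 37 weeks
    bloodspot_conversion_factor: float = 0.4754
    prior_alpha: float = 1.0
    prior_beta: float = 1.0
    interval_kind: str = "central"  # or "hdi"


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(cfg, path: str | Path) -> None:
    """Serialise any config dataclass to YAML (or JSON by extension)."""
    path = Path(path)
    payload = _to_plain(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _coerce_tuples(cls, data: dict) -> dict:
    out = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(out[f.name])
    return out


def load_design_config(path: str | Path) -> DesignConfig:
    return DesignConfig(**_coerce_tuples(DesignConfig, load_mapping(path)))


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    return AnalysisConfig(**load_mapping(path))


def load_mcmc_settings(path: str | Path) -> McmcSettings:
    return McmcSettings(**load_mapping(path))
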