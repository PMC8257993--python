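"""Participant-level trial tables: schema, CSV I/O, derived classifications.

The canonical in-memory container is a pandas DataFrame with one row per
enrolled pregnancy and explicit missing values (pandas NA), never sentinel
numbers.  A row-level :class:`ParticipantRecord` dataclass is provided for
code that prefers objects over frames.

Derived classifications implemented here:

* early preterm birth (EPB): gestational age strictly below 238 days
  (34 completed weeks); preterm: strictly below 259 days (37 weeks);
* DHA status: red-blood-cell phospholipid DHA strictly below 6% of total
  fatty acids is "low" status, at or above is "high";
* a conversion between whole-blood-spot DHA and RBC phospholipid DHA
  (divide by 0.4754), used to port risk cutoffs between assay types;
* enrolment-DHA quartiles over the pooled cohort.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import AnalysisConfig, Arm, Site

GA_DAYS_MIN = 140
GA_DAYS_MAX = 315
DHA_PCT_MIN = 0.0
DHA_PCT_MAX = 25.0

#: CSV column order; a ``schema_version`` column is tolerated and ignored.
COLUMNS = [
    "participant_id",
    "site",
    "arm",
    "enrolment_week",
    "enrolment_dha_pct",
    "ga_days",
    "birth_weight_g",
    "birth_length_cm",
    "head_circumference_cm",
    "gdm",
    "preeclampsia",
    "cesarean",
    "spontaneous_labor",
    "icu_admission",
    "withdrawn",
]

_BINARY_COLS = ["gdm", "preeclampsia", "cesarean", "spontaneous_labor", "icu_admission"]
_FLOAT_COLS = ["enrolment_dha_pct", "birth_weight_g", "birth_length_cm", "head_circumference_cm"]
_INT_COLS = ["enrolment_week", "ga_days"]


class TrialDataError(ValueError):
    """Structured parse/validation failure; names row and column."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        loc = ""
        if row is not None or column is not None:
            loc = f" (row={row}, column={column})"
        super().__init__(message + loc)


class DhaStatus(enum.Enum):
    LOW = "LOW"
    HIGH = "HIGH"
    MISSING = "MISSING"


@dataclass
class ParticipantRecord:
    participant_id: str
    site: str
    arm: str
    enrolment_week: int | None = None
    enrolment_dha_pct: float | None = None
    ga_days: int | None = None
    birth_weight_g: float | None = None
    birth_length_cm: float | None = None
    head_circumference_cm: float | None = None
    gdm: int | None = None
    preeclampsia: int | None = None
    cesarean: int | None = None
    spontaneous_labor: int | None = None
    icu_admission: int | None = None
    withdrawn: bool = False


def _empty(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA


def validate_table(df: pd.DataFrame) -> None:
    """Raise :class:`TrialDataError` on the first invariant violation."""
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrialDataError(f"missing required columns: {missing_cols}")
    for i, row in enumerate(df.itertuples(index=False)):
        if _empty(row.arm) or str(row.arm) not in Arm.__members__:
            raise TrialDataError(f"unknown arm label {row.arm!r}", row=i, column="arm")
        if _empty(row.site) or str(row.site) not in Site.__members__:
            raise TrialDataError(f"unknown site label {row.site!r}", row=i, column="site")
        ga = row.ga_days
        if not _empty(ga) and not (GA_DAYS_MIN <= ga <= GA_DAYS_MAX):
            raise TrialDataError(
                f"ga_days={ga} outside [{GA_DAYS_MIN}, {GA_DAYS_MAX}]", row=i, column="ga_days"
            )
        dha = row.enrolment_dha_pct
        if not _empty(dha) and not (DHA_PCT_MIN < dha < DHA_PCT_MAX):
            raise TrialDataError(
                f"enrolment_dha_pct={dha} outside ({DHA_PCT_MIN}, {DHA_PCT_MAX})",
                row=i,
                column="enrolment_dha_pct",
            )
        for col in _BINARY_COLS:
            v = getattr(row, col)
            if not _empty(v) and v not in (0, 1):
                raise TrialDataError(f"{col}={v!r} not in {{0,1}}", row=i, column=col)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read a participant CSV into a validated DataFrame.

    Empty cells become pandas NA; malformed numeric cells raise a
    :class:`TrialDataError` naming the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise TrialDataError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas-level failure
        raise TrialDataError(f"unreadable CSV: {exc}") from exc
    raw = raw.drop(columns=[c for c in raw.columns if c == "schema_version"])

    df = pd.DataFrame()
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    if missing_cols:
        raise TrialDataError(f"missing required columns: {missing_cols}")
    df["participant_id"] = raw["participant_id"]
    df["site"] = raw["site"]
    df["arm"] = raw["arm"]

    def parse_numeric(col: str, dtype: str) -> pd.Series:
        vals = []
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell == "":
                vals.append(pd.NA)
                continue
            try:
                vals.append(float(cell))
            except ValueError as exc:
                raise TrialDataError(
                    f"malformed numeric cell {cell!r}", row=i, column=col
                ) from exc
        s = pd.Series(vals, dtype="Float64")
        if dtype == "int":
            bad = s.dropna() % 1 != 0
            if bad.any():
                i = int(bad[bad].index[0])
                raise TrialDataError(
                    f"expected integer, got {s[i]}", row=i, column=col
                )
            return s.astype("Int64")
        return s

    for col in _INT_COLS + _BINARY_COLS:
        df[col] = parse_numeric(col, "int")
    for col in _FLOAT_COLS:
        df[col] = parse_numeric(col, "float")

    withdrawn = []
    for i, cell in enumerate(raw["withdrawn"]):
        c = cell.strip().lower()
        if c in ("true", "1"):
            withdrawn.append(True)
        elif c in ("false", "0", ""):
            withdrawn.append(False)
        else:
            raise TrialDataError(f"malformed boolean {cell!r}", row=i, column="withdrawn")
    df["withdrawn"] = withdrawn
    df = df[COLUMNS]
    validate_table(df)
    return df


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a participant table as CSV; missing values become empty cells."""
    validate_table(df)
    out = df[COLUMNS].copy()
    out["withdrawn"] = out["withdrawn"].map({True: "true", False: "false"})
    out.to_csv(path, index=False, na_rep="")


def records_from_frame(df: pd.DataFrame) -> list[ParticipantRecord]:
    recs = []
    for _, row in df.iterrows():
        kwargs = {}
        for f in dc_fields(ParticipantRecord):
            v = row[f.name]
            kwargs[f.name] = None if _empty(v) else v
        recs.append(ParticipantRecord(**kwargs))
    return recs


def frame_from_records(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    rows = [{f.name: getattr(r, f.name) for f in dc_fields(ParticipantRecord)} for r in records]
    df = pd.DataFrame(rows, columns=COLUMNS)
    for col in _INT_COLS + _BINARY_COLS:
        df[col] = pd.array(df[col], dtype="Int64")
    for col in _FLOAT_COLS:
        df[col] = pd.array(df[col], dtype="Float64")
    df["withdrawn"] = df["withdrawn"].fillna(False).astype(bool)
    return df


# ---------------------------------------------------------------------------
# derived classifications
# ---------------------------------------------------------------------------

def classify_dha_status(enrolment_dha_pct: float | None, cutoff_pct: float = 6.0) -> DhaStatus:
    """Low DHA status iff enrolment RBC DHA is strictly below the cutoff.

    Missing input yields an explicit MISSING status (the participant is
    simply excluded from status subgroup analyses).
    """
    if _empty(enrolment_dha_pct):
        return DhaStatus.MISSING
    return DhaStatus.LOW if enrolment_dha_pct < cutoff_pct else DhaStatus.HIGH


def convert_bloodspot_to_rbc(bloodspot_pct: float, factor: float = 0.4754) -> float:
    """Convert whole-blood-spot DHA %% to the RBC phospholipid scale.

    The blood-spot cutpoint 2.85% divided by 0.4754 gives ~5.995%, which is
    where the 6% low-status cutoff on the RBC scale comes from.
    """
    if bloodspot_pct <= 0:
        raise ValueError("bloodspot_pct must be positive")
    return bloodspot_pct / factor


def is_epb(ga_days, threshold_days: int = 238):
    """EPB flag: strictly before 34 completed weeks. NA-propagating."""
    if isinstance(ga_days, (pd.Series,)):
        return ga_days < threshold_days
    if _empty(ga_days):
        return None
    return bool(ga_days < threshold_days)


def is_preterm(ga_days, threshold_days: int = 259):
    """Preterm flag: strictly before 37 weeks. NA-propagating."""
    if isinstance(ga_days, (pd.Series,)):
        return ga_days < threshold_days
    if _empty(ga_days):
        return None
    return bool(ga_days < threshold_days)


def assign_quartiles(values) -> pd.Series:
    """Quartile index 1..4 of enrolment DHA over the pooled cohort.

    Cutpoints are the empirical 25/50/75 percentiles of the non-missing
    values; a value equal to a cutpoint goes to the lower quartile, so
    heavily tied data collapse downward (eight equal values are all
    quartile 1).  Missing values get pandas NA.
    """
    s = pd.Series(values, dtype="Float64")
    obs = s.dropna().astype(float)
    if len(obs) == 0:
        raise TrialDataError("cannot assign quartiles: all enrolment DHA values missing")
    if len(obs) < 4:
        raise TrialDataError("need at least 4 non-missing values for quartiles")
    q1, q2, q3 = np.quantile(obs.to_numpy(), [0.25, 0.5, 0.75])
    out = pd.array([pd.NA] * len(s), dtype="Int64")
    arr = s.to_numpy(dtype=float, na_value=np.nan)
    idx = ~np.isnan(arr)
    quart = 1 + (arr[idx] > q1).astype(int) + (arr[idx] > q2).astype(int) + (arr[idx] > q3).astype(int)
    out[np.flatnonzero(idx)] = quart
    return pd.Series(out, index=s.index, name="dha_quartile")


def add_derived_columns(df: pd.DataFrame, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Return a copy with epb / preterm / dha_status / dha_quartile columns."""
    cfg = cfg or AnalysisConfig()
    out = df.copy()
    out["epb"] = out["ga_days"] < cfg.epb_threshold_days
    out.loc[out["ga_days"].isna(), "epb"] = pd.NA
    out["preterm"] = out["ga_days"] < cfg.preterm_threshold_days
    out.loc[out["ga_days"].isna(), "preterm"] = pd.NA
    out["dha_status"] = [
        classify_dha_status(v, cfg.dha_cutoff_pct).value
        for v in out["enrolment_dha_pct"].to_numpy(dtype=float, na_value=np.nan)
    ]
    try:
        out["dha_quartile"] = assign_quartiles(out["enrolment_dha_pct"])
    except TrialDataError:
        out["dha_quartile"] = pd.array([pd.NA] * len(out), dtype="Int64")
    return out
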