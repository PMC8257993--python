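"""Publication-style analysis bundle for one trial table.

``analyze_trial`` runs the whole intention-to-treat pipeline in sequence —
conjugate binomial primary, mixture-dichotomised primary, DHA-status
subgroups, secondary outcomes under an explicit outcome->model/direction
map, enrolment-DHA quartiles, and (when counts are supplied) the multilevel
adverse-event model — and collects everything into a :class:`ReportBundle`
whose rendering is pure (regenerating the report from the stored results is
byte-identical).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .adverse_events import AeCategoryCount, fit_ae_model
from .config import AnalysisConfig, Arm, Direction, McmcSettings
from .conjugate import (
    NormalSummary,
    fit_beta_binomial,
    impute_missing_binary,
    normal_prob_better,
    number_needed_to_treat,
    prob_better,
    summarize_rate,
)
from .mixture import compare_arms_mixture, fit_mixture, fit_subgroups
from .trial_data import add_derived_columns, read_trial_table, validate_table

#: outcome -> (model kind, direction of benefit for the high dose);
#: explicit because the direction convention is a reporting choice, never
#: inferred from the data.
DEFAULT_OUTCOME_MAP = {
    "preterm": ("binomial", Direction.LOWER_IS_BETTER),
    "gdm": ("binomial", Direction.LOWER_IS_BETTER),
    "preeclampsia": ("binomial", Direction.LOWER_IS_BETTER),
    "cesarean": ("binomial", Direction.LOWER_IS_BETTER),
    "spontaneous_labor": ("binomial", Direction.LOWER_IS_BETTER),
    "icu_admission": ("binomial", Direction.LOWER_IS_BETTER),
    "ga_days": ("normal", Direction.HIGHER_IS_BETTER),
    "birth_weight_g": ("normal", Direction.HIGHER_IS_BETTER),
    "birth_length_cm": ("normal", Direction.HIGHER_IS_BETTER),
    "head_circumference_cm": ("normal", Direction.HIGHER_IS_BETTER),
}


@dataclass
class ReportBundle:
    primary: pd.DataFrame
    subgroups: pd.DataFrame
    secondary: pd.DataFrame
    quartiles: pd.DataFrame
    nnt_lines: list[str]
    ae_summary: pd.DataFrame | None
    metadata: dict = field(default_factory=dict)

    def render_text(self) -> str:
        buf = io.StringIO()
        w = buf.write
        w("== Primary efficacy: early preterm birth (<34 weeks) ==\n")
        w(self.primary.to_string(index=False) + "\n\n")
        if len(self.subgroups):
            w("== Subgroups by enrolment DHA status ==\n")
            w(self.subgroups.to_string(index=False) + "\n\n")
        w("== Secondary outcomes ==\n")
        w(self.secondary.to_string(index=False) + "\n\n")
        w("== EPB by enrolment-DHA quartile ==\n")
        w(self.quartiles.to_string(index=False) + "\n\n")
        for line in self.nnt_lines:
            w(line + "\n")
        if self.ae_summary is not None:
            w("\n== Adverse events (partial pooling) ==\n")
            w(self.ae_summary.to_string(index=False) + "\n")
        w("\n-- run metadata --\n")
        for k, v in sorted(self.metadata.items()):
            w(f"{k}: {v}\n")
        return buf.getvalue()

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.primary.to_csv(outdir / "primary.csv", index=False)
        self.subgroups.to_csv(outdir / "subgroups.csv", index=False)
        self.secondary.to_csv(outdir / "secondary.csv", index=False)
        self.quartiles.to_csv(outdir / "quartiles.csv", index=False)
        if self.ae_summary is not None:
            self.ae_summary.to_csv(outdir / "adverse_events.csv", index=False)
        (outdir / "report.txt").write_text(self.render_text())


def _arm_split(df: pd.DataFrame):
    lo = df[df["arm"] == Arm.LOW_200.value]
    hi = df[df["arm"] == Arm.HIGH_1000.value]
    return lo, hi


def quartile_epb_table(df: pd.DataFrame, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Observed EPB proportion per enrolment-DHA quartile, by arm and pooled."""
    cfg = cfg or AnalysisConfig()
    d = add_derived_columns(df, cfg)
    d = d[d["ga_days"].notna() & d["dha_quartile"].notna()]
    rows = []
    for q in (1, 2, 3, 4):
        sub = d[d["dha_quartile"] == q]
        row = {"quartile": q}
        for label, part in (
            ("low_dose", sub[sub["arm"] == Arm.LOW_200.value]),
            ("high_dose", sub[sub["arm"] == Arm.HIGH_1000.value]),
            ("pooled", sub),
        ):
            n = len(part)
            e = int(part["epb"].astype(bool).sum()) if n else 0
            row[f"{label}_events"] = e
            row[f"{label}_n"] = n
            row[f"{label}_rate_pct"] = 100.0 * e / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_trial(
    table: str | Path | pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    settings: McmcSettings | None = None,
    mixture_settings: McmcSettings | None = None,
    ae_counts: list[AeCategoryCount] | None = None,
    outcome_map: dict | None = None,
) -> ReportBundle:
    """Full intention-to-treat analysis of one participant table."""
    cfg = cfg or AnalysisConfig()
    settings = settings or McmcSettings()
    mixture_settings = mixture_settings or McmcSettings(
        burn_in=1000, keep=4000, seed=settings.seed, chains=2
    )
    outcome_map = outcome_map or DEFAULT_OUTCOME_MAP

    if isinstance(table, (str, Path)):
        df = read_trial_table(table)
    else:
        validate_table(table)
        df = table
    if len(df) == 0:
        raise ValueError("empty table: nothing to analyze")
    d = add_derived_columns(df, cfg)
    lo, hi = _arm_split(d)

    # --- primary binomial (conjugate; imputation over missing outcomes) ---
    def epb_counts(part):
        obs = part[part["ga_days"].notna()]
        return int(obs["epb"].astype(bool).sum()), len(obs), len(part) - len(obs)

    e_lo, n_lo, m_lo = epb_counts(lo)
    e_hi, n_hi, m_hi = epb_counts(hi)
    post_lo = fit_beta_binomial(e_lo, n_lo)
    post_hi = fit_beta_binomial(e_hi, n_hi)
    pp_binom = prob_better(post_hi, post_lo, Direction.LOWER_IS_BETTER,
                           method="monte_carlo", settings=settings)
    imp_lo = impute_missing_binary(e_lo, n_lo, m_lo, settings=settings)
    imp_hi = impute_missing_binary(e_hi, n_hi, m_hi, settings=settings)
    pp_imputed = imp_hi.prob_better_than(imp_lo, Direction.LOWER_IS_BETTER, settings)

    s_lo = summarize_rate(post_lo, Direction.LOWER_IS_BETTER, pp_binom, cfg.interval_kind)
    s_hi = summarize_rate(post_hi, Direction.LOWER_IS_BETTER, pp_binom, cfg.interval_kind)
    primary_rows = [
        {
            "model": "binomial",
            "low_events": e_lo, "low_n": n_lo,
            "high_events": e_hi, "high_n": n_hi,
            "low_mean_pct": s_lo.post_mean, "low_cri": (s_lo.cri_low, s_lo.cri_high),
            "high_mean_pct": s_hi.post_mean, "high_cri": (s_hi.cri_low, s_hi.cri_high),
            "pp_high_better": pp_binom,
            "pp_high_better_imputed": pp_imputed,
        }
    ]

    # --- primary mixture (dichotomised three-normal model) ---
    ga_lo = lo["ga_days"].dropna().to_numpy(dtype=float)
    ga_hi = hi["ga_days"].dropna().to_numpy(dtype=float)
    mix = None
    if min(len(ga_lo), len(ga_hi)) >= 30:
        draws = fit_mixture((ga_lo, ga_hi), settings=mixture_settings,
                            threshold_days=cfg.epb_threshold_days)
        mix = compare_arms_mixture(draws)
        primary_rows.append(
            {
                "model": "mixture",
                "low_events": e_lo, "low_n": n_lo,
                "high_events": e_hi, "high_n": n_hi,
                "low_mean_pct": mix["low"].post_mean,
                "low_cri": (mix["low"].cri_low, mix["low"].cri_high),
                "high_mean_pct": mix["high"].post_mean,
                "high_cri": (mix["high"].cri_low, mix["high"].cri_high),
                "pp_high_better": mix["pp"],
                "pp_high_better_imputed": float("nan"),
            }
        )
    primary = pd.DataFrame(primary_rows)

    # --- subgroups (independent mixture fits per DHA stratum) ---
    sub_res = fit_subgroups(d, cfg.dha_cutoff_pct, settings=mixture_settings,
                            threshold_days=cfg.epb_threshold_days)
    sub_rows = []
    for stratum, res in sub_res.items():
        sub_rows.append(
            {
                "stratum": stratum,
                "low_mean_pct": res["low"].post_mean,
                "high_mean_pct": res["high"].post_mean,
                "pp_high_better": res["pp"],
            }
        )
    subgroups = pd.DataFrame(sub_rows, columns=["stratum", "low_mean_pct",
                                                "high_mean_pct", "pp_high_better"])

    # --- secondary outcomes ---
    sec_rows = []
    for outcome, (kind, direction) in outcome_map.items():
        if outcome not in d.columns:
            continue
        if kind == "binomial":
            col_lo = lo[outcome].dropna()
            col_hi = hi[outcome].dropna()
            if len(col_lo) == 0 or len(col_hi) == 0:
                continue
            p_lo = fit_beta_binomial(int(col_lo.astype(bool).sum()), len(col_lo))
            p_hi = fit_beta_binomial(int(col_hi.astype(bool).sum()), len(col_hi))
            pp = prob_better(p_hi, p_lo, direction, method="monte_carlo", settings=settings)
            sec_rows.append({
                "outcome": outcome, "model": kind,
                "low_summary": f"{int(col_lo.astype(bool).sum())}/{len(col_lo)}",
                "high_summary": f"{int(col_hi.astype(bool).sum())}/{len(col_hi)}",
                "pp_high_better": pp,
            })
        else:
            v_lo = lo[outcome].dropna().to_numpy(dtype=float)
            v_hi = hi[outcome].dropna().to_numpy(dtype=float)
            if len(v_lo) < 2 or len(v_hi) < 2:
                continue
            res = normal_prob_better(
                NormalSummary(float(v_hi.mean()), float(v_hi.std(ddof=1)), len(v_hi)),
                NormalSummary(float(v_lo.mean()), float(v_lo.std(ddof=1)), len(v_lo)),
                direction, settings=settings,
            )
            sec_rows.append({
                "outcome": outcome, "model": kind,
                "low_summary": f"{v_lo.mean():.1f} ({v_lo.std(ddof=1):.1f})",
                "high_summary": f"{v_hi.mean():.1f} ({v_hi.std(ddof=1):.1f})",
                "pp_high_better": res.pp_high_better,
            })
    secondary = pd.DataFrame(sec_rows)

    # --- quartiles & number-needed-to-treat ---
    quartiles = quartile_epb_table(df, cfg)
    nnt_lines = []
    rate_lo_pct = (mix["low"].post_mean if mix else s_lo.post_mean)
    rate_hi_pct = (mix["high"].post_mean if mix else s_hi.post_mean)
    try:
        nnt = number_needed_to_treat(rate_hi_pct, rate_lo_pct)
        nnt_lines.append(
            f"NNT (overall, from posterior means "
            f"{rate_lo_pct:.1f}% vs {rate_hi_pct:.1f}%): {nnt}"
        )
    except ZeroDivisionError:
        nnt_lines.append("NNT (overall): undefined (equal posterior mean rates)")

    # --- adverse events ---
    ae_summary = None
    if ae_counts:
        res = fit_ae_model(ae_counts, settings=McmcSettings(
            burn_in=2000, keep=6000, seed=settings.seed, chains=1))
        ae_summary = pd.DataFrame(
            [{"category": c, "pp_high_better": res.pp_per_category[c],
              "log_or_mean": res.delta_mean[c]} for c in res.categories]
            + [{"category": "(pooled, hyper)", "pp_high_better": res.pp_pooled_hyper,
                "log_or_mean": res.mu_delta_mean},
               {"category": "(pooled, counts)", "pp_high_better": res.pp_pooled_counts,
                "log_or_mean": float("nan")}]
        )

    meta = {
        "package_version": __version__,
        "seed": settings.seed,
        "mc_draws": settings.keep,
        "mixture_burn_in": mixture_settings.burn_in,
        "mixture_keep": mixture_settings.keep,
        "mixture_chains": mixture_settings.chains,
        "dha_cutoff_pct": cfg.dha_cutoff_pct,
        "epb_threshold_days": cfg.epb_threshold_days,
        "n_rows": len(df),
    }
    return ReportBundle(primary, subgroups, secondary, quartiles, nnt_lines, ae_summary, meta)
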