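"""Longitudinal group statistics for the bleomycin fibrosis study design.

Works on a long-format study table — one value per (subject, day, region,
biomarker) with arm assignments SAL (saline control), BLM (bleomycin) and
BLM+NINT (bleomycin + nintedanib) over study days 7/14/21 — and mirrors
the analysis a preclinical imaging study runs on it:

* normalization of every biomarker to the control mean, where the control
  mean pools all SAL subjects over all three days; %Non is exempt and is
  reported as an absolute percentage, since it is essentially zero in
  healthy lungs;
* two-way (group x day) ANOVA with Šidák-adjusted within-group day-21 vs
  day-7 contrasts and Dunnett-adjusted per-day contrasts of SAL and
  BLM+NINT against BLM;
* a signed percent inhibition/recovery of the treated arm versus the
  disease arm at study end: 100 x (mean_NINT - mean_BLM) / mean_BLM,
  negative = inhibition, positive = recovery.  An alternative convention
  relative to the disease delta, 100 x (NINT - BLM) / (SAL - BLM), is
  available behind a flag;
* paired left-vs-right lobe comparisons gated on normality of the paired
  differences (Shapiro-Wilk at alpha = 0.05): paired t when normal,
  Wilcoxon signed-rank otherwise.

Group summaries report mean ± SEM.  Day is treated as a categorical
factor and the ANOVA is an ordinary (not repeated-measures) two-way fit
on per-subject values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .errors import (
    InsufficientDataError,
    NormalizationError,
    UndefinedChangeError,
)

STUDY_COLUMNS = ["subject_id", "group", "day", "region", "biomarker", "value"]

#: biomarkers exempt from control normalization (absolute percentages)
NORMALIZATION_EXEMPT = frozenset({"pct_non"})

#: biomarker columns of the tidy biomarker table that enter the study table
DEFAULT_BIOMARKERS = (
    "pct_normo", "pct_hypo", "pct_non", "tissue",
    "v_p02", "pct_gas_p01", "pct_gas_p02", "tv",
)

CONTROL_GROUP = "SAL"
DISEASE_GROUP = "BLM"
TREATED_GROUP = "BLM+NINT"


def build_study_table(
    biomarker_frame: pd.DataFrame,
    biomarkers: tuple[str, ...] = DEFAULT_BIOMARKERS,
) -> pd.DataFrame:
    """Melt the wide per-(subject, day, region) biomarker table to long format."""
    id_cols = ["subject_id", "group", "day", "region"]
    long = biomarker_frame.melt(
        id_vars=id_cols,
        value_vars=[b for b in biomarkers if b in biomarker_frame.columns],
        var_name="biomarker",
        value_name="value",
    )
    dup = long.duplicated(subset=["subject_id", "day", "region", "biomarker"])
    if dup.any():
        raise ValueError(
            f"study table has {int(dup.sum())} duplicate (subject, day, region, biomarker) cells"
        )
    return long[STUDY_COLUMNS]


def normalize_to_control(
    table: pd.DataFrame,
    control: str = CONTROL_GROUP,
    exempt: frozenset[str] = NORMALIZATION_EXEMPT,
) -> pd.DataFrame:
    """Divide every value by the pooled control mean of its (region, biomarker).

    The control mean pools all control subjects over all days, so the
    normalized control mean is 1 by construction.  Biomarkers in
    ``exempt`` pass through unchanged.
    """
    ctrl = table[table["group"] == control]
    if ctrl.empty:
        raise NormalizationError(f"no {control!r} rows to normalize against")
    means = ctrl.groupby(["region", "biomarker"])["value"].mean()
    out = table.copy()
    for (region, biomarker), mean in means.items():
        if biomarker in exempt:
            continue
        if mean == 0:
            raise NormalizationError(
                f"pooled {control} mean is zero for ({region}, {biomarker})"
            )
        sel = (out["region"] == region) & (out["biomarker"] == biomarker)
        out.loc[sel, "value"] = out.loc[sel, "value"] / mean
    covered = set(means.index)
    needed = set(map(tuple, table[["region", "biomarker"]].drop_duplicates().values))
    missing = {k for k in needed - covered if k[1] not in exempt}
    if missing:
        raise NormalizationError(f"no control values for cells: {sorted(missing)}")
    return out


def percent_change_vs_blm(
    table: pd.DataFrame,
    biomarker: str,
    region: str,
    day: int = 21,
    convention: str = "vs_blm",
) -> float:
    """Signed treated-vs-disease percent change at a study day.

    ``vs_blm`` (default): 100 x (mean_NINT - mean_BLM) / mean_BLM;
    negative values read as percent inhibition, positive as recovery.
    ``vs_disease_delta``: 100 x (mean_NINT - mean_BLM) / (mean_SAL -
    mean_BLM), the fraction of the disease effect removed.
    """
    sub = table[
        (table["biomarker"] == biomarker)
        & (table["region"] == region)
        & (table["day"] == day)
    ]
    means = sub.groupby("group")["value"].mean()
    for g in (DISEASE_GROUP, TREATED_GROUP):
        if g not in means:
            raise InsufficientDataError(f"no {g} values at day {day} for {biomarker}/{region}")
    delta = means[TREATED_GROUP] - means[DISEASE_GROUP]
    if convention == "vs_blm":
        if means[DISEASE_GROUP] == 0:
            raise UndefinedChangeError(
                f"BLM mean is zero for {biomarker}/{region} at day {day}"
            )
        return float(100.0 * delta / means[DISEASE_GROUP])
    if convention == "vs_disease_delta":
        if CONTROL_GROUP not in means:
            raise InsufficientDataError("vs_disease_delta needs SAL values at the day")
        denom = means[CONTROL_GROUP] - means[DISEASE_GROUP]
        if denom == 0:
            raise UndefinedChangeError("SAL and BLM means coincide; delta undefined")
        return float(100.0 * delta / denom)
    raise ValueError(f"unknown convention {convention!r}")


def sidak_adjust(p: float, k: int) -> float:
    """Šidák family-wise adjustment of one p-value over k comparisons."""
    return float(1.0 - (1.0 - min(max(p, 0.0), 1.0)) ** k)


@dataclass
class EffectSummary:
    """Result bundle of the longitudinal analysis of one biomarker/region."""

    biomarker: str
    region: str
    #: (group, day) -> (mean, sem, n)
    group_stats: dict
    #: ANOVA table p-values: {"group": p, "day": p, "group:day": p}
    anova_p: dict
    #: group -> {"p_raw", "p_adj", "estimate"} for the day-21 vs day-7 contrast
    within_group: dict
    #: day -> group -> {"p_raw", "p_adj", "estimate"} for contrasts vs BLM
    vs_blm: dict
    percent_change_vs_blm_day21: float | None
    warnings: list = field(default_factory=list)


def _group_cell(values: np.ndarray) -> tuple[float, float, int]:
    n = len(values)
    mean = float(np.mean(values)) if n else float("nan")
    sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, sem, n


def longitudinal_tests(
    table: pd.DataFrame,
    biomarker: str,
    region: str,
    alpha: float = 0.05,
) -> EffectSummary:
    """Two-way ANOVA with Šidák longitudinal and Dunnett between-group contrasts.

    Within-group day-21 vs day-7 contrasts use the pooled residual error of
    the two-way fit and are Šidák-adjusted over the groups tested.
    Between-group contrasts at each day compare every non-BLM arm against
    BLM with Dunnett's many-to-one procedure.  Missing design cells degrade
    to the available contrasts with a warning rather than failing the run.
    """
    sub = table[
        (table["biomarker"] == biomarker) & (table["region"] == region)
    ].dropna(subset=["value"])
    if sub.empty:
        raise InsufficientDataError(f"no data for {biomarker}/{region}")

    notes: list[str] = []
    groups = sorted(sub["group"].unique())
    days = sorted(sub["day"].unique())

    group_stats = {}
    for g in groups:
        for d in days:
            vals = sub[(sub["group"] == g) & (sub["day"] == d)]["value"].to_numpy()
            group_stats[(g, d)] = _group_cell(vals)
            if len(vals) < 2:
                notes.append(f"cell ({g}, day {d}) has n={len(vals)}")

    # two-way ANOVA, day categorical
    anova_p: dict[str, float] = {}
    mse = np.nan
    df_resid = 0
    if len(groups) > 1 and len(days) > 1:
        fit = ols("value ~ C(group) * C(day)", data=sub).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        anova_p = {
            "group": float(tab.loc["C(group)", "PR(>F)"]),
            "day": float(tab.loc["C(day)", "PR(>F)"]),
            "group:day": float(tab.loc["C(group):C(day)", "PR(>F)"]),
        }
        mse = float(fit.mse_resid)
        df_resid = int(fit.df_resid)
    else:
        notes.append("degenerate design: need >=2 groups and >=2 days for ANOVA")

    # within-group day21-vs-day7 contrasts on the pooled residual error
    within: dict[str, dict] = {}
    d_lo, d_hi = (7, 21) if {7, 21} <= set(days) else (min(days), max(days))
    testable = [
        g for g in groups
        if group_stats[(g, d_lo)][2] >= 2 and group_stats[(g, d_hi)][2] >= 2
    ]
    for g in testable:
        m1, _, n1 = group_stats[(g, d_lo)]
        m2, _, n2 = group_stats[(g, d_hi)]
        est = m2 - m1
        if np.isfinite(mse) and mse > 0 and df_resid > 0:
            se = np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
            t = est / se
            p_raw = float(2.0 * stats.t.sf(abs(t), df_resid))
        else:
            p_raw = 1.0 if est == 0 else float("nan")
            notes.append(f"no residual error available for contrast in group {g}")
        within[g] = {
            "estimate": float(est),
            "p_raw": p_raw,
            "p_adj": sidak_adjust(p_raw, len(testable)) if np.isfinite(p_raw) else p_raw,
        }

    # per-day Dunnett contrasts vs the BLM arm
    vs_blm: dict[int, dict] = {}
    others = [g for g in groups if g != DISEASE_GROUP]
    for d in days:
        ctrl_vals = sub[(sub["group"] == DISEASE_GROUP) & (sub["day"] == d)]["value"].to_numpy()
        if len(ctrl_vals) < 2:
            notes.append(f"day {d}: BLM cell too small for Dunnett contrasts")
            continue
        samples = []
        names = []
        for g in others:
            vals = sub[(sub["group"] == g) & (sub["day"] == d)]["value"].to_numpy()
            if len(vals) >= 2:
                samples.append(vals)
                names.append(g)
            else:
                notes.append(f"day {d}: cell ({g}) too small for Dunnett contrast")
        if not samples:
            continue
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # near-constant cells (e.g. %Non in healthy controls) trip scipy's
            # precision-loss warning; the contrast itself is still well defined
            warnings.simplefilter("ignore", RuntimeWarning)
            # fixed rng: the equicoordinate multivariate-t integral is
            # evaluated by randomized QMC and must be reproducible
            res = stats.dunnett(*samples, control=ctrl_vals, rng=np.random.default_rng(0))
        # raw per-comparison p from the same pooled-variance statistic
        n_all = [len(ctrl_vals)] + [len(s) for s in samples]
        df_pool = sum(n_all) - len(n_all)
        day_out = {}
        for i, g in enumerate(names):
            t_i = float(res.statistic[i])
            p_raw = float(2.0 * stats.t.sf(abs(t_i), df_pool))
            # the max-|T| tail dominates the single-|T| tail by construction;
            # floor the QMC-integrated value to the analytic bound so the
            # ordering survives integration error at extreme statistics
            day_out[g] = {
                "estimate": float(np.mean(samples[i]) - np.mean(ctrl_vals)),
                "p_raw": p_raw,
                "p_adj": float(max(res.pvalue[i], p_raw)),
            }
        vs_blm[d] = day_out

    try:
        pct = percent_change_vs_blm(table, biomarker, region, day=max(days))
    except (InsufficientDataError, UndefinedChangeError):
        pct = None

    return EffectSummary(
        biomarker=biomarker,
        region=region,
        group_stats=group_stats,
        anova_p=anova_p,
        within_group=within,
        vs_blm=vs_blm,
        percent_change_vs_blm_day21=pct,
        warnings=notes,
    )


@dataclass
class PairedTestResult:
    statistic: float
    pvalue: float
    test_used: str  # "paired_t" | "wilcoxon" | "degenerate_*"
    n: int
    mean_diff: float
    shapiro_p: float | None = None


def paired_lobe_test(
    table: pd.DataFrame,
    biomarker: str,
    group: str,
    day: int,
    alpha_normality: float = 0.05,
) -> PairedTestResult:
    """Paired left-vs-right comparison of one biomarker in one group/day.

    Differences (left - right) are tested for normality with Shapiro-Wilk
    at ``alpha_normality``; paired t when normal, Wilcoxon signed-rank
    otherwise.  All-zero differences return the degenerate "no difference"
    result (p = 1); nonzero constant differences are flagged degenerate
    (zero variance defeats both tests).
    """
    sub = table[
        (table["biomarker"] == biomarker)
        & (table["group"] == group)
        & (table["day"] == day)
        & (table["region"].isin(["left", "right"]))
    ]
    wide = sub.pivot_table(index="subject_id", columns="region", values="value")
    wide = wide.dropna(subset=["left", "right"]) if {"left", "right"} <= set(wide.columns) else wide.iloc[0:0]
    n = len(wide)
    if n < 3:
        raise InsufficientDataError(
            f"paired lobe test needs >=3 complete pairs, got {n} "
            f"({biomarker}, {group}, day {day})"
        )
    diffs = (wide["left"] - wide["right"]).to_numpy()
    mean_diff = float(diffs.mean())
    if np.all(diffs == 0):
        return PairedTestResult(0.0, 1.0, "degenerate_no_difference", n, 0.0)
    if np.std(diffs) == 0:
        return PairedTestResult(
            float("nan"), float("nan"), "degenerate_zero_variance", n, mean_diff
        )
    sh_stat, sh_p = stats.shapiro(diffs)
    if sh_p >= alpha_normality:
        t, p = stats.ttest_rel(wide["left"], wide["right"])
        return PairedTestResult(float(t), float(p), "paired_t", n, mean_diff, float(sh_p))
    w, p = stats.wilcoxon(diffs)
    return PairedTestResult(float(w), float(p), "wilcoxon", n, mean_diff, float(sh_p))


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def paired_lobe_matrix(
    table: pd.DataFrame,
    biomarkers: tuple[str, ...],
    groups: tuple[str, ...] = (DISEASE_GROUP, TREATED_GROUP),
    days: tuple[int, ...] = (7, 14, 21),
) -> pd.DataFrame:
    """Significance matrix of paired left-vs-right tests.

    Rows are biomarkers, columns group x day, cells ns/*/**/***.
    """
    rows = {}
    for b in biomarkers:
        row = {}
        for g in groups:
            for d in days:
                try:
                    res = paired_lobe_test(table, b, g, d)
                    row[f"{g}_day{d}"] = significance_stars(res.pvalue)
                except InsufficientDataError:
                    row[f"{g}_day{d}"] = "na"
        rows[b] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "biomarker"
    return out


def effect_summaries_to_frame(summaries: list[EffectSummary]) -> pd.DataFrame:
    """Flatten effect summaries into a tidy CSV-ready table."""
    rows = []
    for s in summaries:
        for (g, d), (mean, sem, n) in sorted(s.group_stats.items()):
            rows.append(
                {
                    "biomarker": s.biomarker,
                    "region": s.region,
                    "group": g,
                    "day": d,
                    "mean": mean,
                    "sem": sem,
                    "n": n,
                    "anova_p_group": s.anova_p.get("group", np.nan),
                    "anova_p_day": s.anova_p.get("day", np.nan),
                    "anova_p_interaction": s.anova_p.get("group:day", np.nan),
                    "within_day21_vs_day7_p_adj": s.within_group.get(g, {}).get("p_adj", np.nan),
                    "vs_blm_p_adj": s.vs_blm.get(d, {}).get(g, {}).get("p_adj", np.nan),
                    "percent_change_vs_blm_day21": (
                        s.percent_change_vs_blm_day21
                        if s.percent_change_vs_blm_day21 is not None
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
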