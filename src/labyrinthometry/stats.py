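"""Cohort statistics: group comparisons, EH-grade correlations,
duration-stratified tests and demographic summaries.

The battery mirrors standard clinical-morphometry practice: one-way ANOVA
across the three ear groups with post hoc pairwise comparisons (Bonferroni
by default, Tukey HSD selectable), Spearman rank correlation between
ordinal endolymphatic-hydrops grades and each metric on affected ears, and
independent-samples t-tests between disease-duration strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "pta",
    "three_group_comparison",
    "eh_correlations",
    "duration_stratified_tests",
    "summarize_cohort",
    "comparison_table",
]

GROUPS = ("MDAE", "MDUE", "HC")

#: Metric columns reported in the standard tables, in presentation order.
COCHLEAR_METRICS = [
    "ch_mm",
    "cochlear_volume_mm3",
    "bld_mm",
    "bsd_mm",
    "cdl_mm",
    "tl2_mm",
    "btl_mm",
    "angle_modiolus_lsc_deg",
    "angle_modiolus_psc_deg",
    "angle_modiolus_ssc_deg",
]
VESTIBULAR_METRICS = [
    "vestibular_volume_mm3",
    "length_a_mm",
    "length_b_mm",
    "length_c_mm",
    "area_ab_mm2",
    "area_bc_mm2",
    "area_ac_mm2",
    "angle_ab_lsc_deg",
    "angle_ac_lsc_deg",
    "angle_bc_lsc_deg",
    "angle_ab_psc_deg",
    "angle_ac_psc_deg",
    "angle_bc_psc_deg",
    "angle_ab_ssc_deg",
    "angle_ac_ssc_deg",
    "angle_bc_ssc_deg",
]
ALL_METRICS = COCHLEAR_METRICS + VESTIBULAR_METRICS


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_stats: dict[str, tuple[int, float, float]]  # group -> (n, mean, sd)
    f_statistic: float
    p_value: float
    posthoc: dict[tuple[str, str], float]  # pair -> adjusted p
    posthoc_method: str


@dataclass(frozen=True)
class CorrelationResult:
    metric: str
    grade_type: str
    spearman_r: float
    p_value: float
    n: int


def pta(thresholds_db) -> float:
    """Pure-tone average: mean of the 500/1000/2000/4000 Hz thresholds."""
    t = np.asarray(thresholds_db, dtype=float)
    if t.shape != (4,) or not np.all(np.isfinite(t)):
        raise ValueError("PTA requires four finite thresholds (500/1k/2k/4k Hz)")
    return float(t.mean())


def three_group_comparison(
    records: pd.DataFrame,
    metric: str,
    *,
    groups: tuple[str, ...] = GROUPS,
    posthoc: str = "bonferroni",
) -> GroupComparison:
    """One-way ANOVA of a metric across ear groups with post hoc pairwise
    comparisons.

    Bonferroni post hoc tests use the ANOVA's pooled error variance (as in
    common statistical packages); ``posthoc="tukey"`` selects Tukey HSD.
    """
    samples = []
    stats_by_group: dict[str, tuple[int, float, float]] = {}
    for g in groups:
        x = records.loc[records["group"] == g, metric].dropna().to_numpy(dtype=float)
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 finite values of {metric}")
        samples.append(x)
        stats_by_group[g] = (len(x), float(x.mean()), float(x.std(ddof=1)))
    if all(np.ptp(x) == 0 for x in samples):
        raise ValueError(f"{metric}: zero variance in every group; F undefined")

    f_stat, p_val = sps.f_oneway(*samples)

    pairs = list(combinations(groups, 2))
    adj: dict[tuple[str, str], float] = {}
    if posthoc == "bonferroni":
        n_tot = sum(len(x) for x in samples)
        df_err = n_tot - len(groups)
        mse = sum(((len(x) - 1) * x.var(ddof=1)) for x in samples) / df_err
        for (ga, xa), (gb, xb) in combinations(zip(groups, samples), 2):
            se = np.sqrt(mse * (1.0 / len(xa) + 1.0 / len(xb)))
            t = (xa.mean() - xb.mean()) / se
            p = 2.0 * sps.t.sf(abs(t), df_err)
            adj[(ga, gb)] = float(min(1.0, p * len(pairs)))
    elif posthoc == "tukey":
        values = np.concatenate(samples)
        labels = np.concatenate([[g] * len(x) for g, x in zip(groups, samples)])
        res = pairwise_tukeyhsd(values, labels)
        for row, p in zip(res._results_table.data[1:], res.pvalues):
            ga, gb = str(row[0]), str(row[1])
            # statsmodels orders pairs alphabetically; map back to our pairs
            key = (ga, gb) if (ga, gb) in pairs else (gb, ga)
            adj[key] = float(p)
    else:
        raise ValueError(f"unknown posthoc method {posthoc!r}")

    return GroupComparison(
        metric=metric,
        group_stats=stats_by_group,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        posthoc=adj,
        posthoc_method=posthoc,
    )


def eh_correlations(
    records: pd.DataFrame,
    grade_type: str,
    metrics: list[str] | None = None,
) -> list[CorrelationResult]:
    """Spearman rank correlation of each metric against an ordinal EH grade.

    Uses average ranks for ties and a two-sided p-value.  Intended for the
    affected-ear subset; rows with missing grades are dropped.  A constant
    grade vector is an error (the correlation is undefined, not zero).
    """
    if metrics is None:
        metrics = [m for m in ALL_METRICS if m in records.columns]
    sub = records.dropna(subset=[grade_type])
    grades = sub[grade_type].to_numpy(dtype=float)
    if len(grades) < 3:
        raise ValueError("need at least 3 graded records")
    if np.ptp(grades) == 0:
        raise ValueError(f"{grade_type} is constant; Spearman r undefined")
    out = []
    for m in metrics:
        r, p = sps.spearmanr(sub[m].to_numpy(dtype=float), grades)
        out.append(
            CorrelationResult(
                metric=m,
                grade_type=grade_type,
                spearman_r=float(r),
                p_value=float(p),
                n=len(grades),
            )
        )
    return out


def duration_stratified_tests(
    records: pd.DataFrame,
    *,
    cutoff_years: float = 5.0,
    strict_greater: bool = True,
    metrics: list[str] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Independent-samples t-tests between duration strata of affected ears.

    The long-duration stratum is duration > cutoff (``strict_greater=True``,
    default) or >= cutoff; ``equal_var`` selects the pooled-variance test
    (typical clinical-package default) versus Welch.  t is signed as
    (short mean - long mean).
    """
    if metrics is None:
        metrics = [m for m in ALL_METRICS if m in records.columns]
    d = records["duration_years"].to_numpy(dtype=float)
    long_mask = d > cutoff_years if strict_greater else d >= cutoff_years
    short = records[~long_mask & np.isfinite(d)]
    long_ = records[long_mask & np.isfinite(d)]
    if len(short) < 2 or len(long_) < 2:
        raise ValueError("each duration stratum needs at least 2 records")
    rows = []
    for m in metrics:
        a = short[m].to_numpy(dtype=float)
        b = long_[m].to_numpy(dtype=float)
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "metric": m,
                "n_short": len(a),
                "n_long": len(b),
                "short_mean": a.mean(),
                "short_sd": a.std(ddof=1),
                "long_mean": b.mean(),
                "long_sd": b.std(ddof=1),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def _pct(k: int, n: int) -> float:
    return round(100.0 * k / n, 2) if n else 0.0


def summarize_cohort(records: pd.DataFrame) -> dict:
    """Demographic/clinical summary of the patient cohort.

    Counts and percentages (2 d.p.) for categorical fields, mean +/- SD for
    continuous ones.  Patient-level fields are computed on affected ears
    (one row per patient); PTA is reported per ear group.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    out: dict = {}
    cols = records.columns
    mdae = records[records["group"] == "MDAE"]
    n = len(mdae)
    if n:
        out["n_patients"] = n
        if "age_years" in cols:
            out["age_years"] = (
                float(mdae["age_years"].mean()),
                float(mdae["age_years"].std(ddof=1)),
            )
        if "sex" in cols:
            n_f = int((mdae["sex"] == "F").sum())
            out["sex"] = {
                "Female": (n_f, _pct(n_f, n)),
                "Male": (n - n_f, _pct(n - n_f, n)),
            }
        if "ear_side" in cols:
            n_left = int((mdae["ear_side"] == "L").sum())
            out["laterality"] = {
                "Left": (n_left, _pct(n_left, n)),
                "Right": (n - n_left, _pct(n - n_left, n)),
            }
        if "duration_years" in cols:
            d = mdae["duration_years"].to_numpy(dtype=float)
            strata = {
                "< 1 year": int((d < 1).sum()),
                "1-5 years": int(((d >= 1) & (d <= 5)).sum()),
                "> 5 years": int((d > 5).sum()),
            }
            out["duration"] = {k: (v, _pct(v, n)) for k, v in strata.items()}
    if "pta_db" in cols:
        out["pta_db"] = {
            g: (
                float(records.loc[records["group"] == g, "pta_db"].mean()),
                float(records.loc[records["group"] == g, "pta_db"].std(ddof=1)),
            )
            for g in GROUPS
            if (records["group"] == g).any()
        }
    return out


def comparison_table(
    records: pd.DataFrame,
    metrics: list[str],
    *,
    posthoc: str = "bonferroni",
) -> pd.DataFrame:
    """Three-group comparison of several metrics as one tidy table
    (mean +/- SD per group, F, p, post hoc p per pair)."""
    rows = []
    for m in metrics:
        c = three_group_comparison(records, m, posthoc=posthoc)
        row: dict = {"metric": m}
        for g, (n, mean, sd) in c.group_stats.items():
            row[f"{g}_mean"] = mean
            row[f"{g}_sd"] = sd
            row[f"{g}_n"] = n
        row["F"] = c.f_statistic
        row["p"] = c.p_value
        for (ga, gb), p in c.posthoc.items():
            row[f"p_{ga}_vs_{gb}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")
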