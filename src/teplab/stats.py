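"""Group statistics: outlier exclusion, t-tests, 2x2 mixed ANOVA,
correlations, Bonferroni correction, and the tidy group-comparison driver.

Conventions follow the classical parametric toolkit: pooled-variance
Student's t with df = n1 + n2 - 2 and Cohen's d on the pooled sd; the 2x2
mixed (split-plot) ANOVA decomposes sums of squares with the between
effect tested against subject-within-group error and the within/interaction
effects against the time-by-subject error, reporting partial eta squared;
Pearson r is reported with df = n - 2 and a t-transform p-value; multiple
comparisons use min(1, p * m). Outlier exclusion removes values more than
``threshold_sd`` sample standard deviations from the group mean in a
single pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateSignalError, EstimatorError, SpecError


@dataclass
class StatResult:
    """One comparison: statistic, degrees of freedom, p, effect size."""

    name: str
    statistic: float
    df: tuple[float, ...] | float
    p_raw: float
    p_corrected: float | None = None
    effect_size: float = float("nan")
    effect_size_kind: str = ""


# ---------------------------------------------------------------------------


def exclude_outliers(values, threshold_sd: float = 2.0) -> np.ndarray:
    """Keep-mask: False where |x - mean| > threshold_sd * sample sd.

    Single pass; with n < 3 (sd unreliable or undefined) nothing is
    excluded. NaNs are excluded.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise EstimatorError("empty value list")
    keep = np.isfinite(x)
    if x.size < 3:
        return keep
    mean = x[keep].mean()
    sd = x[keep].std(ddof=1)
    if sd == 0:
        return keep
    return keep & (np.abs(x - mean) <= threshold_sd * sd)


def two_sample_t(a, b, name: str = "") -> StatResult:
    """Pooled-variance two-tailed t-test with Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise EstimatorError("two_sample_t needs n >= 2 per group")
    df = na + nb - 2
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if pooled_var == 0:
        if a.mean() != b.mean():
            raise DegenerateSignalError("zero pooled variance with unequal means: t infinite")
        return StatResult(name, 0.0, float(df), 1.0, effect_size=0.0, effect_size_kind="cohen_d")
    t = (a.mean() - b.mean()) / np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var)
    return StatResult(
        name, float(t), float(df), float(p), effect_size=float(d), effect_size_kind="cohen_d"
    )


def paired_t(a, b, name: str = "") -> StatResult:
    """Paired two-tailed t-test (used for post-hoc within-group contrasts)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise EstimatorError("paired_t needs matched samples with n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if diff.mean() != 0:
            raise DegenerateSignalError("zero difference variance with nonzero mean")
        return StatResult(name, 0.0, float(a.size - 1), 1.0, effect_size=0.0,
                          effect_size_kind="cohen_dz")
    t = diff.mean() / (sd / np.sqrt(a.size))
    df = a.size - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(name, float(t), float(df), float(p),
                      effect_size=float(diff.mean() / sd), effect_size_kind="cohen_dz")


# ---------------------------------------------------------------------------
# 2x2 mixed-design ANOVA


def mixed_anova_ss(table: pd.DataFrame) -> dict[str, float]:
    """Sums-of-squares decomposition for one between x one within (2-level) design.

    ``table`` columns: subject_id, group, time, value; every subject must
    have exactly one value per time level. Returns all SS/df terms.
    """
    required = {"subject_id", "group", "time", "value"}
    if not required.issubset(table.columns):
        raise SpecError(f"mixed-design table needs columns {sorted(required)}")
    times = sorted(table["time"].unique())
    if len(times) != 2:
        raise SpecError(f"within factor must have exactly 2 levels, got {times}")
    counts = table.groupby(["subject_id", "time"], sort=True).size()
    per_subject = table.groupby("subject_id").size()
    if (counts != 1).any() or (per_subject != 2).any():
        bad = sorted(set(counts[counts != 1].index.get_level_values(0))
                     | set(per_subject[per_subject != 2].index))
        raise SpecError(f"subjects with missing/duplicated time level: {bad[:5]}")
    per_subj_groups = table.groupby("subject_id")["group"].nunique()
    if (per_subj_groups != 1).any():
        raise SpecError("each subject must belong to exactly one group")

    y = table["value"].to_numpy(float)
    grand = y.mean()
    n_sub = table["subject_id"].nunique()
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise SpecError(f"between factor must have exactly 2 levels, got {groups}")

    subj_mean = table.groupby("subject_id")["value"].mean()
    subj_group = table.groupby("subject_id")["group"].first()
    group_mean = table.groupby("group")["value"].mean()
    time_mean = table.groupby("time")["value"].mean()
    cell_mean = table.groupby(["group", "time"])["value"].mean()
    n_per_group = subj_group.value_counts()

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(2.0 * ((subj_mean - grand) ** 2).sum())
    ss_group = float(2.0 * sum(n_per_group[g] * (group_mean[g] - grand) ** 2 for g in groups))
    ss_subj_error = ss_between_subj - ss_group
    ss_within = ss_total - ss_between_subj
    ss_time = float(sum(n_sub * (time_mean[t] - grand) ** 2 for t in times))
    ss_inter = float(
        sum(
            n_per_group[g] * (cell_mean[(g, t)] - group_mean[g] - time_mean[t] + grand) ** 2
            for g in groups
            for t in times
        )
    )
    ss_time_error = ss_within - ss_time - ss_inter
    return dict(
        ss_total=ss_total,
        ss_group=ss_group,
        ss_subj_error=ss_subj_error,
        ss_time=ss_time,
        ss_interaction=ss_inter,
        ss_time_error=ss_time_error,
        df_group=1.0,
        df_subj_error=float(n_sub - 2),
        df_time=1.0,
        df_interaction=1.0,
        df_time_error=float(n_sub - 2),
    )


def mixed_anova_2x2(table: pd.DataFrame) -> list[StatResult]:
    """Group, Time, and Group x Time effects with partial eta squared."""
    ss = mixed_anova_ss(table)

    def _f(name, ss_eff, df_eff, ss_err, df_err):
        if ss_err == 0:
            if ss_eff == 0:
                return StatResult(name, 0.0, (df_eff, df_err), 1.0, effect_size=0.0,
                                  effect_size_kind="partial_eta_sq")
            raise DegenerateSignalError(f"zero error SS for {name}: F infinite")
        f = (ss_eff / df_eff) / (ss_err / df_err)
        p = float(sps.f.sf(f, df_eff, df_err))
        eta = ss_eff / (ss_eff + ss_err)
        return StatResult(name, float(f), (df_eff, df_err), p, effect_size=float(eta),
                          effect_size_kind="partial_eta_sq")

    return [
        _f("Group", ss["ss_group"], ss["df_group"], ss["ss_subj_error"], ss["df_subj_error"]),
        _f("Time", ss["ss_time"], ss["df_time"], ss["ss_time_error"], ss["df_time_error"]),
        _f("Group x Time", ss["ss_interaction"], ss["df_interaction"], ss["ss_time_error"],
           ss["df_time_error"]),
    ]


# ---------------------------------------------------------------------------


def pearson_r(x, y, name: str = "") -> StatResult:
    """Sample Pearson correlation, df = n - 2, two-tailed p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise EstimatorError("pearson_r needs matched samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateSignalError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return StatResult(name, float(r), float(x.size - 2), float(p), effect_size=float(r),
                      effect_size_kind="r")


def bonferroni(p_raw: float, m: int) -> float:
    """min(1, p * m)."""
    if not 0.0 <= p_raw <= 1.0:
        raise SpecError(f"p must be in [0, 1], got {p_raw}")
    if m < 1:
        raise SpecError(f"family size must be >= 1, got {m}")
    return min(1.0, p_raw * m)


# ---------------------------------------------------------------------------
# Tidy group-comparison driver


def compare_groups(
    data: pd.DataFrame,
    measures: list[str],
    design: str = "between",
    threshold_sd: float | None = 2.0,
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Exclusion -> test -> correction for each measure; tidy result table.

    ``design='between'`` expects columns group + measures (one row per
    subject) and runs pooled t-tests; ``design='mixed'`` expects
    subject_id, group, time + measures and runs the 2x2 mixed ANOVA
    (no exclusion is applied in the mixed design: dropping one time point
    would unbalance subjects). ``threshold_sd=None`` disables exclusion.
    The Bonferroni family size defaults to the number of measures; with
    m = 1 no corrected p is reported.
    """
    unknown = [m for m in measures if m not in data.columns]
    if unknown:
        known = [c for c in data.columns if c not in ("subject_id", "group", "time")]
        raise SpecError(f"unknown measures {unknown}; known measures: {known}")
    if design not in ("between", "mixed"):
        raise SpecError("design must be 'between' or 'mixed'")
    m_family = bonferroni_m if bonferroni_m is not None else len(measures)

    rows = []
    for measure in measures:
        if design == "between":
            groups = sorted(data["group"].unique())
            if len(groups) != 2:
                raise SpecError(f"between design needs exactly 2 groups, got {groups}")
            samples = []
            n_excluded = 0
            for g in groups:
                vals = data.loc[data["group"] == g, measure].to_numpy(float)
                keep = (
                    exclude_outliers(vals, threshold_sd)
                    if threshold_sd is not None
                    else np.isfinite(vals)
                )
                n_excluded += int((~keep).sum())
                samples.append(vals[keep])
            res = two_sample_t(samples[0], samples[1], name=f"{measure}: {groups[0]} vs {groups[1]}")
            results = [(f"{groups[0]} vs {groups[1]}", res, len(samples[0]) + len(samples[1]),
                        n_excluded)]
        else:
            table = data.rename(columns={measure: "value"})[
                ["subject_id", "group", "time", "value"]
            ]
            n_sub = table["subject_id"].nunique()
            results = [
                (r.name, r, n_sub, 0) for r in mixed_anova_2x2(table)
            ]
        for contrast, res, n_used, n_excluded in results:
            p_corr = bonferroni(res.p_raw, m_family) if m_family > 1 else None
            df = res.df if isinstance(res.df, float) else "x".join(str(v) for v in res.df)
            rows.append(
                dict(
                    measure=measure,
                    contrast=contrast,
                    statistic=res.statistic,
                    df=df,
                    p_raw=res.p_raw,
                    p_corrected=p_corr,
                    effect_size=res.effect_size,
                    effect_size_kind=res.effect_size_kind,
                    n_after_exclusion=n_used,
                    n_excluded=n_excluded,
                )
            )
    return pd.DataFrame(rows)
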