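"""Time-binned treatment-response statistics for APTW cohorts.

Scans are grouped into four clinical time bins (by onset time or by
post-treatment duration): up to 96 h, 4-7 days, 8-21 days, and 22 days or
later. Group comparisons follow common clinical-stats practice: one-way
ANOVA with the least-significant-difference (LSD) post hoc test against the
pre-treatment group, pooled-variance independent-samples t-tests, and
Pearson correlations. LSD pairwise p-values deliberately carry no
multiplicity adjustment — that is the definition of the procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CohortTable

__all__ = [
    "TimeBin",
    "TIME_BINS",
    "assign_time_bin",
    "StatResult",
    "pearson",
    "anova_lsd",
    "ttest_ind",
    "build_tables",
    "CohortReport",
]


@dataclass(frozen=True)
class TimeBin:
    """One clinical time bin: half-open/closed hour interval with a label."""

    label: str
    lo_h: float  # inclusive
    hi_h: float  # exclusive for the first bin edge rule below

    def __contains__(self, time_h: float) -> bool:
        return assign_time_bin(time_h).label == self.label


#: Bin edges in hours: [0, 96), [96, 168], (168, 504], (504, inf). A time
#: recorded as "4 days" (= 96 h) therefore falls in the 4-7 day bin, which
#: is the edge rule that reproduces the reference cohort's published
#: pre-treatment onset-bin sizes (30 and 13).
TIME_BINS: tuple[TimeBin, ...] = (
    TimeBin("<=96h", 0.0, 96.0),
    TimeBin("4-7d", 96.0, 168.0),
    TimeBin("8-21d", 168.0, 504.0),
    TimeBin(">=22d", 504.0, float("inf")),
)


def assign_time_bin(time_h: float) -> TimeBin:
    """Map a positive time in hours to its clinical bin (total partition)."""
    if not time_h > 0:
        raise ValueError(f"time must be positive, got {time_h}")
    if time_h < 96.0:
        return TIME_BINS[0]
    if time_h <= 168.0:
        return TIME_BINS[1]
    if time_h <= 504.0:
        return TIME_BINS[2]
    return TIME_BINS[3]


@dataclass
class StatResult:
    """A test statistic with its p-value and bookkeeping."""

    statistic: float
    p_value: float
    df: float
    group_ns: tuple[int, ...]
    pairwise: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def pearson(x, y) -> StatResult:
    """Pearson product-moment correlation with a two-sided t-transform p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(x.size - 2),
        group_ns=(int(x.size),),
    )


def ttest_ind(a, b, equal_var: bool = True) -> StatResult:
    """Independent-samples t-test (pooled-variance form by default)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            df = a.size + b.size - 2
            return StatResult(statistic=0.0, p_value=1.0, df=float(df), group_ns=(a.size, b.size))
        raise ValueError("zero variance with unequal means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(df),
        group_ns=(int(a.size), int(b.size)),
    )


def anova_lsd(
    groups: list[np.ndarray] | dict[str, np.ndarray],
) -> StatResult:
    """One-way ANOVA with LSD (Fisher's least significant difference) post hoc.

    Groups with fewer than two observations are reported in ``group_ns`` but
    excluded from the F test and the pairwise table. Pairwise comparisons
    use the pooled within-group mean square with ``N - k`` degrees of
    freedom and are two-sided with no multiplicity adjustment.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        data = [np.asarray(g, float) for g in groups.values()]
    else:
        labels = [str(i) for i in range(len(groups))]
        data = [np.asarray(g, float) for g in groups]
    ns_all = tuple(int(g.size) for g in data)
    keep = [i for i, g in enumerate(data) if g.size >= 2]
    if len(keep) < 2:
        raise ValueError("need at least two groups with n >= 2")
    kd = [data[i] for i in keep]
    kl = [labels[i] for i in keep]
    allv = np.concatenate(kd)
    if np.all(allv == allv[0]):
        raise ValueError("all observations identical: F undefined")

    k = len(kd)
    N = allv.size
    grand = allv.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in kd)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in kd)
    df_b, df_w = k - 1, N - k
    mse = ss_within / df_w
    F = (ss_between / df_b) / mse
    p = float(sps.f.sf(F, df_b, df_w))

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = kd[i], kd[j]
            se = np.sqrt(mse * (1.0 / gi.size + 1.0 / gj.size))
            t = (gi.mean() - gj.mean()) / se
            rows.append(
                {
                    "group_a": kl[i],
                    "group_b": kl[j],
                    "mean_diff": float(gi.mean() - gj.mean()),
                    "t": float(t),
                    "df": df_w,
                    "p_value": float(2.0 * sps.t.sf(abs(t), df_w)),
                }
            )
    return StatResult(
        statistic=float(F),
        p_value=p,
        df=float(df_w),
        group_ns=ns_all,
        pairwise=pd.DataFrame(rows),
    )


_MEASURES = {
    "lesion": "lesion_aptw_pct",
    "cnawm": "cnawm_aptw_pct",
    "contrast": "contrast_pct",
    "nihss": "nihss",
}


@dataclass
class CohortReport:
    """The three statistical surfaces of a cohort analysis."""

    by_treatment_time: pd.DataFrame
    by_onset_time: pd.DataFrame
    correlations: pd.DataFrame


def _group_row(measure: str, label: str, values: np.ndarray) -> dict:
    return {
        "measure": measure,
        "group": label,
        "n": int(values.size),
        "mean": float(values.mean()) if values.size else np.nan,
        "sd": float(values.std(ddof=1)) if values.size > 1 else np.nan,
    }


def build_tables(cohort: CohortTable) -> CohortReport:
    """Pre/post group comparisons and time correlations for one cohort.

    Post-treatment scans of patients whose treatment was ineffective are
    excluded from all group statistics; their pre-treatment baselines remain
    in the pre-treatment group. Three surfaces are produced:

    * ``by_treatment_time``: pre-treatment group vs post-treatment groups
      binned by post-treatment duration; per measure, group mean/SD/n, the
      one-way ANOVA across groups and the LSD p-value of each post group
      against pre-treatment.
    * ``by_onset_time``: scans binned by time since onset; per bin and
      measure, pre vs post pooled-variance t-test where both groups exist.
    * ``correlations``: Pearson r of each APTW measure against onset time
      (pre-treatment scans), against post-treatment duration and against
      onset time (post-treatment scans), plus each baseline APTW measure
      against NIHSS at arrival.
    """
    df = cohort.df
    pre = df[df["post_treatment_time_h"].isna()]
    post = df[df["post_treatment_time_h"].notna() & (df["effective"].fillna(True))]

    rows = []
    for measure, col in _MEASURES.items():
        groups: dict[str, np.ndarray] = {"pre": pre[col].dropna().to_numpy()}
        for b in TIME_BINS:
            sel = post[post["post_treatment_time_h"].map(lambda h: assign_time_bin(h).label) == b.label]
            groups[b.label] = sel[col].dropna().to_numpy()
        testable = {k: v for k, v in groups.items() if v.size >= 2}
        res = anova_lsd(testable) if len(testable) >= 2 else None
        for label, vals in groups.items():
            row = _group_row(measure, label, vals)
            row["anova_F"] = res.statistic if res else np.nan
            row["anova_p"] = res.p_value if res else np.nan
            row["p_vs_pre"] = np.nan
            if res is not None and label != "pre" and vals.size >= 2 and "pre" in testable:
                pw = res.pairwise
                hit = pw[
                    ((pw["group_a"] == "pre") & (pw["group_b"] == label))
                    | ((pw["group_b"] == "pre") & (pw["group_a"] == label))
                ]
                if len(hit):
                    row["p_vs_pre"] = float(hit["p_value"].iloc[0])
            rows.append(row)
    by_treatment = pd.DataFrame(rows)

    rows = []
    for b in TIME_BINS:
        in_bin = df["onset_time_h"].map(lambda h: assign_time_bin(h).label) == b.label
        pre_b = df[in_bin & df["post_treatment_time_h"].isna()]
        post_b = df[in_bin & df["post_treatment_time_h"].notna() & df["effective"].fillna(True)]
        for measure, col in _MEASURES.items():
            a = pre_b[col].dropna().to_numpy()
            c = post_b[col].dropna().to_numpy()
            row = {
                "onset_bin": b.label,
                "measure": measure,
                "n_pre": int(a.size),
                "mean_pre": float(a.mean()) if a.size else np.nan,
                "sd_pre": float(a.std(ddof=1)) if a.size > 1 else np.nan,
                "n_post": int(c.size),
                "mean_post": float(c.mean()) if c.size else np.nan,
                "sd_post": float(c.std(ddof=1)) if c.size > 1 else np.nan,
                "t": np.nan,
                "p_value": np.nan,
            }
            if a.size >= 2 and c.size >= 2:
                res = ttest_ind(a, c)
                row["t"] = res.statistic
                row["p_value"] = res.p_value
            rows.append(row)
    by_onset = pd.DataFrame(rows)

    rows = []
    aptw_measures = {k: v for k, v in _MEASURES.items() if k != "nihss"}

    def corr_rows(sub: pd.DataFrame, xcol: str, analysis: str) -> None:
        for measure, col in aptw_measures.items():
            x = sub[xcol].dropna()
            y = sub[col].loc[x.index].dropna()
            x = x.loc[y.index]
            if x.size >= 3 and np.std(x) > 0 and np.std(y) > 0:
                res = pearson(x, y)
                rows.append(
                    {
                        "analysis": analysis,
                        "measure": measure,
                        "n": int(x.size),
                        "r": res.statistic,
                        "p_value": res.p_value,
                    }
                )

    corr_rows(pre, "onset_time_h", "pre_vs_onset_time")
    corr_rows(post, "post_treatment_time_h", "post_vs_treatment_time")
    corr_rows(post, "onset_time_h", "post_vs_onset_time")
    corr_rows(pre, "nihss", "baseline_vs_nihss")
    correlations = pd.DataFrame(rows)

    return CohortReport(
        by_treatment_time=by_treatment,
        by_onset_time=by_onset,
        correlations=correlations,
    )
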