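"""Cohort-level comparison of TMB across groups and filtering criteria.

This layer reproduces the comparison design of the analysis: per-group mean
and standard error of TMB under each criterion, pooled-variance two-sample
t-tests between groups, a two-way ANOVA with the group x criterion
interaction (TMB ~ group + criterion + group:criterion), Pearson
correlations of per-patient TMB across criteria, and TMB-high
classification at the clinically used threshold of 10 mutations/Mb.

The interaction is tested by comparing the full model against the additive
model, which is the interaction term's test under any sums-of-squares type
when the interaction enters last — well defined for unbalanced group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tmb_calculator import TMBRecord
from .variant_core import DataError


def records_to_frame(records: Iterable[TMBRecord]) -> pd.DataFrame:
    """Long-format DataFrame of TMB records."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "group": r.group,
                "region": r.region,
                "criterion": r.criterion,
                "counted_mutations": r.counted_mutations,
                "tmb": r.tmb,
            }
            for r in records
        ]
    )


def summarize_groups(records: Iterable[TMBRecord] | pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of TMB per (group, criterion, region).

    The standard error is sd/sqrt(n) with the sample (n-1) standard
    deviation; a single-patient cell reports a missing SE.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise DataError("no TMB records to summarize")
    out = (
        df.groupby(["region", "criterion", "group"], sort=True)["tmb"]
        .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def table1_layout(summary: pd.DataFrame, region: str,
                  criteria_order: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Render a group-by-criterion 'mean (se)' table for one region."""
    sub = summary[summary["region"] == region]
    cells = sub.assign(
        cell=[f"{m:.3f} ({s:.3f})" if np.isfinite(s) else f"{m:.3f} (NA)"
              for m, s in zip(sub["mean"], sub["se"])]
    ).pivot(index="criterion", columns="group", values="cell")
    if criteria_order is not None:
        cells = cells.reindex([c for c in criteria_order if c in cells.index])
    return cells


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def student_t_test(a: Sequence[float], b: Sequence[float],
                   welch: bool = False) -> TTestResult:
    """Two-sample t-test; pooled-variance Student form by default.

    The Welch form is exposed but off by default. Degenerate input (zero
    pooled variance) yields t = 0, p = 1 when means agree and raises
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each sample needs at least 2 observations")
    if not welch:
        sp2 = (np.var(a, ddof=1) * (a.size - 1) + np.var(b, ddof=1) * (b.size - 1))
        sp2 /= a.size + b.size - 2
        if sp2 == 0.0:
            if np.mean(a) == np.mean(b):
                return TTestResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
            raise DataError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


@dataclass(frozen=True)
class AnovaInteractionResult:
    f: float
    df_num: int
    df_den: int
    p: float
    #: sequential sums of squares: group, criterion, interaction, residual
    ss_table: pd.DataFrame = field(repr=False)


def interaction_anova(long_table: pd.DataFrame,
                      group_col: str = "group",
                      criterion_col: str = "criterion",
                      value_col: str = "tmb") -> AnovaInteractionResult:
    """F-test of the group:criterion interaction on a long TMB table.

    Fits tmb ~ C(group) + C(criterion) and the model with the interaction
    added, and reports the nested-model comparison F. Requires >= 2 levels
    per factor, every cell non-empty, and residual degrees of freedom >= 1.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = long_table[[group_col, criterion_col, value_col]].rename(
        columns={group_col: "group", criterion_col: "criterion",
                 value_col: "tmb"}
    ).copy()
    g_levels = df["group"].nunique()
    c_levels = df["criterion"].nunique()
    if g_levels < 2 or c_levels < 2:
        raise DataError("need >= 2 levels of group and criterion")
    cell_n = df.groupby(["group", "criterion"]).size()
    full_grid = g_levels * c_levels
    if len(cell_n) < full_grid:
        seen = set(cell_n.index)
        missing = [
            (g, c)
            for g in df["group"].unique()
            for c in df["criterion"].unique()
            if (g, c) not in seen
        ]
        raise DataError(f"empty design cells: {missing}")

    additive = smf.ols("tmb ~ C(group) + C(criterion)", data=df).fit()
    full = smf.ols("tmb ~ C(group) * C(criterion)", data=df).fit()
    if full.df_resid < 1:
        raise DataError("residual degrees of freedom < 1")
    f_stat, p_val, df_num = full.compare_f_test(additive)

    seq = anova_lm(full, typ=1)
    ss = pd.DataFrame(
        {
            "ss": [
                seq.loc["C(group)", "sum_sq"],
                seq.loc["C(criterion)", "sum_sq"],
                seq.loc["C(group):C(criterion)", "sum_sq"],
                seq.loc["Residual", "sum_sq"],
            ],
            "df": [
                seq.loc["C(group)", "df"],
                seq.loc["C(criterion)", "df"],
                seq.loc["C(group):C(criterion)", "df"],
                seq.loc["Residual", "df"],
            ],
        },
        index=["group", "criterion", "interaction", "residual"],
    )
    return AnovaInteractionResult(
        f=float(f_stat),
        df_num=int(round(df_num)),
        df_den=int(round(full.df_resid)),
        p=float(p_val),
        ss_table=ss,
    )


def tmb_wide(records: Iterable[TMBRecord] | pd.DataFrame,
             region: str) -> pd.DataFrame:
    """Per-patient wide table (one column per criterion) for one region."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    sub = df[df["region"] == region]
    return sub.pivot(index="patient_id", columns="criterion", values="tmb")


def correlation_matrix(wide_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of per-patient TMB across criteria.

    Symmetric with unit diagonal; a zero-variance column yields missing
    entries. Requires at least 3 patients.
    """
    if len(wide_table) < 3:
        raise DataError("need >= 3 patients for correlations")
    corr = wide_table.corr(method="pearson")
    zero_var = wide_table.std(ddof=1) == 0
    for col in wide_table.columns[zero_var]:
        corr.loc[col, :] = np.nan
        corr.loc[:, col] = np.nan
    for col in corr.columns[~zero_var]:
        corr.loc[col, col] = 1.0
    return corr


@dataclass(frozen=True)
class TMBHighResult:
    """TMB-high counts per (group, criterion) and tumor-only discordance.

    ``counts`` has one row per (region, group, criterion) with the number of
    patients at or above threshold; ``discordant`` counts patients called
    TMB-high under a database criterion but not under the paired-germline
    criterion — the patients who would be inappropriately selected for
    checkpoint-inhibitor therapy by tumor-only filtering.
    """

    threshold: float
    counts: pd.DataFrame = field(repr=False)
    discordant: pd.DataFrame = field(repr=False)


def classify_tmb_high(records: Iterable[TMBRecord] | pd.DataFrame,
                      threshold: float = 10.0,
                      germline_label: str = "TMB_Germline") -> TMBHighResult:
    """Classify patients as TMB-high (tmb >= threshold, inclusive).

    Discordance is computed per patient against the paired-germline
    criterion whenever that criterion is present for the patient/region.
    """
    if threshold <= 0:
        raise DataError("threshold must be > 0")
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.copy()
    df["tmb_high"] = df["tmb"] >= threshold

    counts = (
        df.groupby(["region", "group", "criterion"], sort=True)["tmb_high"]
        .agg(n_patients="size", n_tmb_high="sum")
        .reset_index()
    )

    germ = df[df["criterion"] == germline_label][
        ["region", "patient_id", "tmb_high"]
    ].rename(columns={"tmb_high": "germline_high"})
    dbpart = df[df["criterion"] != germline_label].merge(
        germ, on=["region", "patient_id"], how="inner"
    )
    dbpart["discordant"] = dbpart["tmb_high"] & ~dbpart["germline_high"]
    discordant = (
        dbpart.groupby(["region", "group", "criterion"], sort=True)["discordant"]
        .sum()
        .reset_index(name="n_discordant")
    )
    return TMBHighResult(threshold=threshold, counts=counts,
                         discordant=discordant)
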