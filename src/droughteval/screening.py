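"""Screening statistics: two-group tests, one-way ANOVA, correlation matrix.

These reproduce the descriptive layer of a genotype x stress-stage trial:
per-stage two-sample comparisons between genotypes (with significance-star
bands), across-stage one-way ANOVA per indicator, and the all-pairs Pearson
correlation matrix across the stage-mean samples.

No multiple-testing correction is applied by default; Benjamini-Hochberg
adjusted p-values are available via :func:`adjust_pvalues`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import IndicatorTable, SampleMatrix
from .errors import DegenerateDataError

__all__ = [
    "DEFAULT_STAR_BANDS",
    "stars",
    "GroupComparison",
    "two_sample_t",
    "one_way_anova",
    "CorrelationMatrix",
    "pearson_matrix",
    "compare_genotypes_by_stage",
    "anova_across_stages",
    "adjust_pvalues",
]

#: (p threshold, label) pairs, most stringent first.
DEFAULT_STAR_BANDS: tuple[tuple[float, str], ...] = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


def stars(p: float, bands=DEFAULT_STAR_BANDS) -> str:
    """Significance label for a p-value; 'ns' above the loosest band."""
    for threshold, label in sorted(bands):
        if p < threshold:
            return label
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    indicator: str
    stage: str
    statistic: float
    df: float
    p: float
    stars: str
    infinite_t: bool = False


def two_sample_t(
    group_a,
    group_b,
    variant: str = "student",
    indicator: str = "",
    stage: str = "",
    bands=DEFAULT_STAR_BANDS,
) -> GroupComparison:
    """Two-sided two-sample t test.

    ``student`` pools variances (df = nA + nB - 2); ``welch`` uses the
    Welch-Satterthwaite approximation.  Degenerate inputs follow an explicit
    contract: zero variance with equal means gives t = 0, p = 1; zero
    variance with unequal means is flagged infinite-t (p = 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("each group needs >= 2 finite values")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant: {variant}")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0.0 and var_b == 0.0:
        if a.mean() == b.mean():
            df = float(a.size + b.size - 2)
            return GroupComparison(indicator, stage, 0.0, df, 1.0, stars(1.0, bands))
        t_inf = math.copysign(math.inf, a.mean() - b.mean())
        df = float(a.size + b.size - 2)
        return GroupComparison(indicator, stage, t_inf, df, 0.0, stars(0.0, bands), True)
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    df = float(a.size + b.size - 2) if variant == "student" else float(res.df)
    return GroupComparison(
        indicator, stage, float(res.statistic), df, float(res.pvalue), stars(float(res.pvalue), bands)
    )


def one_way_anova(groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA; returns (F, df_between, df_within, p).

    All-identical data (zero between- and within-group variance) returns
    F = 0, p = 1 by contract rather than NaN.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n = sum(a.size for a in arrays)
    df_between, df_within = len(arrays) - 1, n - len(arrays)
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0.0:
        return 0.0, df_between, df_within, 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), df_between, df_within, float(p)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r and two-sided p over indicator columns.

    Entries involving a constant column are NaN and flagged in ``undefined``
    rather than silently zeroed.
    """

    labels: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    undefined: list[str]


def pearson_matrix(m: SampleMatrix | pd.DataFrame) -> CorrelationMatrix:
    """All-pairs Pearson correlation over the sample rows.

    p-values come from the t transform t = r * sqrt((n-2)/(1-r^2)) with
    n - 2 degrees of freedom.
    """
    df = m.df if isinstance(m, SampleMatrix) else m
    n = df.shape[0]
    if n < 3:
        raise DegenerateDataError("need >= 3 samples for a correlation matrix")
    labels = list(df.columns)
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    constant = [labels[j] for j in np.flatnonzero(sd == 0.0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    for j, lab in enumerate(labels):
        if lab in constant:
            r[j, :] = np.nan
            r[:, j] = np.nan
    np.fill_diagonal(r, np.where(np.isin(labels, constant), np.nan, 1.0))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.isinf(t), 0.0, p))
    np.fill_diagonal(p, np.where(np.isin(labels, constant), np.nan, 0.0))
    return CorrelationMatrix(
        labels,
        pd.DataFrame(r, index=labels, columns=labels),
        pd.DataFrame(p, index=labels, columns=labels),
        constant,
    )


def compare_genotypes_by_stage(
    table: IndicatorTable,
    variant: str = "student",
    bands=DEFAULT_STAR_BANDS,
) -> pd.DataFrame:
    """Per (indicator, stage) two-sample t test between the two genotypes."""
    genotypes = table.genotypes
    if len(genotypes) != 2:
        raise ValueError(f"stage comparison needs exactly 2 genotypes, got {genotypes}")
    g1, g2 = genotypes
    rows = []
    for code in table.indicator_order:
        sub = table.df[table.df["indicator"] == code]
        for stage in table.stage_order:
            a = sub[(sub["stage"] == stage) & (sub["genotype"] == g1)]["value"].to_numpy()
            b = sub[(sub["stage"] == stage) & (sub["genotype"] == g2)]["value"].to_numpy()
            if a.size < 2 or b.size < 2:
                continue
            cmp_ = two_sample_t(a, b, variant=variant, indicator=code, stage=stage, bands=bands)
            rows.append(
                {
                    "indicator": code,
                    "stage": stage,
                    "t": cmp_.statistic,
                    "df": cmp_.df,
                    "p": cmp_.p,
                    "stars": cmp_.stars,
                }
            )
    return pd.DataFrame(rows)


def anova_across_stages(table: IndicatorTable) -> pd.DataFrame:
    """Per (genotype, indicator) one-way ANOVA across the stress stages."""
    rows = []
    for g in table.genotypes:
        for code in table.indicator_order:
            sub = table.df[(table.df["genotype"] == g) & (table.df["indicator"] == code)]
            groups = [
                sub[sub["stage"] == s]["value"].to_numpy() for s in table.stage_order
            ]
            groups = [grp for grp in groups if grp.size >= 2]
            if len(groups) < 2:
                continue
            f, dfb, dfw, p = one_way_anova(groups)
            rows.append(
                {
                    "genotype": g,
                    "indicator": code,
                    "F": f,
                    "df_between": dfb,
                    "df_within": dfw,
                    "p": p,
                    "stars": stars(p),
                }
            )
    return pd.DataFrame(rows)


def adjust_pvalues(p, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjusted p-values (Benjamini-Hochberg by default)."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method=method)[1]
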