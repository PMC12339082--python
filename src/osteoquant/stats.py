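"""Cohort-level comparison statistics.

The study design compares wild-type and mutant groups per measure, pooling
sexes: normality is gated per group with Shapiro-Wilk at alpha = 0.05; both
groups normal → unpaired two-sided Student's t-test, otherwise two-sided
Mann-Whitney.  Mineral-content measures additionally get a two-way factorial
analysis (site × genotype, type-II sums of squares for unbalanced cohorts)
with Tukey HSD post-hoc comparisons.  No multiple-testing adjustment is
applied across measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateSampleError, DesignError, SampleSizeError

GENOTYPES = ("WT", "MUT")
SEXES = ("M", "F")
AGE_GROUPS = ("8W", "15W")


@dataclass
class CohortTable:
    """Long-format per-sample measurement table.

    Columns: sample_id, genotype, sex, age_group, site, measure, value.
    """

    df: pd.DataFrame

    REQUIRED = ("sample_id", "genotype", "sex", "age_group", "site", "measure", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"CohortTable missing columns: {missing}")
        keys = self.df[["sample_id", "site", "measure"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (sample_id, site, measure) key: {dup}")
        if not np.isfinite(self.df["value"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite values in cohort table")

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def values(self, measure: str, genotype: str, site: str | None = None) -> np.ndarray:
        sel = (self.df["measure"] == measure) & (self.df["genotype"] == genotype)
        if site is not None:
            sel &= self.df["site"] == site
        return self.df.loc[sel, "value"].to_numpy(dtype=float)


@dataclass(frozen=True)
class GroupComparison:
    test_name: str  # "t-test" or "mann-whitney"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    percent_difference: float | None  # 100*(mean_b - mean_a)/mean_a


@dataclass
class AnovaTukeyResult:
    anova_table: pd.DataFrame  # type-II SS table with p-values per term
    factor_p_values: dict[str, float]
    tukey: pd.DataFrame  # pairwise comparisons with adjusted p-values
    family: str  # "site" or "cells"


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value (Royston approximation, via scipy)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise SampleSizeError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample has no defined W statistic")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def percent_difference(mean_a: float, mean_b: float) -> float:
    """Percent change of b relative to baseline a: 100*(b - a)/a."""
    if mean_a == 0:
        raise ZeroDivisionError("baseline mean is zero")
    return 100.0 * (mean_b - mean_a) / mean_a


def compare_two_groups(a, b, alpha: float = 0.05) -> GroupComparison:
    """Normality-gated two-group comparison.

    Shapiro-Wilk per group at ``alpha``; both pass → unpaired two-sided
    Student's t-test (equal variances), either fails → two-sided
    Mann-Whitney U (exact null distribution when min(n) <= 8 and no ties,
    normal approximation with tie correction otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise SampleSizeError("each group needs at least 3 observations")

    def _normal(x) -> bool:
        try:
            return shapiro_wilk(x)[1] >= alpha
        except DegenerateSampleError:
            return False

    identical = a.size == b.size and np.array_equal(np.sort(a), np.sort(b))
    if _normal(a) and _normal(b):
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        if identical:
            stat, p = 0.0, 1.0  # guard: scipy returns nan for zero pooled variance
        name = "t-test"
    else:
        combined = np.concatenate([a, b])
        has_ties = np.unique(combined).size < combined.size
        method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        name = "mann-whitney"
    mean_a, mean_b = float(a.mean()), float(b.mean())
    pct = percent_difference(mean_a, mean_b) if mean_a != 0 else None
    return GroupComparison(
        test_name=name,
        statistic=float(stat),
        p_value=float(np.clip(p, 0.0, 1.0)),
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=mean_a,
        mean_b=mean_b,
        percent_difference=pct,
    )


def two_way_anova_tukey(
    table: CohortTable,
    measure: str,
    factors: tuple[str, str] = ("site", "genotype"),
    tukey_family: str = "site",
    alpha: float = 0.05,
) -> AnovaTukeyResult:
    """Two-way factorial analysis with Tukey HSD post-hoc comparisons.

    Type-II sums of squares accommodate the unbalanced cohorts.  The Tukey
    family is the levels of ``tukey_family='site'`` by default, or every
    site×genotype cell with ``tukey_family='cells'``.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols as sm_ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    fa, fb = factors
    df = table.df[table.df["measure"] == measure].copy()
    if df.empty:
        raise DesignError(f"no rows for measure '{measure}'")
    for fac in factors:
        if df[fac].nunique() < 2:
            raise DesignError(f"factor '{fac}' needs at least 2 levels for '{measure}'")
    cell_counts = df.groupby([fa, fb], observed=True).size()
    for levels in (
        (la, lb) for la in df[fa].unique() for lb in df[fb].unique()
    ):
        if cell_counts.get(levels, 0) < 2:
            raise DesignError(f"cell {dict(zip(factors, levels))} has fewer than 2 observations")

    model = sm_ols(f"value ~ C({fa}) * C({fb})", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    p_values = {
        fa: float(anova.loc[f"C({fa})", "PR(>F)"]),
        fb: float(anova.loc[f"C({fb})", "PR(>F)"]),
        f"{fa}:{fb}": float(anova.loc[f"C({fa}):C({fb})", "PR(>F)"]),
    }

    if tukey_family == "site":
        groups = df[fa].astype(str)
    elif tukey_family == "cells":
        groups = df[fa].astype(str) + "/" + df[fb].astype(str)
    else:
        raise ValueError("tukey_family must be 'site' or 'cells'")
    hsd = pairwise_tukeyhsd(df["value"].to_numpy(float), groups.to_numpy(), alpha=alpha)
    tukey_df = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    return AnovaTukeyResult(
        anova_table=anova, factor_p_values=p_values, tukey=tukey_df, family=tukey_family
    )
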