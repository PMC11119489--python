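"""Cohort statistics: Welch tests, ANOVA with Bonferroni, effect sizes.

Two-group comparisons (cell-level morphometrics, pooled vesicle features)
use the unpaired t-test with Welch's correction; multi-parameter panels use
one-way ANOVA with Bonferroni-adjusted pairwise comparisons.  Effect sizes
are eta-squared (the squared correlation ratio: between-class sum of squares
over total).  Significance stars follow the reporting convention
* p<0.05, ** p<0.01, *** p<0.001, dagger p<0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "significance_stars",
    "welch_t_test",
    "anova_bonferroni",
    "eta_squared",
    "pooled_bin_fractions",
    "compare_feature_table",
]


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "†"  # dagger
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ComparisonResult:
    feature: str
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    statistic: float
    df: float
    p_value: float
    stars: str = ""
    eta_squared: float | None = None
    degenerate: bool = False
    test: str = "welch_t"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")
        if not self.stars:
            self.stars = significance_stars(self.p_value)


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float],
                 feature: str = "") -> ComparisonResult:
    """Two-sided unpaired t-test with Welch's correction (Satterthwaite df)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    degenerate = va == 0.0 and vb == 0.0
    if degenerate:
        equal = a.mean() == b.mean()
        t, p, dof = (0.0, 1.0, float(len(a) + len(b) - 2)) if equal else (np.inf, 0.0, float(len(a) + len(b) - 2))
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        t, p, dof = float(res.statistic), float(res.pvalue), float(res.df)
    return ComparisonResult(
        feature=feature,
        group_means=(float(a.mean()), float(b.mean())),
        group_sds=(float(np.sqrt(va)), float(np.sqrt(vb))),
        statistic=t,
        df=dof,
        p_value=p,
        degenerate=degenerate,
    )


def anova_bonferroni(
    groups: Sequence[Sequence[float]],
    n_comparisons: int | None = None,
    names: Sequence[str] | None = None,
) -> list[ComparisonResult]:
    """One-way ANOVA plus Bonferroni-adjusted pairwise comparisons.

    Element 0 of the returned list is the omnibus F test; subsequent elements
    are pairwise two-sided t-tests whose p-values are multiplied by
    ``n_comparisons`` (default: the number of pairs) and capped at 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    names = list(names) if names is not None else [f"group{i}" for i in range(len(gs))]
    pairs = list(combinations(range(len(gs)), 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)

    allv = np.concatenate(gs)
    if allv.var(ddof=0) == 0.0:
        f_stat, f_p, degen = 0.0, 1.0, True
    else:
        f_stat, f_p = sps.f_oneway(*gs)
        degen = False
    k, n = len(gs), len(allv)
    results = [
        ComparisonResult(
            feature="omnibus",
            group_means=tuple(float(g.mean()) for g in gs),
            group_sds=tuple(float(g.std(ddof=1)) for g in gs),
            statistic=float(f_stat),
            df=float(n - k),
            p_value=float(f_p),
            degenerate=degen,
            test="anova_F",
        )
    ]
    for i, j in pairs:
        if gs[i].var(ddof=1) == 0.0 and gs[j].var(ddof=1) == 0.0:
            equal = gs[i].mean() == gs[j].mean()
            t, p = (0.0, 1.0) if equal else (np.inf, 0.0)
            dof = float(len(gs[i]) + len(gs[j]) - 2)
        else:
            res = sps.ttest_ind(gs[i], gs[j], equal_var=True)
            t, p, dof = float(res.statistic), float(res.pvalue), float(len(gs[i]) + len(gs[j]) - 2)
        results.append(
            ComparisonResult(
                feature=f"{names[i]} vs {names[j]}",
                group_means=(float(gs[i].mean()), float(gs[j].mean())),
                group_sds=(float(gs[i].std(ddof=1)), float(gs[j].std(ddof=1))),
                statistic=t,
                df=dof,
                p_value=min(1.0, p * m),
                test="t_bonferroni",
            )
        )
    return results


def eta_squared(values: Sequence[float], class_labels: Sequence) -> float:
    """Squared correlation ratio: between-class SS over total SS."""
    x = np.asarray(values, dtype=float)
    labels = np.asarray(class_labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    grand = x.mean()
    ss_total = float(np.sum((x - grand) ** 2))
    if ss_total == 0.0:
        raise ValueError("zero total variance: eta-squared undefined")
    ss_between = float(
        sum(np.sum(labels == c) * (x[labels == c].mean() - grand) ** 2 for c in classes)
    )
    return ss_between / ss_total


def pooled_bin_fractions(diameters: Sequence[float], bin_edges: Sequence[float]) -> np.ndarray:
    """Histogram proportions over the given edges (normalised to sum 1)."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter pool")
    counts, _ = np.histogram(d, bins=np.asarray(bin_edges, dtype=float))
    total = counts.sum()
    if total == 0:
        raise ValueError("no diameters fall inside the bins")
    return counts / total


def compare_feature_table(
    table: pd.DataFrame,
    features: Sequence[str],
    class_column: str = "cell_class",
    with_eta: bool = True,
) -> pd.DataFrame:
    """Welch comparisons (and eta-squared) for each feature across 2 classes.

    Mirrors the cohort summary-table layout: one row per feature with group
    mean +- sd, Welch statistic, p-value, stars and effect size.
    """
    classes = sorted(table[class_column].dropna().unique())
    if len(classes) != 2:
        raise ValueError("compare_feature_table expects exactly two classes")
    rows = []
    for feat in features:
        a = table.loc[table[class_column] == classes[0], feat].to_numpy()
        b = table.loc[table[class_column] == classes[1], feat].to_numpy()
        res = welch_t_test(a, b, feature=feat)
        row = {
            "feature": feat,
            f"{classes[0]}_mean": res.group_means[0],
            f"{classes[0]}_sd": res.group_sds[0],
            f"{classes[1]}_mean": res.group_means[1],
            f"{classes[1]}_sd": res.group_sds[1],
            "t": res.statistic,
            "df": res.df,
            "p": res.p_value,
            "stars": res.stars,
        }
        if with_eta:
            row["eta_squared"] = eta_squared(
                table[feat].to_numpy(), table[class_column].to_numpy()
            )
        rows.append(row)
    return pd.DataFrame(rows)
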