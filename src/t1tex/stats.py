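"""Group-comparison statistics and power arithmetic.

Per continuous variable: Shapiro-Wilk normality in each group; if both
groups look normal, a Welch two-sample t-test with mean (SD) summaries,
otherwise a Wilcoxon rank-sum test with median (IQR) summaries.
Categorical variables use the chi-square test of independence.  P-values
are adjusted across the table by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestIndPower


@dataclass
class GroupComparisonRow:
    variable: str
    summary_a: str
    summary_b: str
    test: str  # "welch_t" | "wilcoxon_ranksum" | "chi_square"
    normal: bool | None
    p: float
    p_adjusted: float = np.nan


@dataclass
class PowerSpec:
    cohens_d: float = 0.9
    power: float = 0.8
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.power < 1 and 0 < self.alpha < 1):
            raise ValueError("power and alpha must lie in (0, 1)")


def _mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.3g} ({np.std(x, ddof=1):.3g})"


def _median_iqr(x: np.ndarray) -> str:
    q1, q3 = np.percentile(x, [25, 75])
    return f"{np.median(x):.3g} ({q1:.3g}, {q3:.3g})"


def compare_groups(
    table: pd.DataFrame,
    group_column: str,
    alpha_normality: float = 0.05,
) -> list[GroupComparisonRow]:
    """Compare every non-group column between the two groups."""
    groups = sorted(table[group_column].unique(), key=str)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ga = table[table[group_column] == groups[0]]
    gb = table[table[group_column] == groups[1]]
    rows: list[GroupComparisonRow] = []
    for col in table.columns:
        if col == group_column:
            continue
        a, b = ga[col].dropna(), gb[col].dropna()
        if pd.api.types.is_numeric_dtype(table[col]) and table[col].nunique() > 2:
            if min(len(a), len(b)) < 3:
                warnings.warn(f"variable {col!r} skipped: a group has < 3 observations")
                continue
            xa, xb = a.to_numpy(float), b.to_numpy(float)
            normal = (
                stats.shapiro(xa).pvalue > alpha_normality
                and stats.shapiro(xb).pvalue > alpha_normality
            )
            if normal:
                p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
                rows.append(
                    GroupComparisonRow(col, _mean_sd(xa), _mean_sd(xb), "welch_t", True, p)
                )
            else:
                if np.array_equal(np.sort(xa), np.sort(xb)):
                    p = 1.0  # identical samples: rank test is degenerate
                else:
                    p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
                rows.append(
                    GroupComparisonRow(
                        col, _median_iqr(xa), _median_iqr(xb), "wilcoxon_ranksum", False, p
                    )
                )
        else:
            ct = pd.crosstab(table[group_column], table[col])
            p = float(stats.chi2_contingency(ct).pvalue)
            rows.append(
                GroupComparisonRow(
                    col,
                    "/".join(str(v) for v in ct.iloc[0]),
                    "/".join(str(v) for v in ct.iloc[1]),
                    "chi_square",
                    None,
                    p,
                )
            )
    if rows:
        adj = multipletests([r.p for r in rows], method="fdr_bh")[1]
        for r, pa in zip(rows, adj):
            r.p_adjusted = float(pa)
    return rows


def comparison_table(rows: list[GroupComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "group_a": r.summary_a,
                "group_b": r.summary_b,
                "test": r.test,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
            }
            for r in rows
        ]
    ).set_index("variable")


def required_sample_size(spec: PowerSpec, max_n: int = 10**6) -> int:
    """Smallest per-group n for a two-sided two-sample t-test at the spec."""
    if spec.cohens_d == 0:
        raise ValueError("effect size 0: target power unachievable")
    n = TTestIndPower().solve_power(
        effect_size=abs(spec.cohens_d),
        alpha=spec.alpha,
        power=spec.power,
        alternative="two-sided",
    )
    if not np.isfinite(n) or n > max_n:
        raise ValueError("required sample size exceeds the cap")
    return int(np.ceil(n))
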