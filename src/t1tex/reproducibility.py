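"""Reproducibility gating of texture features (ICC + CV).

Features enter downstream selection only if intra-reader ICC >= 0.75,
inter-reader ICC >= 0.75 and coefficient of variation <= 10%, computed from
a gate set of cases contoured twice by each of two readers.

The ICC is the two-way mixed-effects consistency form ICC(C,1):
``(MSR - MSE) / (MSR + (k - 1) MSE)`` from the ANOVA mean squares of a
subjects x raters table; fixed per-rater shifts do not lower it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (0.75, 0.75, 0.10)  # icc_intra, icc_inter, cv


@dataclass
class IccResult:
    icc: float
    ms_rows: float
    ms_error: float
    k: int
    n: int
    degenerate: bool = False

    @property
    def label(self) -> str:
        if self.icc < 0.5:
            return "poor"
        if self.icc < 0.75:
            return "fair"
        if self.icc < 0.90:
            return "good"
        return "excellent"


@dataclass
class GateDecision:
    feature: str
    icc_intra: float
    icc_inter: float
    cv: float
    passed: bool
    unstable_cv: bool = False  # |mean| ~ 0 for some case


def icc_consistency(ratings: np.ndarray) -> IccResult:
    """ICC(C,1) from a complete subjects x raters matrix."""
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = ratings.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if not np.isfinite(ratings).all():
        raise ValueError("missing or non-finite cells in the ratings matrix")
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_total = float(((ratings - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total == 0.0:
        return IccResult(icc=1.0, ms_rows=0.0, ms_error=0.0, k=k, n=n, degenerate=True)
    denom = msr + (k - 1) * mse
    icc = (msr - mse) / denom if denom > 0 else 1.0
    return IccResult(icc=float(icc), ms_rows=msr, ms_error=mse, k=k, n=n)


def coefficient_of_variation(values: np.ndarray) -> float:
    """sd / |mean| of one case's repeated measurements (ddof=1)."""
    values = np.asarray(values, dtype=float)
    m = np.abs(values.mean())
    if m == 0:
        return np.inf
    return float(values.std(ddof=1) / m)


def feature_cv(table: np.ndarray) -> tuple[float, bool]:
    """Per-feature CV: per-case sd/|mean| across measurements, median over cases."""
    table = np.asarray(table, dtype=float)
    cvs = np.array([coefficient_of_variation(row) for row in table])
    unstable = bool(np.isinf(cvs).any())
    return float(np.median(cvs[np.isfinite(cvs)])) if np.isfinite(cvs).any() else np.inf, unstable


def reproducibility_gate(
    tables: dict[tuple[int, int], pd.DataFrame],
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> list[GateDecision]:
    """Gate decisions from feature tables keyed by (reader, repeat).

    ``tables`` must contain keys (1, 1), (1, 2), (2, 1), (2, 2); each value
    is a cases x features frame sharing index and columns.  Intra-reader ICC
    compares reader 1's two passes; inter-reader ICC compares the readers'
    first passes; the CV pools all four measurements per case.
    """
    required = {(1, 1), (1, 2), (2, 1), (2, 2)}
    if not required.issubset(tables):
        raise ValueError(f"gate needs tables for {sorted(required)}")
    ref = tables[(1, 1)]
    for key in required:
        t = tables[key]
        if not (t.index.equals(ref.index) and t.columns.equals(ref.columns)):
            raise ValueError("mismatched case sets or feature catalogs across tables")
    thr_intra, thr_inter, thr_cv = thresholds
    decisions = []
    for feat in ref.columns:
        intra = icc_consistency(
            np.column_stack([tables[(1, 1)][feat], tables[(1, 2)][feat]])
        ).icc
        inter = icc_consistency(
            np.column_stack([tables[(1, 1)][feat], tables[(2, 1)][feat]])
        ).icc
        all4 = np.column_stack([tables[k][feat] for k in sorted(required)])
        cv, unstable = feature_cv(all4)
        passed = (
            (intra >= thr_intra)
            and (inter >= thr_inter)
            and (cv <= thr_cv)
            and not unstable
        )
        decisions.append(
            GateDecision(
                feature=feat,
                icc_intra=float(intra),
                icc_inter=float(inter),
                cv=float(cv),
                passed=bool(passed),
                unstable_cv=unstable,
            )
        )
    return decisions


def gate_report(decisions: list[GateDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": d.feature,
                "icc_intra": d.icc_intra,
                "icc_inter": d.icc_inter,
                "cv": d.cv,
                "passed": d.passed,
            }
            for d in decisions
        ]
    ).set_index("feature")
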