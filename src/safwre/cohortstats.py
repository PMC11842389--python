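"""Group-comparison statistics between impaired and normal patients.

Continuous features are compared with the independent two-sample pooled-
variance t-test (equal variances assumed; this convention, not Welch,
matches published group tables in this literature), categorical features
with the Pearson chi-square test without Yates continuity correction.
Both tests are also available directly from printed summary statistics
(mean/SD/n per group; per-level counts), so published tables can be checked
without patient-level data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import CohortTable

__all__ = [
    "GroupSummary",
    "TestResult",
    "pooled_t_from_summaries",
    "chi_square_contingency",
    "cohort_comparison_table",
]


@dataclass
class TestResult:
    statistic: float
    statistic_kind: str  # "t" or "chi2"
    df: float
    p_value: float


@dataclass
class GroupSummary:
    """Per-group descriptives for one feature (continuous or categorical)."""

    feature: str
    kind: str  # "continuous" | "categorical"
    group1: dict  # impaired
    group0: dict  # normal


def pooled_t_from_summaries(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TestResult:
    """|t| of the pooled-variance two-sample t-test from group summaries.

    s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2); df = n1+n2-2; two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    t = abs(m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(t, df)
    return TestResult(statistic=float(t), statistic_kind="t", df=float(df), p_value=float(p))


def chi_square_contingency(counts) -> TestResult:
    """Pearson chi-square on an R x 2 table, no continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("expected an R x 2 contingency table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected <= 0).any():
        raise ValueError("all expected counts must be positive")
    return TestResult(statistic=float(chi2), statistic_kind="chi2", df=float(df), p_value=float(p))


def cohort_comparison_table(
    cohort: CohortTable, features: list[str] | None = None
) -> pd.DataFrame:
    """Published-table-style group comparison on raw patient data.

    One row per requested feature: class-conditional summaries plus the
    pooled t (continuous) or Pearson chi-square (binary/ordinal) statistic
    and its p-value.
    """
    if features is None:
        features = cohort.feature_names
    y = cohort.y
    rows = []
    for name in features:
        vals = cohort.data[name].to_numpy(dtype=float)
        kind = cohort.feature_types[name]
        g1, g0 = vals[y == 1], vals[y == 0]
        if kind == "continuous":
            res = pooled_t_from_summaries(
                g1.mean(), g1.std(ddof=1), len(g1), g0.mean(), g0.std(ddof=1), len(g0)
            )
            rows.append(
                {
                    "feature": name,
                    "kind": "continuous",
                    "impaired_mean": g1.mean(),
                    "impaired_sd": g1.std(ddof=1),
                    "normal_mean": g0.mean(),
                    "normal_sd": g0.std(ddof=1),
                    "statistic_kind": "t",
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                }
            )
        else:
            levels = np.unique(vals)
            table = np.array(
                [[np.sum(g1 == lv), np.sum(g0 == lv)] for lv in levels], dtype=float
            )
            res = chi_square_contingency(table)
            rows.append(
                {
                    "feature": name,
                    "kind": "categorical",
                    "impaired_mean": np.nan,
                    "impaired_sd": np.nan,
                    "normal_mean": np.nan,
                    "normal_sd": np.nan,
                    "statistic_kind": "chi2",
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
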