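"""Group-comparison statistics for the screening cohort.

Mirrors the reporting structure of a two-group clinical comparison:
medians with interquartile ranges and Mann-Whitney U tests for the
drawing features, a pooled-variance t-test for age, and a Pearson
chi-square test for sex. Raw two-sided p-values are reported per row
with no multiple-testing correction, flagged significant at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .features import FEATURE_NAMES
from .recordings import SHAPES

__all__ = ["GroupComparison", "median_iqr", "mann_whitney_u",
           "chi_square_2x2", "student_t", "comparison_table",
           "comparison_markdown", "ALPHA"]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """One comparison row: group summaries plus a two-sided test."""

    variable: str
    shape: str | None
    summary_a: tuple  # (median, q1, q3) or (count, percent)
    summary_b: tuple
    test: str
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles using linear-interpolation (type-7)
    quantiles, the numpy default. Returns ``(median, q1, q3)``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median_iqr of empty input")
    med, q1, q3 = np.percentile(v, [50, 25, 75])
    return float(med), float(q1), float(q3)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Reports ``U = min(U_a, U_b)`` from midrank rank sums. The p-value is
    exact (full enumeration) for small tie-free samples
    (``n_a + n_b <= 12``), otherwise the normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = _stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                              use_continuity=True)
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    return u, float(res.pvalue)


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 count table,
    df = 1; continuity (Yates) correction off by default."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, expected = _stats.chi2_contingency(t, correction=yates)
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    return float(chi2), float(p)


def student_t(a, b) -> tuple[float, float]:
    """Two-tailed pooled-variance two-sample t-test,
    df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = _stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def comparison_table(features: pd.DataFrame,
                     group_a: str = "nonCM",
                     group_b: str = "CM") -> list[GroupComparison]:
    """Per-shape, per-feature group comparison.

    For each of the 3 shapes x 3 features: group medians/IQRs plus the
    Mann-Whitney two-sided p-value, ``group_a`` summarized first.
    """
    required = {"group", "shape"} | set(FEATURE_NAMES)
    if not required.issubset(features.columns):
        raise ValueError(f"feature table needs columns {sorted(required)}")
    present = set(features["group"].dropna())
    if not {group_a, group_b}.issubset(present):
        raise ValueError(f"need both groups {group_a!r} and {group_b!r}; "
                         f"found {sorted(present)}")
    rows = []
    for shape in SHAPES:
        sub = features[features["shape"] == shape]
        if sub.empty:
            continue
        va = sub[sub["group"] == group_a]
        vb = sub[sub["group"] == group_b]
        for feat in FEATURE_NAMES:
            u, p = mann_whitney_u(va[feat], vb[feat])
            rows.append(GroupComparison(
                variable=feat, shape=shape,
                summary_a=median_iqr(va[feat]),
                summary_b=median_iqr(vb[feat]),
                test="mann-whitney", statistic=u, p_value=p))
    return rows


def _fmt_miqr(summary: tuple) -> str:
    m, q1, q3 = summary
    return f"{m:.1f} ({q1:.1f}-{q3:.1f})"


def comparison_markdown(rows: list[GroupComparison],
                        group_a: str = "non-CM",
                        group_b: str = "CM") -> str:
    """Markdown rendering of the comparison table, one block per shape.

    A footnote records that p-values are raw (no multiple-testing
    correction).
    """
    lines = []
    by_shape: dict[str | None, list[GroupComparison]] = {}
    for r in rows:
        by_shape.setdefault(r.shape, []).append(r)
    for shape, shape_rows in by_shape.items():
        lines.append(f"### {shape}")
        lines.append(f"| feature | {group_a} median (IQR) | "
                     f"{group_b} median (IQR) | p-value |")
        lines.append("|---|---|---|---|")
        for r in shape_rows:
            star = " *" if r.significant else ""
            lines.append(f"| {r.variable} | {_fmt_miqr(r.summary_a)} | "
                         f"{_fmt_miqr(r.summary_b)} | "
                         f"{r.p_value:.2g}{star} |")
        lines.append("")
    lines.append("`*` p < 0.05 (Mann-Whitney, two-sided; raw p-values, "
                 "no multiple-testing correction)")
    return "\n".join(lines)


def comparison_frame(rows: list[GroupComparison]) -> pd.DataFrame:
    """The comparison table as a flat DataFrame (CSV-friendly)."""
    return pd.DataFrame([{
        "shape": r.shape, "feature": r.variable,
        "a_median": r.summary_a[0], "a_q1": r.summary_a[1],
        "a_q3": r.summary_a[2],
        "b_median": r.summary_b[0], "b_q1": r.summary_b[1],
        "b_q3": r.summary_b[2],
        "test": r.test, "statistic": r.statistic, "p_value": r.p_value,
        "significant": r.significant} for r in rows])
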