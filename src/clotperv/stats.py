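"""Cohort statistics: normality screening, group comparisons, FDR control,
pairwise clot-type comparisons across uptake categories, per-category Pearson
correlations with verbal strength bands, and the population summary table.

All tests are two-sided with significance at p < 0.05 by default; families of
related comparisons are corrected with the Benjamini–Hochberg step-up
procedure.  The heavy lifting is delegated to scipy / statsmodels; this
module fixes the conventions (tie handling, families, strength bands,
percentage precision) so results are reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "CorrelationResult",
    "SummaryTable",
    "ks_normality",
    "kruskal_wallis",
    "chi_squared_contingency",
    "bh_adjust",
    "pairwise_category_comparisons",
    "pearson_by_category",
    "strength_label",
    "cohort_summary",
]


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    df: float | None = None
    group_sizes: tuple = ()
    notes: str = ""
    expected: np.ndarray | None = None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    strength_label: str
    pair: tuple
    direction: int
    category: str = ""
    n: int = 0


@dataclass
class SummaryTable:
    """Cohort characteristics: categorical counts/percentages and numeric mean±SD."""

    n: int
    categorical: pd.DataFrame  # variable, level, count, percentage
    numeric: pd.DataFrame  # variable, mean, sd


def ks_normality(values: Sequence[float]) -> StatResult:
    """Kolmogorov–Smirnov normality test with sample-estimated parameters.

    Because mean and SD are estimated from the sample, the Lilliefors-
    corrected critical values are used; the uncorrected KS test would be
    anti-conservative here.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality test needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("normality test is undefined for a constant sample")
    stat, p = lilliefors(x, dist="norm")
    return StatResult(
        test_name="ks_normality",
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
        group_sizes=(int(x.size),),
        notes="Lilliefors correction applied (parameters estimated from sample)",
    )


def kruskal_wallis(groups: Iterable[Sequence[float]]) -> StatResult:
    """Kruskal–Wallis H test with tie correction, chi-squared approximate p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    total_n = sum(g.size for g in groups)
    if total_n < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        # all observations tied: no evidence of a difference
        return StatResult(
            test_name="kruskal_wallis",
            statistic=0.0,
            p_value=1.0,
            df=len(groups) - 1,
            group_sizes=tuple(g.size for g in groups),
            notes="all observations identical",
        )
    stat, p = sps.kruskal(*groups)
    return StatResult(
        test_name="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        df=len(groups) - 1,
        group_sizes=tuple(int(g.size) for g in groups),
    )


def chi_squared_contingency(
    table: np.ndarray, yates: bool = False
) -> StatResult:
    """Pearson chi-squared test of independence on a counts table.

    Rows/columns with a zero margin are dropped (with a note) before
    testing.  Expected counts below 5 trigger a warning note rather than a
    switch to an exact test.  No Yates continuity correction unless
    requested.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2D")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must contain non-negative integer counts")
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")

    notes = []
    row_keep = t.sum(axis=1) > 0
    col_keep = t.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        notes.append(
            f"dropped {int((~row_keep).sum())} empty row(s) and "
            f"{int((~col_keep).sum())} empty column(s)"
        )
    t = t[np.ix_(row_keep, col_keep)]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("fewer than 2 non-empty rows or columns")

    res = sps.chi2_contingency(t, correction=yates)
    if np.any(res.expected_freq < 5):
        notes.append("expected count < 5 in at least one cell")
    return StatResult(
        test_name="chi_squared",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.dof),
        group_sizes=tuple(int(n) for n in t.sum(axis=1)),
        notes="; ".join(notes),
        expected=np.asarray(res.expected_freq),
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(q) for q in adjusted]


def pairwise_category_comparisons(
    df: pd.DataFrame,
    category_col: str = "dynamic_label",
    clot_type_col: str = "clot_type",
    rich_label: str = "fibrin_platelet_rich",
) -> list[StatResult]:
    """Fibrin/platelet-rich vs. the rest, compared between every pair of
    uptake categories.

    For each unordered pair of categories present in the data, a 2x2
    chi-squared tests (fibrin-rich vs. RBC-rich + mixed) against category
    membership; the resulting p-values are BH-adjusted as a single family.
    Pairs where one category has no patients are skipped with a note, and
    degenerate 2x2 tables (a zero margin, e.g. no fibrin-rich clot in either
    category) score statistic 0, p = 1.
    """
    cats = [c for c in df[category_col].dropna().unique()]
    if len(cats) < 2:
        raise ValueError("need at least 2 categories present")
    cats = sorted(cats)

    results = []
    for a, b in itertools.combinations(cats, 2):
        sub_a = df[df[category_col] == a]
        sub_b = df[df[category_col] == b]
        name = f"fibrin_rich:{a}|{b}"
        if len(sub_a) == 0 or len(sub_b) == 0:
            results.append(
                StatResult(name, np.nan, np.nan, notes="skipped: empty category")
            )
            continue
        table = np.array(
            [
                [(sub_a[clot_type_col] == rich_label).sum(), (sub_a[clot_type_col] != rich_label).sum()],
                [(sub_b[clot_type_col] == rich_label).sum(), (sub_b[clot_type_col] != rich_label).sum()],
            ]
        )
        try:
            res = chi_squared_contingency(table)
            res.test_name = name
            res.group_sizes = (len(sub_a), len(sub_b))
        except ValueError:
            res = StatResult(
                name, 0.0, 1.0, group_sizes=(len(sub_a), len(sub_b)),
                notes="degenerate 2x2 table (zero margin); no evidence of difference",
            )
        results.append(res)

    tested = [r for r in results if np.isfinite(r.p_value)]
    adjusted = bh_adjust([r.p_value for r in tested])
    for r, q in zip(tested, adjusted):
        r.p_adjusted = q
    return results


_STRENGTH_BANDS = (
    (0.90, "very strong"),
    (0.70, "strong"),
    (0.40, "moderate"),
    (0.20, "weak"),
    (0.00, "negligible"),
)


def strength_label(r: float) -> str:
    """Verbal strength of a Pearson coefficient: |r| ≥ 0.90 very strong,
    0.70–0.89 strong, 0.40–0.69 moderate, 0.20–0.39 weak, below negligible."""
    a = abs(r)
    if a > 1 + 1e-12:
        raise ValueError("|r| cannot exceed 1")
    for cut, label in _STRENGTH_BANDS:
        if a >= cut:
            return label
    return "negligible"


_COMPONENT_PAIRS = (
    ("fibrin_platelet_pct", "rbc_pct"),
    ("fibrin_platelet_pct", "wbc_pct"),
    ("rbc_pct", "wbc_pct"),
)


def pearson_by_category(
    df: pd.DataFrame,
    category_col: str = "dynamic_label",
    pairs: tuple = _COMPONENT_PAIRS,
) -> list[CorrelationResult]:
    """Pearson r between clot components within each uptake category."""
    out = []
    for category, sub in df.groupby(category_col, sort=True):
        if len(sub) < 3:
            raise ValueError(
                f"category {category!r} has n={len(sub)} < 3; correlation undefined"
            )
        for x_col, y_col in pairs:
            x = sub[x_col].to_numpy(dtype=float)
            y = sub[y_col].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(
                    f"zero variance in {x_col}/{y_col} within category {category!r}"
                )
            r = float(sps.pearsonr(x, y).statistic)
            out.append(
                CorrelationResult(
                    r=r,
                    strength_label=strength_label(r),
                    pair=(x_col, y_col),
                    direction=int(np.sign(r)) if r != 0 else 0,
                    category=str(category),
                    n=len(sub),
                )
            )
    return out


_DEFAULT_CATEGORICAL = ("sex", "etiology", "site_of_occlusion", "rtpa", "mtici")
_DEFAULT_NUMERIC = ("age", "nihss")


def cohort_summary(
    df: pd.DataFrame,
    categorical: Sequence[str] = _DEFAULT_CATEGORICAL,
    numeric: Sequence[str] = _DEFAULT_NUMERIC,
    precision: int = 1,
) -> SummaryTable:
    """Population-characteristics table: n (%) per categorical level and
    mean ± SD per numeric variable.

    Percentages are 100 * count / cohort n, rounded to ``precision``
    decimals; counts within a variable always sum to n (missing values are
    reported as their own level).
    """
    if len(df) == 0:
        raise ValueError("empty cohort")
    n = len(df)
    cat_rows = []
    for var in categorical:
        if var not in df.columns:
            continue
        col = df[var].astype("object").where(df[var].notna(), "missing")
        counts = col.value_counts(sort=False)
        for level, count in counts.items():
            cat_rows.append(
                {
                    "variable": var,
                    "level": str(level),
                    "count": int(count),
                    "percentage": round(100.0 * count / n, precision),
                }
            )
    num_rows = []
    for var in numeric:
        if var not in df.columns:
            continue
        x = df[var].dropna().to_numpy(dtype=float)
        if x.size == 0:
            continue
        num_rows.append(
            {"variable": var, "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0}
        )
    return SummaryTable(
        n=n,
        categorical=pd.DataFrame(cat_rows, columns=["variable", "level", "count", "percentage"]),
        numeric=pd.DataFrame(num_rows, columns=["variable", "mean", "sd"]),
    )
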