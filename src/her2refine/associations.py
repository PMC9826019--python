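"""Contingency-table association tests between HER2 scores and covariates.

Cross-tabulates a categorical clinicopathological variable against HER2
score groups and tests independence with Pearson's chi-square (Yates
continuity correction optional for 2x2) or Fisher's exact test when the
asymptotic approximation is dubious (any expected cell count below 5).
The three score comparisons mirror how such tables are reported: 0 vs 1+,
1+ vs 2+, and 0 vs the pooled HER2-low class {1+, 2+}.  No
multiple-testing correction is applied; raw p-values are reported with
their comparison label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import Her2Score

__all__ = [
    "ZeroMarginError",
    "ContingencyTable",
    "chi_square",
    "fisher_exact",
    "pairwise_score_tests",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
]


class ZeroMarginError(ValueError):
    """A row or column margin is zero; expected counts are undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative integer counts with labelled margins."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"table must be at least 2x2, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if arr.sum() == 0:
            raise ValueError("table total must be positive")

    @classmethod
    def from_array(
        cls,
        counts: "np.typing.ArrayLike",
        row_labels: Sequence[str] = (),
        col_labels: Sequence[str] = (),
    ) -> "ContingencyTable":
        arr = np.asarray(counts, dtype=int)
        return cls(
            tuple(tuple(int(v) for v in row) for row in arr),
            tuple(row_labels),
            tuple(col_labels),
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def _check_margins(t: ContingencyTable) -> np.ndarray:
    arr = t.array
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    for i, r in enumerate(rows):
        if r == 0:
            lab = t.row_labels[i] if t.row_labels else str(i)
            raise ZeroMarginError(f"row {lab!r} has zero margin")
    for j, c in enumerate(cols):
        if c == 0:
            lab = t.col_labels[j] if t.col_labels else str(j)
            raise ZeroMarginError(f"column {lab!r} has zero margin")
    return arr


def expected_counts(t: ContingencyTable) -> np.ndarray:
    """Expected cell counts under independence, from the margins."""
    arr = _check_margins(t)
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def chi_square(t: ContingencyTable, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence.

    Returns ``(statistic, df, p)`` with df = (r-1)(c-1).  ``yates`` applies
    the continuity correction (2x2 tables only, where scipy applies it).
    """
    arr = _check_margins(t)
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=yates)
    return float(stat), int(dof), float(p)


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums the hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.
    """
    arr = t.array
    if arr.shape != (2, 2):
        raise ValueError(f"Fisher exact test requires a 2x2 table, got {arr.shape}")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def _score_group(score, groups: dict[str, str]) -> str | None:
    return groups.get(str(Her2Score.parse(score)))


def pairwise_score_tests(
    cohort: pd.DataFrame,
    variable: str,
    score_col: str = "refined_score",
    expected_min: float = 5.0,
) -> list[dict]:
    """The three score-group association tests for one categorical variable.

    Builds variable x score-group tables for 0 vs 1+, 1+ vs 2+, and
    0 vs {1+, 2+} (pooled HER2-low) and applies the chi-square test, or the
    Fisher exact test for a 2x2 table with any expected count below
    ``expected_min``.  Returns one record per comparison with keys
    ``comparison, test, statistic, df, p, table``.
    """
    comparisons = [
        ("0 vs 1+", {"0": "0", "1+": "1+"}),
        ("1+ vs 2+", {"1+": "1+", "2+": "2+"}),
        ("0 vs 1+/2+", {"0": "0", "1+": "1+/2+", "2+": "1+/2+"}),
    ]
    results = []
    for name, groups in comparisons:
        sub = cohort[[variable, score_col]].dropna().copy()
        sub["group"] = [_score_group(s, groups) for s in sub[score_col]]
        sub = sub.dropna(subset=["group"])
        tab = pd.crosstab(sub[variable], sub["group"])
        if tab.shape[0] < 2:
            raise ZeroMarginError(
                f"variable {variable!r} has a single observed level; "
                "association is undefined"
            )
        if tab.shape[1] < 2:
            raise ZeroMarginError(f"a score group is empty for comparison {name!r}")
        table = ContingencyTable.from_array(
            tab.to_numpy(), [str(r) for r in tab.index], [str(c) for c in tab.columns]
        )
        expected = expected_counts(table)
        if table.array.shape == (2, 2) and (expected < expected_min).any():
            p = fisher_exact(table)
            rec = {"test": "fisher_exact", "statistic": float("nan"), "df": 1, "p": p}
        else:
            stat, df, p = chi_square(table)
            rec = {"test": "chi_square", "statistic": stat, "df": df, "p": p}
        rec.update({"comparison": name, "variable": variable, "table": table})
        results.append(rec)
    return results


def kruskal_wallis(cohort: pd.DataFrame, variable: str, score_col: str = "refined_score"):
    """Kruskal-Wallis H-test of a continuous variable across score groups.

    Thin wrapper over the standard test, provided for report parity with
    continuous covariates.
    """
    groups = [g[variable].dropna().to_numpy() for _, g in cohort.groupby(score_col)]
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def wilcoxon_rank_sum(x, y, continuity: bool = True):
    """Wilcoxon rank-sum (Mann-Whitney) test between two samples."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", use_continuity=continuity)
    return float(res.statistic), float(res.pvalue)
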