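"""Observer-agreement analytics over 3x3 HER2 score cross-tabulations.

The HER2-negative cohort carries scores 0 / 1+ / 2+ only, so agreement
between two scorings is summarised on a 3x3 confusion matrix: Cohen's
kappa (chance-corrected agreement), the raw exact-agreement proportion,
and a decomposition of the discordant cases by unordered category pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .profiles import Her2Score

__all__ = [
    "SCORE_LABELS",
    "ConfusionMatrix3",
    "cross_tabulate",
    "cohen_kappa",
    "exact_agreement",
    "discordance_breakdown",
    "concordance_report",
]

SCORE_LABELS = ("0", "1+", "2+")
_PAIRS = (("0", "1+"), ("1+", "2+"), ("0", "2+"))


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 cross-tabulation; rows = scoring A, columns = scoring B."""

    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3):
            raise ValueError(f"expected a 3x3 matrix, got shape {arr.shape}")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if arr.sum() == 0:
            raise ValueError("matrix total must be positive")

    @classmethod
    def from_array(cls, counts: "np.typing.ArrayLike") -> "ConfusionMatrix3":
        arr = np.asarray(counts, dtype=int)
        return cls(tuple(tuple(int(v) for v in row) for row in arr))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @property
    def total(self) -> int:
        return int(self.array.sum())


def _as_indices(scores: Iterable) -> np.ndarray:
    idx = []
    for s in scores:
        score = Her2Score.parse(s)
        if score.value > 2:
            raise ValueError(
                "3+ scores are outside the HER2-negative cohort scope "
                f"(got {score})"
            )
        idx.append(score.value)
    return np.asarray(idx, dtype=int)


def cross_tabulate(scores_a: Sequence, scores_b: Sequence) -> ConfusionMatrix3:
    """Count cases into a 3x3 matrix, rows = ``scores_a`` categories."""
    a = _as_indices(scores_a)
    b = _as_indices(scores_b)
    if a.size != b.size:
        raise ValueError(f"score lists differ in length: {a.size} vs {b.size}")
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (a, b), 1)
    return ConfusionMatrix3.from_array(counts)


def cohen_kappa(m: ConfusionMatrix3, weighted: bool = False) -> float:
    """Cohen's kappa, kappa = (P_o - P_e) / (1 - P_e).

    ``P_o`` is the observed agreement (diagonal proportion) and ``P_e`` the
    chance agreement from the marginals.  Unweighted by default; with
    ``weighted=True`` linear disagreement weights are applied (non-default,
    provided for sensitivity checks).
    """
    arr = m.array
    n = arr.sum()
    p = arr / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    if weighted:
        k = len(SCORE_LABELS)
        w = 1.0 - np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
        po = float((w * p).sum())
        pe = float((w * np.outer(row, col)).sum())
    else:
        po = float(np.trace(p))
        pe = float(row @ col)
    if pe >= 1.0 - 1e-12:
        if po >= 1.0 - 1e-12:
            return 1.0  # all mass in a single agreeing cell-pair: defined limit
        raise ZeroDivisionError("chance agreement is 1; kappa undefined")
    return (po - pe) / (1.0 - pe)


def exact_agreement(m: ConfusionMatrix3) -> float:
    """Raw proportion of exact score agreement (diagonal / total)."""
    arr = m.array
    return float(np.trace(arr) / arr.sum())


def discordance_breakdown(m: ConfusionMatrix3) -> dict[str, int]:
    """Off-diagonal total and per-unordered-pair discordance counts."""
    arr = m.array.astype(int)
    out = {"total": int(arr.sum() - np.trace(arr))}
    for a, b in _PAIRS:
        i, j = SCORE_LABELS.index(a), SCORE_LABELS.index(b)
        out[f"{a} vs {b}"] = int(arr[i, j] + arr[j, i])
    return out


def concordance_report(m: ConfusionMatrix3) -> dict:
    """Bundle kappa, exact agreement and discordance for reporting.

    Kappa is additionally rounded to 2 decimal places and agreement to a
    whole percent, matching the precision such tables are reported at.
    """
    kappa = cohen_kappa(m)
    agreement = exact_agreement(m)
    return {
        "kappa": kappa,
        "kappa_2dp": round(kappa, 2),
        "exact_agreement": agreement,
        "exact_agreement_pct": round(100.0 * agreement),
        "discordance": discordance_breakdown(m),
        "total": m.total,
    }


def format_matrix(m: ConfusionMatrix3) -> str:
    """Plain-text table of the cross-tabulation with marginals."""
    arr = m.array.astype(int)
    lines = ["second \\ first\t" + "\t".join(SCORE_LABELS) + "\tTotal"]
    for i, lab in enumerate(SCORE_LABELS):
        lines.append(lab + "\t" + "\t".join(str(v) for v in arr[i]) + f"\t{arr[i].sum()}")
    lines.append("Total\t" + "\t".join(str(v) for v in arr.sum(axis=0)) + f"\t{arr.sum()}")
    return "\n".join(lines)
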