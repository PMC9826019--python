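"""Dichotomization of continuous HER2 mRNA by exact one-dimensional 2-means.

HER2 mRNA here is on the normalised RT-PCR scale (mean reference-gene CT
minus target CT); in the development cohort it spans roughly 5.0-10.8
units.  Splitting a single continuous variable into two clusters that
minimise the within-cluster sum of squares does not need the iterative
Lloyd algorithm: in one dimension every optimal 2-partition is a split of
the sorted values, so an exhaustive scan over the n-1 split positions finds
the global optimum deterministically and without seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "InsufficientDataError",
    "DegenerateInputError",
    "ClusterAssignment",
    "kmeans_dichotomize",
    "cluster_summary",
]

#: mRNA values outside this window trigger a plausible-range warning.
PLAUSIBLE_RANGE = (0.0, 20.0)


class InsufficientDataError(ValueError):
    """Fewer than two observations: no 2-partition exists."""


class DegenerateInputError(ValueError):
    """All values identical (or inseparable): the 2-means split is undefined."""


@dataclass(frozen=True)
class ClusterAssignment:
    """Result of a two-cluster split of a 1-D variable.

    ``labels`` is aligned to the input order with entries ``"low"`` /
    ``"high"``; ``cutoff`` separates the clusters (all low values < cutoff
    <= all high values under the default midpoint convention);
    ``centroids`` are the two cluster means, ordered low < high.
    """

    labels: tuple[str, ...]
    cutoff: float
    cluster_sizes: tuple[int, int]
    centroids: tuple[float, float]


def kmeans_dichotomize(
    levels: "np.typing.ArrayLike", cutoff_convention: str = "midpoint"
) -> ClusterAssignment:
    """Globally optimal 2-means split of a 1-D sample.

    Scans all split positions of the sorted values and returns the
    partition minimising the within-cluster sum of squares.  The reported
    cutoff is, by default, the midpoint of the gap between the largest low
    value and the smallest high value; ``cutoff_convention="max_of_low"``
    reports the largest low value instead (the midpoint convention is the
    one under which re-thresholding at the cutoff reproduces the labels).

    Raises
    ------
    InsufficientDataError
        If fewer than two values are supplied.
    DegenerateInputError
        If all values are identical.
    """
    x = np.asarray(levels, dtype=float).ravel()
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("mRNA levels must be finite")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("all values identical; no two-cluster split exists")
    if x.min() < PLAUSIBLE_RANGE[0] or x.max() > PLAUSIBLE_RANGE[1]:
        warnings.warn(
            f"mRNA levels outside plausible range {PLAUSIBLE_RANGE}: "
            f"observed [{x.min():g}, {x.max():g}]",
            stacklevel=2,
        )

    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    cum = np.cumsum(xs)
    cum2 = np.cumsum(xs**2)
    k = np.arange(1, n)  # size of the low cluster
    low_ss = cum2[k - 1] - cum[k - 1] ** 2 / k
    high_ss = (cum2[-1] - cum2[k - 1]) - (cum[-1] - cum[k - 1]) ** 2 / (n - k)
    wcss = low_ss + high_ss

    best = wcss.min()
    candidates = k[np.isclose(wcss, best, rtol=0.0, atol=1e-9 * max(1.0, abs(best)))]
    # Among equally optimal splits prefer the widest boundary gap, so the
    # cutoff is well separated from both clusters (ties can only arise with
    # duplicated values).
    gaps = xs[candidates] - xs[candidates - 1]
    k_best = int(candidates[np.argmax(gaps)])
    if xs[k_best] - xs[k_best - 1] <= 0.0:
        raise DegenerateInputError(
            "optimal split falls between tied values; clusters are inseparable"
        )

    if cutoff_convention == "midpoint":
        cutoff = float((xs[k_best - 1] + xs[k_best]) / 2.0)
    elif cutoff_convention == "max_of_low":
        cutoff = float(xs[k_best - 1])
    else:
        raise ValueError(f"unknown cutoff convention {cutoff_convention!r}")

    labels = np.empty(n, dtype=object)
    labels[order[:k_best]] = "low"
    labels[order[k_best:]] = "high"
    centroids = (float(xs[:k_best].mean()), float(xs[k_best:].mean()))
    return ClusterAssignment(
        labels=tuple(labels),
        cutoff=cutoff,
        cluster_sizes=(k_best, n - k_best),
        centroids=centroids,
    )


def cluster_summary(
    assignment: ClusterAssignment, levels: "np.typing.ArrayLike"
) -> dict[str, dict[str, float]]:
    """Per-cluster sample mean and standard deviation (ddof=1).

    A singleton cluster reports SD 0.0.
    """
    x = np.asarray(levels, dtype=float).ravel()
    labels = np.asarray(assignment.labels, dtype=object)
    if x.size != labels.size:
        raise ValueError("levels and assignment labels have different lengths")
    out: dict[str, dict[str, float]] = {}
    for name in ("low", "high"):
        vals = x[labels == name]
        if vals.size == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out[name] = {"n": int(vals.size), "mean": float(vals.mean()), "sd": sd}
    return out
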