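"""Opinion-cluster identification and conformity-driven rating updates.

A panel of experts rates items on a bounded ordinal scale (1..q).  Within a
single item the ratings often pile up in one or more narrow windows of the
scale — opinion clusters ("clustered consensus", with more than one cluster
signalling structured dissensus).  A cluster here is an interval of at most
``cluster_width`` consecutive scale points.  The modal window (the interval
holding the most ratings, count ``r_mode``) is always a cluster; any further
disjoint window holding at least ``secondary_threshold * r_mode`` ratings is
a secondary cluster.

Between survey rounds each expert moves toward the mean rating of the
cluster nearest their current score, with a Group Conformity Index (GCI) in
[0, 1] weighting the pull: 0 leaves the rating unchanged ("stubborn"), 1
adopts the cluster mean outright ("fully conforming").
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Absolute slack when deciding whether a rating sits exactly midway between
#: two cluster means.  Means are ratios of small integers, so genuine midway
#: ties (e.g. rating 6 between means 4.0 and 8.0) are represented exactly or
#: within a few ulps; anything farther apart than this is a real difference.
MIDWAY_TOLERANCE = 1e-9


class NoTargetClusterError(ValueError):
    """Raised when a convergence target is requested from an empty cluster set."""


@dataclass(frozen=True)
class ClusteringParams:
    """Parameters of the sliding-window cluster rule.

    Parameters
    ----------
    cluster_width
        Maximum number of consecutive scale points a cluster may span
        (the window size *v*).  Default 3, i.e. three points of a 1–10 scale.
    secondary_threshold
        Fraction *p* of the modal count that a disjoint window must reach to
        count as a secondary cluster.  Values at or above 0.5 are recommended
        so that small outlying windows cannot proliferate.  Default 0.5.
    """

    cluster_width: int = 3
    secondary_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.cluster_width < 1:
            raise ValueError("cluster_width must be a positive integer")
        if not 0.0 < self.secondary_threshold < 1.0:
            raise ValueError("secondary_threshold must lie strictly in (0, 1)")


@dataclass(frozen=True)
class Cluster:
    """One opinion cluster: an inclusive interval of scale points.

    ``member_count`` ratings fall inside the interval and ``mean_rating`` is
    their arithmetic mean — the convergence target for experts assigned to
    this cluster.
    """

    low: int
    high: int
    member_count: int
    mean_rating: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("cluster interval reversed (low > high)")
        if self.member_count < 1:
            raise ValueError("a cluster must contain at least one rating")
        if not self.low <= self.mean_rating <= self.high:
            raise ValueError("mean_rating must lie inside the cluster interval")

    def __contains__(self, rating: float) -> bool:
        return self.low <= rating <= self.high

    def overlaps(self, other: "Cluster") -> bool:
        return not (self.high < other.low or other.high < self.low)

    def to_dict(self) -> dict:
        return {
            "low": self.low,
            "high": self.high,
            "member_count": self.member_count,
            "mean_rating": self.mean_rating,
        }


@dataclass(frozen=True)
class ClusterSet:
    """The disjoint opinion clusters identified for one item in one round."""

    clusters: tuple[Cluster, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.clusters, key=lambda c: c.low))
        object.__setattr__(self, "clusters", ordered)
        for a, b in zip(ordered, ordered[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping clusters: {a} and {b}")

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def r_mode(self) -> int:
        """Rating count of the most populous cluster (0 for an empty set)."""
        return max((c.member_count for c in self.clusters), default=0)

    def to_dicts(self) -> list[dict]:
        return [c.to_dict() for c in self.clusters]


# ---------------------------------------------------------------------------
# Window enumeration and greedy selection
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def _window_table(scale_max: int, width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All candidate intervals [low, high] of width 1..`width` on 1..scale_max."""
    lows, highs = [], []
    for w in range(1, width + 1):
        for lo in range(1, scale_max - w + 2):
            lows.append(lo)
            highs.append(lo + w - 1)
    lows_a = np.asarray(lows, dtype=np.intp)
    highs_a = np.asarray(highs, dtype=np.intp)
    return lows_a, highs_a, highs_a - lows_a


def _identify(counts: np.ndarray, scale_max: int, width: int,
              threshold: float) -> list[tuple[int, int, int, float]]:
    """Greedy cluster selection on a rating histogram.

    `counts[j]` is the number of ratings equal to j (index 0 unused).
    Returns ``(low, high, member_count, mean)`` tuples sorted by ``low``.

    Candidates are every interval of width <= `width`; selection is greedy by
    (count desc, width desc, low asc), skipping candidates that overlap an
    already-selected cluster, stopping once counts drop below
    ``threshold * r_mode``.
    """
    csum = np.cumsum(counts)
    wsum = np.cumsum(np.arange(counts.shape[0]) * counts)
    lows, highs, widths = _window_table(scale_max, width)
    window_counts = csum[highs] - csum[lows - 1]
    # np.lexsort: last key is primary
    order = np.lexsort((lows, -widths, -window_counts))
    wc = window_counts.tolist()
    lo_l = lows.tolist()
    hi_l = highs.tolist()
    r_mode = wc[order[0]]
    if r_mode == 0:
        return []
    cut = threshold * r_mode
    chosen: list[tuple[int, int, int, float]] = []
    for idx in order.tolist():
        m = wc[idx]
        if m < cut:
            break
        lo, hi = lo_l[idx], hi_l[idx]
        if all(hi < c[0] or lo > c[1] for c in chosen):
            chosen.append((lo, hi, m, float(wsum[hi] - wsum[lo - 1]) / m))
    chosen.sort()
    return chosen


def identify_clusters(item_ratings: Sequence[int] | np.ndarray,
                      params: ClusteringParams = ClusteringParams(),
                      scale_max: int = 10) -> ClusterSet:
    """Identify the opinion clusters among one item's ratings.

    The modal window — the interval of at most ``params.cluster_width``
    consecutive scale points holding the most ratings — is always selected;
    every further non-overlapping window holding at least
    ``params.secondary_threshold`` times the modal count is a secondary
    cluster.  Ratings falling in no selected window belong to no cluster.

    Parameters
    ----------
    item_ratings
        Integer scores in ``[1, scale_max]``; at least one required.
    params
        Window width and secondary-cluster threshold.
    scale_max
        Upper end of the ordinal scale.

    Returns
    -------
    ClusterSet
        Disjoint clusters ordered by their lower bound.
    """
    ratings = np.asarray(item_ratings)
    if ratings.size == 0:
        raise ValueError("at least one rating is required")
    if ratings.min() < 1 or ratings.max() > scale_max:
        raise ValueError(f"ratings must lie in [1, {scale_max}]")
    if params.cluster_width > scale_max:
        raise ValueError("cluster_width exceeds the rating scale")
    counts = np.bincount(ratings.ravel().astype(np.intp), minlength=scale_max + 1)
    found = _identify(counts, scale_max, params.cluster_width,
                      params.secondary_threshold)
    return ClusterSet(tuple(Cluster(lo, hi, m, mean) for lo, hi, m, mean in found))


# ---------------------------------------------------------------------------
# Convergence target and rating update
# ---------------------------------------------------------------------------

def assign_target_cluster(expert_rating: float, clusters: ClusterSet) -> Cluster:
    """The cluster an expert converges toward: nearest mean wins.

    Distance is measured from the expert's current rating to each cluster's
    mean (the convergence target).  A rating exactly midway between two
    cluster means goes to the more populous cluster; if the counts also tie,
    to the lower-lying cluster.

    Raises
    ------
    NoTargetClusterError
        If the cluster set is empty (callers keep the rating unchanged).
    """
    if len(clusters) == 0:
        raise NoTargetClusterError("empty cluster set: no convergence target")
    best: Cluster | None = None
    best_d = math.inf
    # Priority order encodes the tie rules: bigger cluster first, then lower.
    for c in sorted(clusters, key=lambda c: (-c.member_count, c.low)):
        d = abs(expert_rating - c.mean_rating)
        if d < best_d - MIDWAY_TOLERANCE:
            best, best_d = c, d
    assert best is not None
    return best


def update_rating(prev_rating: int, target_mean: float, gci: float,
                  scale_max: int = 10) -> int:
    """Next-round rating: ``round(gci * target_mean + (1 - gci) * prev)``.

    Rounding is half-away-from-zero (all quantities positive, so half-up),
    and the result is clamped to the scale.  ``gci = 0`` returns the previous
    rating unchanged; ``gci = 1`` returns the rounded cluster mean.
    """
    if not 0.0 <= gci <= 1.0:
        raise ValueError("gci must lie in [0, 1]")
    x = gci * target_mean + (1.0 - gci) * prev_rating
    score = int(math.floor(x + 0.5))
    return min(max(score, 1), scale_max)


def _advance_item(col: np.ndarray, found: list[tuple[int, int, int, float]],
                  gci: float, scale_max: int) -> np.ndarray:
    """Vectorised one-round update of one item's ratings toward `found` clusters."""
    if not found:
        return col.copy()
    pri = sorted(found, key=lambda c: (-c[2], c[0]))
    means = np.array([c[3] for c in pri])
    if len(pri) == 1:
        targets = np.full(col.shape, means[0])
    else:
        d = np.abs(col[:, None] - means[None, :])
        dmin = d.min(axis=1)
        choice = (d <= dmin[:, None] + MIDWAY_TOLERANCE).argmax(axis=1)
        targets = means[choice]
    new = np.floor(gci * targets + (1.0 - gci) * col + 0.5).astype(col.dtype)
    np.clip(new, 1, scale_max, out=new)
    return new
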