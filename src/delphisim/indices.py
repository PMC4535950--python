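"""Nine multi-rater consensus indices for bounded ordinal ratings.

All indices operate on a ratings matrix of r experts scoring n items on an
integer scale 1..q.  Seven of them are defined per item and averaged over
items for a study-wide value:

* ``DM``   — De Moivre unanimity indicator (1 iff all experts agree).
* ``PWA``  — proportion of agreeing unordered expert pairs.
* ``CPWA`` — pairwise agreement counted within opinion clusters.
* ``XCPWA``— pairwise agreement within the two fixed extreme score ranges.
* ``M``    — proportion of experts on the modal score.
* ``CM``   — proportion of experts in the modal cluster.
* ``IQR``  — interquartile range of the item's ratings (a dispersion, not a
  proportion: 0 means full central agreement).

The two chance-corrected kappas are inherently study-wide (their printed
formulas sum over items before correcting for chance):

* ``KF`` — Fleiss' kappa, chance agreement from pooled rating marginals.
* ``KC`` — Conger's kappa, chance agreement corrected by the between-expert
  variance of per-rating marginals, so ``KC >= KF`` whenever agreement is
  imperfect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clusters import ClusteringParams, ClusterSet, identify_clusters

#: Canonical ordering of the nine indices in all reports and tables.
ALL_INDICES = ("DM", "PWA", "CPWA", "XCPWA", "KF", "KC", "M", "CM", "IQR")


@dataclass(frozen=True)
class RatingMatrix:
    """Integer scores of ``n_experts`` experts on ``n_items`` items.

    ``scores[k, i]`` is expert k's rating of item i, an integer in
    ``[1, scale_max]``.  At least two experts are required — the pairwise
    formulas divide by r(r-1).
    """

    scores: np.ndarray
    scale_max: int = 10

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores)
        if arr.ndim != 2:
            raise ValueError("scores must be a 2-D array (experts x items)")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("ratings must be integers")
        arr = arr.astype(np.int64)
        if arr.shape[0] < 2:
            raise ValueError("at least 2 experts are required")
        if arr.shape[1] < 1:
            raise ValueError("at least 1 item is required")
        if self.scale_max < 2:
            raise ValueError("scale_max must be at least 2")
        if arr.min() < 1 or arr.max() > self.scale_max:
            raise ValueError(f"ratings must lie in [1, {self.scale_max}]")
        object.__setattr__(self, "scores", arr)

    @property
    def n_experts(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    def rating_counts(self) -> np.ndarray:
        """r_ij table: ``counts[i, j]`` experts gave rating j to item i (col 0 unused)."""
        q1 = self.scale_max + 1
        offset = np.arange(self.n_items, dtype=np.int64) * q1
        flat = (self.scores + offset[None, :]).ravel()
        return np.bincount(flat, minlength=self.n_items * q1).reshape(self.n_items, q1)


@dataclass(frozen=True)
class ExtremeGroups:
    """The two fixed extreme ranges of the scale used by XCPWA.

    Defaults are the bottom and top three points of a 1-10 scale.
    """

    lower_group: tuple[int, int] = (1, 3)
    upper_group: tuple[int, int] = (8, 10)

    def __post_init__(self) -> None:
        lo, hi = self.lower_group
        lo2, hi2 = self.upper_group
        if lo > hi or lo2 > hi2:
            raise ValueError("extreme group intervals are reversed")
        if hi >= lo2:
            raise ValueError("extreme groups must not overlap")
        if lo < 1:
            raise ValueError("extreme groups must lie within the scale")


@dataclass(frozen=True)
class IndexReport:
    """One consensus index evaluated on one ratings matrix.

    ``per_item`` holds the item-by-item values (None for the kappas, which
    are only defined study-wide); ``study_wide`` is the single summary
    number — the unweighted mean over items where per-item values exist.
    """

    index_name: str
    study_wide: float
    per_item: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "index": self.index_name,
            "per_item": None if self.per_item is None else [float(v) for v in self.per_item],
            "study_wide": float(self.study_wide),
        }


def _report(name: str, per_item: np.ndarray) -> IndexReport:
    return IndexReport(name, float(per_item.mean()), per_item)


def _cluster_member_counts(matrix: RatingMatrix,
                           clusters_per_item: Sequence[ClusterSet]) -> list[list[int]]:
    """Experts-per-cluster, recounted from the matrix for each item's clusters."""
    if len(clusters_per_item) != matrix.n_items:
        raise ValueError("need exactly one ClusterSet per item")
    csum = matrix.rating_counts().cumsum(axis=1)
    out: list[list[int]] = []
    for i, cset in enumerate(clusters_per_item):
        row = csum[i]
        out.append([int(row[c.high] - row[c.low - 1]) for c in cset])
    return out


# ---------------------------------------------------------------------------
# Per-item indices
# ---------------------------------------------------------------------------

def de_moivre(matrix: RatingMatrix) -> IndexReport:
    """Unanimity indicator: c_i = 1 iff all experts gave item i the same score."""
    counts = matrix.rating_counts()
    per = (counts.max(axis=1) == matrix.n_experts).astype(float)
    return _report("DM", per)


def pairwise_agreement(matrix: RatingMatrix) -> IndexReport:
    """a_i: agreeing unordered expert pairs over all r(r-1)/2 pairs.

    Two experts agree on an item iff they gave it the identical score, so the
    number of agreeing pairs is sum_j r_ij (r_ij - 1) / 2.
    """
    counts = matrix.rating_counts()
    r = matrix.n_experts
    per = (counts * (counts - 1)).sum(axis=1) / (r * (r - 1))
    return _report("PWA", per.astype(float))


def clustered_pwa(matrix: RatingMatrix,
                  clusters_per_item: Sequence[ClusterSet]) -> IndexReport:
    """ac_i: pairs of experts landing in the same opinion cluster.

    For each item, sum over its clusters of m_j (m_j - 1), divided by
    r(r-1), where m_j counts the experts whose score falls inside cluster j.
    Scores outside every cluster contribute nothing.
    """
    r = matrix.n_experts
    memb = _cluster_member_counts(matrix, clusters_per_item)
    per = np.array([sum(m * (m - 1) for m in row) / (r * (r - 1)) for row in memb])
    return _report("CPWA", per)


def extremity_cpwa(matrix: RatingMatrix,
                   groups: ExtremeGroups = ExtremeGroups()) -> IndexReport:
    """acx_i: clustered pairwise agreement with the two extreme ranges as clusters."""
    if groups.upper_group[1] > matrix.scale_max:
        raise ValueError("extreme groups must lie within the scale")
    csum = matrix.rating_counts().cumsum(axis=1)
    r = matrix.n_experts
    (l_lo, l_hi), (u_lo, u_hi) = groups.lower_group, groups.upper_group
    low = csum[:, l_hi] - csum[:, l_lo - 1]
    up = csum[:, u_hi] - csum[:, u_lo - 1]
    per = (low * (low - 1) + up * (up - 1)) / (r * (r - 1))
    return _report("XCPWA", per.astype(float))


def mode_index(matrix: RatingMatrix) -> IndexReport:
    """s_i: share of experts on the item's most frequent score.

    Modal ties do not change the share; the modal score itself, were it
    reported, would be the lowest tied score.
    """
    counts = matrix.rating_counts()
    per = counts.max(axis=1) / matrix.n_experts
    return _report("M", per.astype(float))


def clustered_mode(matrix: RatingMatrix,
                   clusters_per_item: Sequence[ClusterSet]) -> IndexReport:
    """cs_i: share of experts inside the item's most populous cluster.

    Ties go to the cluster with the lower bound (the share is unaffected);
    an item with an empty cluster set scores 0.
    """
    r = matrix.n_experts
    memb = _cluster_member_counts(matrix, clusters_per_item)
    per = np.array([max(row, default=0) / r for row in memb])
    return _report("CM", per)


def iqr_index(matrix: RatingMatrix) -> IndexReport:
    """Per-item interquartile range, q_75 - q_25.

    Quantiles use linear interpolation between order statistics at rank
    1 + (r-1) m/100 (the classical 'linear' definition).  0 means the middle
    half of the panel sits on a single score; the maximum is scale_max - 1.
    """
    q25, q75 = np.percentile(matrix.scores, [25.0, 75.0], axis=0, method="linear")
    return _report("IQR", (q75 - q25).astype(float))


def iqr_consensus(matrix: RatingMatrix, threshold: float = 1.0) -> np.ndarray:
    """Boolean per-item consensus verdict: IQR_i <= threshold.

    The conventional reading of the IQR criterion — consensus is declared on
    an item when the middle 50% of ratings spans at most `threshold` scale
    points (default 1.0).
    """
    return iqr_index(matrix).per_item <= threshold


# ---------------------------------------------------------------------------
# Study-wide kappas
# ---------------------------------------------------------------------------

def _observed_and_chance(matrix: RatingMatrix) -> tuple[float, float, np.ndarray]:
    counts = matrix.rating_counts()
    n, r = matrix.n_items, matrix.n_experts
    p_obs = (float((counts * counts).sum()) - n * r) / (n * r * (r - 1))
    marg = counts.sum(axis=0) / (n * r)  # pooled share of each rating value
    return p_obs, float((marg * marg).sum()), counts


def fleiss_kappa(matrix: RatingMatrix) -> IndexReport:
    """Fleiss' multi-rater kappa over all items jointly.

    KF = (P - P_e) / (1 - P_e) with observed agreement
    P = (sum_ij r_ij^2 - nr) / (nr(r-1)) and chance agreement P_e the sum of
    squared pooled rating shares.  The degenerate all-identical matrix
    (P = P_e = 1) scores 1 by convention: perfect agreement is perfect
    consensus, not undefined.
    """
    p_obs, p_exp, _ = _observed_and_chance(matrix)
    if 1.0 - p_exp <= 0.0:
        return IndexReport("KF", 1.0)
    return IndexReport("KF", (p_obs - p_exp) / (1.0 - p_exp))


def conger_kappa(matrix: RatingMatrix) -> IndexReport:
    """Conger's multi-rater kappa over all items jointly.

    Starts from the same observed agreement P as Fleiss' kappa but shrinks
    the chance term by the between-expert variance of the per-rating
    marginals: P_e,C = P_e - sum_j s_j^2/(r-1), where
    s_j^2 = [r sum_k n_jk^2 - (sum_k n_jk)^2] / (n^2 r^2) and n_jk is the
    number of items expert k rated j.  Identical expert marginals give
    s_j^2 = 0 and KC = KF; otherwise KC >= KF whenever P < 1.
    """
    p_obs, p_exp, _ = _observed_and_chance(matrix)
    n, r, q = matrix.n_items, matrix.n_experts, matrix.scale_max
    # n_jk table via one bincount: flat index = rating * r + expert
    flat = (matrix.scores * r + np.arange(r, dtype=np.int64)[:, None]).ravel()
    njk = np.bincount(flat, minlength=(q + 1) * r).reshape(q + 1, r)
    row_sum = njk.sum(axis=1)
    s2 = (r * (njk * njk).sum(axis=1) - row_sum * row_sum) / (n * n * r * r)
    p_exp_c = p_exp - float(s2.sum()) / (r - 1)
    if 1.0 - p_exp_c <= 0.0:
        return IndexReport("KC", 1.0)
    return IndexReport("KC", (p_obs - p_exp_c) / (1.0 - p_exp_c))


# ---------------------------------------------------------------------------
# One-call evaluation of all nine indices
# ---------------------------------------------------------------------------

def compute_all(matrix: RatingMatrix,
                clusters_per_item: Sequence[ClusterSet] | None = None,
                clustering: ClusteringParams = ClusteringParams(),
                groups: ExtremeGroups | None = None) -> dict[str, IndexReport]:
    """Evaluate all nine indices on one ratings matrix.

    If no cluster sets are supplied they are identified from the matrix
    itself with `clustering`.  Returns reports keyed by index name in the
    canonical ``ALL_INDICES`` order.
    """
    if clusters_per_item is None:
        clusters_per_item = [
            identify_clusters(matrix.scores[:, i], clustering, matrix.scale_max)
            for i in range(matrix.n_items)
        ]
    if groups is None:
        span = max(1, min(3, matrix.scale_max // 3))
        groups = ExtremeGroups((1, span), (matrix.scale_max - span + 1, matrix.scale_max))
    reports = {
        "DM": de_moivre(matrix),
        "PWA": pairwise_agreement(matrix),
        "CPWA": clustered_pwa(matrix, clusters_per_item),
        "XCPWA": extremity_cpwa(matrix, groups),
        "KF": fleiss_kappa(matrix),
        "KC": conger_kappa(matrix),
        "M": mode_index(matrix),
        "CM": clustered_mode(matrix, clusters_per_item),
        "IQR": iqr_index(matrix),
    }
    return {name: reports[name] for name in ALL_INDICES}
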