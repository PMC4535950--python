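"""Three-round Delphi panel simulation with clustered opinion convergence.

Round 1 draws every expert's score for every question independently from
the discrete uniform distribution on the scale — maximal prior dissensus.
Each later round identifies the opinion clusters among the previous round's
scores for each question and moves every expert toward the mean of the
cluster nearest their own score, weighted by the Group Conformity Index
(GCI).  All randomness lives in round 1: given the round-1 matrix the later
rounds are deterministic.

The final round's matrix is the study outcome; the nine consensus indices
are evaluated on it, with the cluster-based indices using cluster sets
re-identified from the final round itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clusters import (Cluster, ClusteringParams, ClusterSet, _advance_item,
                       _identify)
from .indices import IndexReport, RatingMatrix, compute_all


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated Delphi study.

    Defaults are the baseline study design: 12 survey questions, 20 experts,
    GCI 0.5, a 1-10 ordinal scale, clusters of up to three scale points with
    a 0.5 secondary-cluster threshold, and three survey rounds.
    """

    n_items: int = 12
    n_experts: int = 20
    gci: float = 0.5
    scale_max: int = 10
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    n_rounds: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be at least 1")
        if self.n_experts < 2:
            raise ValueError("n_experts must be at least 2")
        if not 0.0 <= self.gci <= 1.0:
            raise ValueError("gci must lie in [0, 1]")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be at least 1")
        if self.clustering.cluster_width > self.scale_max:
            raise ValueError("cluster_width exceeds the rating scale")


@dataclass(frozen=True)
class StudyResult:
    """Everything produced by one simulated study.

    ``rounds[t]`` is the ratings matrix after round t+1; the last entry is
    the final-round matrix on which ``index_reports`` were computed, with
    ``final_cluster_sets`` identified from that final round.
    """

    config: SimulationConfig
    rounds: tuple[RatingMatrix, ...]
    final_cluster_sets: tuple[ClusterSet, ...]
    index_reports: dict[str, IndexReport]

    @property
    def final_round_matrix(self) -> RatingMatrix:
        return self.rounds[-1]

    @property
    def study_wide(self) -> dict[str, float]:
        """Study-wide value of each index on the final round."""
        return {name: rep.study_wide for name, rep in self.index_reports.items()}

    def to_dict(self) -> dict:
        return {
            "config": {
                "n_items": self.config.n_items,
                "n_experts": self.config.n_experts,
                "gci": self.config.gci,
                "scale_max": self.config.scale_max,
                "cluster_width": self.config.clustering.cluster_width,
                "secondary_threshold": self.config.clustering.secondary_threshold,
                "n_rounds": self.config.n_rounds,
                "seed": self.config.seed,
            },
            "rounds": [m.scores.tolist() for m in self.rounds],
            "final_cluster_sets": [cs.to_dicts() for cs in self.final_cluster_sets],
            "index_reports": {k: v.to_dict() for k, v in self.index_reports.items()},
        }


def generate_round1(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> RatingMatrix:
    """Round-1 ratings: i.i.d. discrete uniform on {1..scale_max}."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    scores = rng.integers(1, config.scale_max + 1,
                          size=(config.n_experts, config.n_items))
    return RatingMatrix(scores, config.scale_max)


def advance_round(matrix: RatingMatrix, config: SimulationConfig) -> RatingMatrix:
    """One Delphi round: cluster each item's ratings, converge every expert.

    Per item, clusters are identified among the current ratings and each
    expert's new score is the GCI-weighted pull toward the mean of their
    nearest cluster, rounded to the nearest scale point.  Deterministic.
    An item admitting no cluster (impossible under the modal-window rule,
    kept as a defensive fallback) is left unchanged.
    """
    q = matrix.scale_max
    v = config.clustering.cluster_width
    p = config.clustering.secondary_threshold
    cols = []
    for i in range(matrix.n_items):
        col = matrix.scores[:, i]
        counts = np.bincount(col, minlength=q + 1)
        found = _identify(counts, q, v, p)
        cols.append(_advance_item(col, found, config.gci, q))
    return RatingMatrix(np.stack(cols, axis=1), q)


def run_study(config: SimulationConfig,
              rng: np.random.Generator | None = None) -> StudyResult:
    """Run one full Delphi study and evaluate all nine indices.

    Chains `generate_round1` and ``n_rounds - 1`` `advance_round` steps, then
    identifies the final-round cluster sets and computes every index report
    on the final-round matrix.  Fully determined by ``(config, rng)``; when
    `rng` is omitted it is seeded from ``config.seed``.
    """
    matrix = generate_round1(config, rng)
    rounds = [matrix]
    for _ in range(config.n_rounds - 1):
        matrix = advance_round(matrix, config)
        rounds.append(matrix)
    q = config.scale_max
    v = config.clustering.cluster_width
    p = config.clustering.secondary_threshold
    cluster_sets = []
    for i in range(matrix.n_items):
        counts = np.bincount(matrix.scores[:, i], minlength=q + 1)
        found = _identify(counts, q, v, p)
        cluster_sets.append(ClusterSet(tuple(Cluster(*c) for c in found)))
    reports = compute_all(matrix, cluster_sets)
    return StudyResult(config, tuple(rounds), tuple(cluster_sets), reports)
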