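"""Unit and property tests for the nine consensus indices."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import delphisim as ds

from conftest import random_matrix


def column(*scores):
    return ds.RatingMatrix(np.asarray(scores, dtype=np.int64)[:, None])


matrices = st.integers(2, 8).flatmap(
    lambda r: st.integers(1, 5).flatmap(
        lambda n: st.lists(
            st.lists(st.integers(1, 10), min_size=n, max_size=n),
            min_size=r, max_size=r)))


def to_matrix(rows):
    return ds.RatingMatrix(np.asarray(rows, dtype=np.int64))


# ---------------------------------------------------------------------------
# Worked examples, frozen from hand computation
# ---------------------------------------------------------------------------

class TestWorkedExamples:
    @pytest.mark.parametrize("scores,expected", [
        ((5, 5, 5), 1.0),
        ((5, 5, 7), 0.0),
    ])
    def test_de_moivre_single_item(self, scores, expected):
        assert ds.de_moivre(column(*scores)).study_wide == expected

    def test_de_moivre_mixed_items(self):
        m = ds.RatingMatrix(np.array([[4, 2], [4, 5], [4, 9]]))
        rep = ds.de_moivre(m)
        assert list(rep.per_item) == [1.0, 0.0]
        assert rep.study_wide == 0.5

    @pytest.mark.parametrize("scores,expected", [
        ((5, 5, 7), 1 / 3),   # one agreeing pair of three
        ((4, 4, 4, 4), 1.0),
        ((1, 5, 9), 0.0),
    ])
    def test_pairwise_agreement(self, scores, expected):
        assert ds.pairwise_agreement(column(*scores)).study_wide == pytest.approx(expected)

    def test_clustered_pwa_bimodal(self, bimodal):
        clusters = [ds.identify_clusters(bimodal.scores[:, 0])]
        # memberships 3 in [1,3] and 5 in [8,10]: (3*2 + 5*4) / (9*8)
        assert ds.clustered_pwa(bimodal, clusters).study_wide == pytest.approx(26 / 72)

    def test_clustered_pwa_edge_cases(self):
        m = column(4, 4, 4)
        full = [ds.ClusterSet((ds.Cluster(3, 5, 3, 4.0),))]
        assert ds.clustered_pwa(m, full).study_wide == 1.0
        elsewhere = [ds.ClusterSet((ds.Cluster(8, 10, 1, 9.0),))]
        assert ds.clustered_pwa(m, elsewhere).study_wide == 0.0

    def test_extremity_cpwa(self, bimodal):
        # same extreme memberships (3 low, 5 high) as the clustered example
        assert ds.extremity_cpwa(bimodal).study_wide == pytest.approx(26 / 72)
        assert ds.extremity_cpwa(column(5, 5, 5, 5)).study_wide == 0.0
        assert ds.extremity_cpwa(column(10, 10, 10)).study_wide == 1.0

    @pytest.mark.parametrize("scores,expected", [
        ((5, 5, 7), 2 / 3),
        ((5, 5, 7, 7), 0.5),  # tied modes: either tie gives the same share
        ((6, 6, 6), 1.0),
    ])
    def test_mode_index(self, scores, expected):
        assert ds.mode_index(column(*scores)).study_wide == pytest.approx(expected)

    def test_clustered_mode_bimodal(self, bimodal):
        clusters = [ds.identify_clusters(bimodal.scores[:, 0])]
        assert ds.clustered_mode(bimodal, clusters).study_wide == pytest.approx(5 / 9)

    def test_clustered_mode_unanimous_and_empty(self):
        m = column(4, 4, 4)
        one = [ds.ClusterSet((ds.Cluster(3, 5, 3, 4.0),))]
        assert ds.clustered_mode(m, one).study_wide == 1.0
        assert ds.clustered_mode(m, [ds.ClusterSet(())]).study_wide == 0.0

    @pytest.mark.parametrize("scores,expected", [
        ((4, 4, 4, 4), 0.0),
        ((1, 2, 3, 4), 1.5),    # q25 = 1.75, q75 = 3.25 by linear interpolation
        ((2, 2, 2, 9), 1.75),   # q25 = 2, q75 = 3.75
    ])
    def test_iqr(self, scores, expected):
        assert ds.iqr_index(column(*scores)).study_wide == pytest.approx(expected)

    def test_iqr_consensus_predicate(self):
        m = ds.RatingMatrix(np.array([[4, 1], [4, 2], [4, 3], [5, 4]]))
        assert list(ds.iqr_consensus(m, threshold=1.0)) == [True, False]


class TestKappas:
    def test_fleiss_two_unanimous_items(self):
        # item 1 all score 4, item 2 all score 9: P = 1, P_e = 0.5
        m = ds.RatingMatrix(np.array([[4, 9]] * 3))
        assert ds.fleiss_kappa(m).study_wide == pytest.approx(1.0)
        assert ds.conger_kappa(m).study_wide == pytest.approx(1.0)

    def test_fleiss_single_item_split(self):
        # P = 1/3, P_e = 5/9 -> KF = -0.5
        assert ds.fleiss_kappa(column(5, 5, 7)).study_wide == pytest.approx(-0.5)

    def test_degenerate_all_identical_is_one(self):
        m = ds.RatingMatrix(np.full((4, 3), 7))
        assert ds.fleiss_kappa(m).study_wide == 1.0
        assert ds.conger_kappa(m).study_wide == 1.0

    def test_conger_equals_fleiss_with_identical_marginals(self):
        # both experts rate item1 -> 1, item2 -> 2: expert marginals coincide
        m = ds.RatingMatrix(np.array([[1, 2], [1, 2]]))
        assert ds.conger_kappa(m).study_wide == pytest.approx(
            ds.fleiss_kappa(m).study_wide) == pytest.approx(1.0)
        # shifted-rater design with identical per-rating marginals, P < 1
        m2 = ds.RatingMatrix(np.array([[1, 2], [2, 1]]))
        assert ds.conger_kappa(m2).study_wide == pytest.approx(
            ds.fleiss_kappa(m2).study_wide)

    def test_conger_at_least_fleiss(self, rng):
        for _ in range(50):
            m = random_matrix(rng)
            kf = ds.fleiss_kappa(m).study_wide
            kc = ds.conger_kappa(m).study_wide
            assert kc >= kf - 1e-12

    def test_kappas_have_no_per_item_values(self):
        m = column(5, 5, 7)
        assert ds.fleiss_kappa(m).per_item is None
        assert ds.conger_kappa(m).per_item is None


# ---------------------------------------------------------------------------
# Brute-force oracle for pairwise agreement
# ---------------------------------------------------------------------------

def pwa_by_pair_enumeration(matrix):
    """Independent oracle: count agreeing unordered expert pairs directly."""
    r = matrix.n_experts
    out = []
    for i in range(matrix.n_items):
        col = matrix.scores[:, i]
        agree = sum(1 for a, b in itertools.combinations(range(r), 2)
                    if col[a] == col[b])
        out.append(agree / (r * (r - 1) / 2))
    return np.array(out)


def test_pwa_matches_pair_enumeration(rng):
    for _ in range(40):
        m = random_matrix(rng)
        np.testing.assert_allclose(ds.pairwise_agreement(m).per_item,
                                   pwa_by_pair_enumeration(m))


# ---------------------------------------------------------------------------
# Invariants over randomized matrices
# ---------------------------------------------------------------------------

@settings(max_examples=60, derandomize=True, deadline=None)
@given(matrices)
def test_index_ranges_and_aggregation(rows):
    m = to_matrix(rows)
    reports = ds.compute_all(m)
    for name in ("DM", "PWA", "CPWA", "XCPWA", "M", "CM"):
        rep = reports[name]
        assert np.all(rep.per_item >= 0) and np.all(rep.per_item <= 1)
        assert rep.study_wide == pytest.approx(rep.per_item.mean())
    assert np.all(reports["IQR"].per_item >= 0)
    assert np.all(reports["IQR"].per_item <= m.scale_max - 1)
    assert reports["KF"].study_wide <= 1 + 1e-12
    assert reports["KC"].study_wide <= 1 + 1e-12
    # the modal cluster holds at least the raters of the modal score alone
    assert np.all(reports["CM"].per_item >= reports["M"].per_item - 1e-12)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(matrices, st.randoms(use_true_random=False))
def test_expert_and_item_permutation_invariance(rows, pyrandom):
    m = to_matrix(rows)
    base = {k: v.study_wide for k, v in ds.compute_all(m).items()}
    experts = list(range(m.n_experts))
    items = list(range(m.n_items))
    pyrandom.shuffle(experts)
    pyrandom.shuffle(items)
    shuffled = ds.RatingMatrix(m.scores[np.ix_(experts, items)], m.scale_max)
    new = {k: v.study_wide for k, v in ds.compute_all(shuffled).items()}
    for name in ds.ALL_INDICES:
        assert new[name] == pytest.approx(base[name]), name


def test_unanimity_implies_full_consensus():
    m = ds.make_fixture("unanimous-4")
    reports = ds.compute_all(m)
    for name in ("DM", "PWA", "M", "CM"):
        assert reports[name].study_wide == pytest.approx(1.0)
    assert reports["IQR"].study_wide == 0.0


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

class TestValidation:
    def test_single_expert_rejected(self):
        with pytest.raises(ValueError):
            ds.RatingMatrix(np.array([[5, 7]]))

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError):
            ds.RatingMatrix(np.array([[0], [5]]))
        with pytest.raises(ValueError):
            ds.RatingMatrix(np.array([[5], [11]]))

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            ds.RatingMatrix(np.array([[5.5], [7.0]]))

    def test_overlapping_clusters_rejected(self):
        with pytest.raises(ValueError):
            ds.ClusterSet((ds.Cluster(1, 3, 2, 2.0), ds.Cluster(3, 5, 2, 4.0)))

    def test_cluster_count_mismatch_rejected(self, bimodal):
        with pytest.raises(ValueError):
            ds.clustered_pwa(bimodal, [])

    def test_overlapping_extreme_groups_rejected(self):
        with pytest.raises(ValueError):
            ds.ExtremeGroups((1, 5), (5, 10))
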