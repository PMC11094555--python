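"""Label-vector alignment, similarity normalization and clustering order."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from genectx import (
    AlignParams,
    EmptyNeighborhoodError,
    Gene,
    LabelVector,
    Neighborhood,
    NeighborhoodSet,
    NothingToClusterError,
    cluster_neighborhoods,
    label_vector,
    local_align,
    similarity,
)

from ._oracles import brute_force_local_score
from .conftest import random_label_vector

NOREV = AlignParams(try_reverse=False)


def vec(*entries, anchor=0):
    return LabelVector(tuple(frozenset(e) for e in entries), anchor)


def singletons(*labels, anchor=0):
    return vec(*[{l} for l in labels], anchor=anchor)


class TestLabelVector:
    def _nbh(self):
        genes = [
            Gene("a", "c", 100, 200, "+", labels={"pfam": {"PF1"}}),
            Gene("b", "c", 300, 400, "+"),
            Gene("d", "c", 500, 600, "+", labels={"pfam": {"PF2", "PF3"},
                                                  "kegg": {"K1"}}),
        ]
        return Neighborhood("n1", "b", genes, 1, 700)

    def test_projection_and_anchor_index(self):
        lv = label_vector(self._nbh(), "pfam")
        assert lv.entries == (frozenset({"PF1"}), frozenset(), frozenset({"PF2", "PF3"}))
        assert lv.anchor_index == 1

    def test_absent_namespace_all_empty(self):
        lv = label_vector(self._nbh(), "tigrfam")
        assert all(not e for e in lv.entries)

    def test_namespace_switch_preserves_shape(self):
        a, b = label_vector(self._nbh(), "kegg"), label_vector(self._nbh(), "pfam")
        assert len(a) == len(b) and a.anchor_index == b.anchor_index


class TestLocalAlign:
    def test_perfect_self_alignment(self):
        u = singletons("A", "B", "C", "D")
        r = local_align(u, u, NOREV)
        assert r.score == 4.0
        assert r.aligned_pairs == ((0, 0), (1, 1), (2, 2), (3, 3))

    def test_disjoint_vectors_floor_zero(self):
        r = local_align(singletons("A", "B"), singletons("X", "Y"), NOREV)
        assert r.score == 0.0 and r.aligned_pairs == ()

    def test_shared_block_scores_two(self):
        u = singletons("A", "B", "C", "D")
        v = singletons("X", "B", "C", "Y")
        r = local_align(u, v, NOREV)
        assert r.score == 2.0
        assert r.aligned_pairs == ((1, 1), (2, 2))

    def test_reversal_recovers_inverted_cluster(self):
        u = singletons("A", "B", "C")
        v = singletons("C", "B", "A")
        r = local_align(u, v, AlignParams(try_reverse=True))
        assert r.score == 3.0 and r.reversed
        assert local_align(u, v, NOREV).score < 3.0

    def test_empty_vector_rejected(self):
        with pytest.raises(EmptyNeighborhoodError, match="empty neighborhood"):
            local_align(LabelVector((), 0), singletons("A"), NOREV)

    def test_empty_sets_never_match_each_other(self):
        u = vec(set(), set())
        assert local_align(u, u, NOREV).score == 0.0

    def test_multi_label_intersection_matches(self):
        u = vec({"PF1", "PF2"})
        v = vec({"PF2", "PF9"})
        assert local_align(u, v, NOREV).score == 1.0

    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        u = LabelVector(tuple(random_label_vector(rng)), 0)
        v = LabelVector(tuple(random_label_vector(rng)), 0)
        expected = brute_force_local_score(list(u.entries), list(v.entries))
        assert local_align(u, v, NOREV).score == expected

    @given(seed=st.integers(0, 5000))
    def test_symmetry_and_bound(self, seed):
        rng = np.random.default_rng(seed)
        u = LabelVector(tuple(random_label_vector(rng)), 0)
        v = LabelVector(tuple(random_label_vector(rng)), 0)
        for p in (NOREV, AlignParams(try_reverse=True)):
            a, b = local_align(u, v, p), local_align(v, u, p)
            assert a.score == b.score
            assert a.score <= p.match_score * min(len(u), len(v))
            i_seq = [i for i, _ in a.aligned_pairs]
            j_seq = [j for _, j in a.aligned_pairs]
            assert i_seq == sorted(set(i_seq)) and j_seq == sorted(set(j_seq))

    @given(seed=st.integers(0, 2000))
    def test_appending_shared_label_never_decreases_score(self, seed):
        rng = np.random.default_rng(seed)
        base_u = random_label_vector(rng)
        base_v = random_label_vector(rng)
        u1 = LabelVector(tuple(base_u + [frozenset({"ZZZ"})]), 0)
        v1 = LabelVector(tuple(base_v + [frozenset({"ZZZ"})]), 0)
        u0 = LabelVector(tuple(base_u), 0)
        v0 = LabelVector(tuple(base_v), 0)
        s0 = local_align(u0, v0, NOREV).score
        # any old alignment is still available, and Z-Z alone scores 1
        assert local_align(u1, v1, NOREV).score >= max(s0, 1.0)

    @given(n=st.integers(1, 6))
    def test_appending_shared_label_at_aligned_ends_adds_exactly_match(self, n):
        # identical fully-annotated vectors: the optimum ends at both ends,
        # so a fresh shared terminal label extends it by exactly one match
        labels = [f"L{i}" for i in range(n)]
        u0 = singletons(*labels)
        u1 = singletons(*(labels + ["ZZZ"]))
        s0 = local_align(u0, u0, NOREV).score
        assert local_align(u1, u1, NOREV).score == s0 + 1.0

    def test_anchored_mode_forces_anchor_pair(self):
        u = singletons("A", "B", "C", anchor=0)
        v = singletons("X", "B", "C", anchor=0)
        free = local_align(u, v, NOREV)
        anchored = local_align(u, v, AlignParams(try_reverse=False, anchored=True))
        assert free.score == 2.0
        assert (0, 0) in anchored.aligned_pairs
        assert anchored.score == 1.0  # A-X mismatch then B,C matches


class TestSimilarity:
    def test_self_similarity_is_one(self):
        u = vec({"A"}, set(), {"B"})
        assert similarity(u, u) == 1.0

    def test_disjoint_is_zero(self):
        assert similarity(singletons("A", "B"), singletons("X", "Y")) == 0.0

    def test_half_overlap(self):
        u = singletons("A", "B", "C", "D")
        v = singletons("X", "B", "C", "Y")
        assert similarity(u, v) == 0.5

    def test_unannotated_pair_defined_zero(self):
        u = vec(set(), set())
        assert similarity(u, u) == 0.0

    @given(seed=st.integers(0, 3000))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        u = LabelVector(tuple(random_label_vector(rng)), 0)
        v = LabelVector(tuple(random_label_vector(rng)), 0)
        s = similarity(u, v)
        assert s == similarity(v, u)
        assert 0.0 <= s <= 1.0


def _nbh_from_labels(nid, labels):
    genes = [
        Gene(f"{nid}_g{i}", "c", 100 + 1000 * i, 500 + 1000 * i, "+",
             labels={"pfam": {lab}} if lab else {})
        for i, lab in enumerate(labels)
    ]
    return Neighborhood(nid, f"{nid}_g0", genes, 1, 100 + 1000 * len(labels))


class TestClustering:
    def test_single_neighborhood(self):
        s = NeighborhoodSet([_nbh_from_labels("n0", ["A", "B"])], "pfam")
        out = cluster_neighborhoods(s)
        assert out.order == [0]
        assert out.distance_matrix.shape == (1, 1) and out.distance_matrix[0, 0] == 0

    def test_empty_set_rejected(self):
        with pytest.raises(NothingToClusterError, match="nothing to cluster"):
            cluster_neighborhoods(NeighborhoodSet([], "pfam"))

    def test_identical_pair_adjacent(self):
        s = NeighborhoodSet(
            [
                _nbh_from_labels("n0", ["A", "B", "C"]),
                _nbh_from_labels("n1", ["X", "Y", "Z"]),
                _nbh_from_labels("n2", ["A", "B", "C"]),
            ],
            "pfam",
        )
        order = cluster_neighborhoods(s).order
        assert abs(order.index(0) - order.index(2)) == 1

    def test_duplicated_inputs_pairwise_adjacent(self):
        base = [["A", "B"], ["C", "D"], ["E", "F"]]
        s = NeighborhoodSet(
            [_nbh_from_labels(f"n{i}", labs)
             for i, labs in enumerate(base + base)],
            "pfam",
        )
        order = cluster_neighborhoods(s).order
        for i in range(3):
            assert abs(order.index(i) - order.index(i + 3)) == 1

    def test_deterministic_across_runs(self):
        s = NeighborhoodSet(
            [_nbh_from_labels(f"n{i}", ["A", "B"][: 1 + i % 2] + [f"L{i % 3}"])
             for i in range(8)],
            "pfam",
        )
        a = cluster_neighborhoods(s)
        b = cluster_neighborhoods(s)
        assert a.order == b.order
        assert np.array_equal(a.distance_matrix, b.distance_matrix)

    def test_distance_matrix_properties(self, small_set):
        out = cluster_neighborhoods(small_set)
        D = out.distance_matrix
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)
        assert np.all((D >= 0) & (D <= 1))
        assert sorted(out.order) == list(range(len(small_set)))
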