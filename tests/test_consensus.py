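"""Partition similarity, bootstrap stability, and consensus grouping."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stratakit.consensus import (
    JaccardMatrix,
    bootstrap_stability,
    build_jaccard_matrix,
    filter_robust,
    group_and_represent,
    make_embedding_reclusterer,
    partition_jaccard,
)
from stratakit.engine import StratificationCandidate


def jaccard_by_enumeration(a, b) -> float:
    """Independent oracle: explicit double loop over all patient pairs."""
    n = len(a)
    n11 = n10 = n01 = 0
    for i, j in combinations(range(n), 2):
        in_a = a[i] == a[j]
        in_b = b[i] == b[j]
        n11 += in_a and in_b
        n10 += in_a and not in_b
        n01 += in_b and not in_a
    if n11 + n10 + n01 == 0:
        return 1.0
    return n11 / (n11 + n10 + n01)


def _candidate(name, assignment, depth=1, code="a"):
    return StratificationCandidate(
        name=name, depth=depth, code=code, distance="correlation", method="kmeans",
        k=len(np.unique(assignment)), assignment=np.asarray(assignment),
    )


class TestPartitionJaccard:
    def test_identical_partitions_score_one(self):
        a = np.array([0, 0, 1, 1, 2])
        assert partition_jaccard(a, a) == 1.0

    def test_invariant_to_cluster_relabeling(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = (a + 1) % 3
        assert partition_jaccard(a, b) == 1.0

    def test_worked_example_quarter(self):
        # [1,1,2,2] vs [1,1,1,2]: co-pairs {12,34} vs {12,13,23} -> 1/4
        assert partition_jaccard([1, 1, 2, 2], [1, 1, 1, 2]) == pytest.approx(0.25)

    def test_all_singletons_vs_itself(self):
        a = np.arange(6)
        assert partition_jaccard(a, a) == 1.0

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_exhaustive_enumeration(self, data):
        n = data.draw(st.integers(min_value=2, max_value=12))
        a = np.array(data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n)))
        b = np.array(data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n)))
        assert partition_jaccard(a, b) == pytest.approx(jaccard_by_enumeration(a, b))
        assert partition_jaccard(a, b) == pytest.approx(partition_jaccard(b, a))


class TestBootstrapStability:
    def test_point_mass_clusters_are_fully_stable(self):
        rng = np.random.default_rng(0)
        X = rng.normal(scale=0.05, size=(40, 3))
        X[20:] += 10.0
        assignment = np.array([0] * 20 + [1] * 20)
        recluster = make_embedding_reclusterer(X, "d", 2)
        res = bootstrap_stability(
            assignment, recluster, n_boot=20, seed_seq=np.random.SeedSequence(1)
        )
        assert res.stability == pytest.approx(1.0)
        assert all(j == pytest.approx(1.0) for j in res.per_cluster_jaccard)

    def test_structureless_noise_is_unstable(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        assignment = make_embedding_reclusterer(X, "a", 2)(np.arange(60), seed=0)
        recluster = make_embedding_reclusterer(X, "a", 2)
        res = bootstrap_stability(
            assignment, recluster, n_boot=20, seed_seq=np.random.SeedSequence(2)
        )
        assert res.stability < 0.85

    def test_failed_replicates_count_as_zero(self):
        assignment = np.array([0, 0, 1, 1] * 5)

        def broken(idx, seed):
            raise RuntimeError("cannot recluster")

        res = bootstrap_stability(
            assignment, broken, n_boot=5, seed_seq=np.random.SeedSequence(3)
        )
        assert res.stability == 0.0

    def test_stability_threshold_is_inclusive(self):
        # retained iff stability >= threshold ("below" is excluded)
        rng = np.random.default_rng(4)
        X = rng.normal(scale=0.05, size=(30, 3))
        X[15:] += 10.0
        cand = _candidate("cuts_d_1", np.array([0] * 15 + [1] * 15), code="d")

        def factory(c):
            return make_embedding_reclusterer(X, "d", 2)

        robust, table = filter_robust([cand], factory, n_boot=10, threshold=1.0, seed=0)
        assert cand.stability == pytest.approx(1.0)
        assert [c.name for c in robust] == ["cuts_d_1"]  # exactly at threshold

    def test_duplicated_cohort_does_not_destabilise(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        X[15:] += 4.0
        X2 = np.repeat(X, 2, axis=0)
        a1 = make_embedding_reclusterer(X, "d", 2)(np.arange(30), seed=0)
        a2 = make_embedding_reclusterer(X2, "d", 2)(np.arange(60), seed=0)
        r1 = bootstrap_stability(
            a1, make_embedding_reclusterer(X, "d", 2), n_boot=15,
            seed_seq=np.random.SeedSequence(6),
        )
        r2 = bootstrap_stability(
            a2, make_embedding_reclusterer(X2, "d", 2), n_boot=15,
            seed_seq=np.random.SeedSequence(6),
        )
        assert r2.stability >= r1.stability - 0.05


class TestJaccardMatrix:
    def test_single_candidate(self):
        jm = build_jaccard_matrix([_candidate("only", [0, 0, 1, 1])])
        assert jm.values.shape == (1, 1) and jm.values[0, 0] == 1.0

    def test_duplicated_candidates_fill_off_diagonal_with_ones(self):
        a = [0, 0, 1, 1, 2]
        jm = build_jaccard_matrix([_candidate("x", a), _candidate("y", a)])
        assert np.allclose(jm.values, 1.0)

    def test_annotations_carry_combo_metadata(self):
        jm = build_jaccard_matrix([_candidate("cuts_a_3", [0, 1, 0, 1], depth=3)])
        row = jm.annotations.loc["cuts_a_3"]
        assert row["distance"] == "correlation" and row["depth"] == 3


class TestGroupAndRepresent:
    def _block_matrix(self):
        # two blocks: within-similarity >= 0.95, across 0.2
        names = ["n1", "n2", "n3", "m1", "m2"]
        J = np.full((5, 5), 0.2)
        J[:3, :3] = 0.96
        J[3:, 3:] = 0.95
        np.fill_diagonal(J, 1.0)
        return JaccardMatrix(names=names, values=J)

    def test_identical_candidates_form_one_group(self):
        a = [0, 0, 1, 1]
        jm = build_jaccard_matrix([_candidate("x", a), _candidate("y", a)])
        groups = group_and_represent(jm, threshold=0.9)
        assert len(groups) == 1 and groups[0].size == 2

    def test_two_blocks_split_at_high_threshold(self):
        groups = group_and_represent(self._block_matrix(), threshold=0.9)
        assert sorted(g.size for g in groups) == [2, 3]
        for g in groups:  # blocks must not mix
            assert len({m[0] for m in g.members}) == 1

    def test_within_group_pairs_respect_threshold(self):
        jm = self._block_matrix()
        for thr in (0.5, 0.9, 0.96):
            for g in group_and_represent(jm, threshold=thr):
                idx = [jm.names.index(m) for m in g.members]
                for i, j in combinations(idx, 2):
                    assert jm.values[i, j] >= thr - 1e-9

    def test_raising_threshold_never_merges_groups(self):
        rng = np.random.default_rng(7)
        base = rng.random((8, 8))
        J = (base + base.T) / 2
        np.fill_diagonal(J, 1.0)
        jm = JaccardMatrix(names=[f"c{i}" for i in range(8)], values=J)
        counts = [len(group_and_represent(jm, threshold=t)) for t in (0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts)

    def test_representative_maximises_mean_similarity(self):
        names = ["a", "b", "c"]
        J = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.95], [0.8, 0.95, 1.0]])
        jm = JaccardMatrix(names=names, values=J)
        (group,) = group_and_represent(jm, threshold=0.7)
        assert group.representative == "b"  # mean sims: a .85, b .925, c .875

    def test_representative_tie_breaks_lexicographically(self):
        names = ["z", "a"]
        jm = JaccardMatrix(names=names, values=np.array([[1.0, 0.8], [0.8, 1.0]]))
        (group,) = group_and_represent(jm, threshold=0.7)
        assert group.representative == "a"

    def test_min_size_filters_singletons(self):
        jm = self._block_matrix()
        groups = group_and_represent(jm, threshold=0.99, min_size=2)
        assert all(g.size >= 2 for g in groups)
        assert group_and_represent(jm, threshold=0.99, min_size=1)
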