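"""Distances, clustering methods, validation indices and the sweep."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from stratakit.consensus import partition_jaccard
from stratakit.engine import (
    avg_silhouette,
    choose_k,
    cluster_once,
    dunn_index,
    pairwise_distance,
    run_stratification_process,
    wb_ratio,
)
from stratakit.reduction import Embedding


def _blob_embedding(n=60, sep=8.0, seed=0, depth=1, dims=3):
    """Two separated Gaussian blobs with distinct row-profile shapes.

    The anchors differ both in location (for Euclidean/Gower methods) and
    in shape (for correlation-geometry methods).
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    anchor_a = sep * np.array([1.0 if i % 2 == 0 else -1.0 for i in range(dims)])
    anchor_b = sep * np.array([-1.0 if i % 2 == 0 else 1.0 for i in range(dims)])
    X = rng.normal(size=(n, dims))
    X[:half] += anchor_a
    X[half:] += anchor_b
    truth = np.array([0] * half + [1] * (n - half))
    matrix = pd.DataFrame(X, columns=[f"c{i}" for i in range(dims)])
    return Embedding(depth=depth, groups=[[c] for c in matrix.columns], matrix=matrix), truth


class TestPairwiseDistance:
    def test_identical_rows_are_at_distance_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (4, 1))
        X += np.arange(4)[:, None] * 0  # identical rows
        for metric in ("correlation", "gower"):
            if metric == "gower":
                # add one distinct row so columns are not constant
                Y = np.vstack([X, [4.0, 5.0, 6.0]])
                D = pairwise_distance(Y, metric)
                assert np.allclose(D[:4, :4], 0.0)
            else:
                D = pairwise_distance(X, metric)
                assert np.allclose(D, 0.0)

    def test_exact_negative_profiles_have_correlation_distance_two(self):
        X = np.array([[1.0, 0.0, -1.0], [-1.0, 0.0, 1.0]])
        D = pairwise_distance(X, "correlation")
        assert D[0, 1] == pytest.approx(2.0)

    def test_gower_matches_hand_computation(self):
        X = np.array(
            [[0, 2, 10], [4, 2, 10], [2, 0, 30], [4, 4, 50]], dtype=float
        )
        D = pairwise_distance(X, "gower")
        ranges = X.max(axis=0) - X.min(axis=0)
        for i, j in combinations(range(4), 2):
            expected = np.mean(np.abs(X[i] - X[j]) / ranges)
            assert D[i, j] == pytest.approx(expected)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_constant_patient_profile_rejected_under_correlation(self):
        X = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [3.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="zero variance"):
            pairwise_distance(X, "correlation")


class TestClusterOnce:
    @pytest.mark.parametrize("code", list("abcd"))
    def test_point_masses_separate_perfectly(self, code):
        emb, truth = _blob_embedding(n=40, sep=50.0, seed=1)
        labels = cluster_once(emb.matrix.to_numpy(), code, k=2, seed=0)
        assert partition_jaccard(labels, truth) == pytest.approx(1.0)

    @pytest.mark.parametrize("code", list("abcd"))
    def test_same_seed_same_assignment(self, code):
        emb, _ = _blob_embedding(n=30, sep=3.0, seed=2)
        X = emb.matrix.to_numpy()
        a = cluster_once(X, code, k=3, seed=42)
        b = cluster_once(X, code, k=3, seed=42)
        assert np.array_equal(a, b)

    def test_pam_matches_exhaustive_medoid_search(self):
        # independent oracle: enumerate every medoid set and its cost
        from stratakit._pam import pam

        for seed in range(10):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(6, 2))
            D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            for k in (2, 3):
                labels, medoids = pam(D, k, return_medoids=True)
                cost = D[np.asarray(medoids)].min(axis=0).sum()
                best = min(
                    D[list(s)].min(axis=0).sum() for s in combinations(range(6), k)
                )
                assert cost == pytest.approx(best)
                assert len(np.unique(labels)) == k


class TestIndices:
    def _four_point_D(self):
        pts = np.array([0.0, 0.1, 10.0, 10.1])
        return np.abs(pts[:, None] - pts[None, :]), np.array([0, 0, 1, 1])

    def test_wb_ratio_tight_far_clusters(self):
        # within pairs at 0.1, between pairs at 10 -> ratio 0.01
        D = np.array(
            [
                [0, 0.1, 10, 10],
                [0.1, 0, 10, 10],
                [10, 10, 0, 0.1],
                [10, 10, 0.1, 0],
            ]
        )
        assert wb_ratio(np.array([0, 0, 1, 1]), D) == pytest.approx(0.01)

    def test_wb_ratio_degenerate_identical_points(self):
        D = np.zeros((4, 4))
        with pytest.warns(UserWarning, match="degenerate"):
            assert wb_ratio(np.array([0, 0, 1, 1]), D) == 0.0

    def test_wb_ratio_near_one_for_random_labels(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 5))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        labels = rng.integers(0, 3, size=80)
        assert wb_ratio(labels, D) == pytest.approx(1.0, abs=0.1)

    def test_dunn_hand_value(self):
        D, labels = self._four_point_D()
        # min inter = 9.9, max diameter = 0.1
        assert dunn_index(labels, D) == pytest.approx(99.0)

    def test_dunn_singletons_get_infinity(self):
        D, _ = self._four_point_D()
        assert dunn_index(np.arange(4), D) == np.inf

    def test_merging_separated_clusters_lowers_dunn(self):
        D, labels = self._four_point_D()
        merged = np.array([0, 0, 0, 1])
        assert dunn_index(merged, D) < dunn_index(labels, D)

    def test_silhouette_point_masses_near_one(self):
        D = np.array(
            [
                [0, 0.0, 10, 10],
                [0.0, 0, 10, 10],
                [10, 10, 0, 0.0],
                [10, 10, 0.0, 0],
            ]
        )
        assert avg_silhouette(np.array([0, 0, 1, 1]), D) == pytest.approx(1.0)

    def test_silhouette_hand_value(self):
        D, labels = self._four_point_D()
        # a_i = 0.1 for all; b = [10.05, 9.95, 9.95, 10.05]
        expected = np.mean([(b - 0.1) / b for b in (10.05, 9.95, 9.95, 10.05)])
        assert avg_silhouette(labels, D) == pytest.approx(expected)

    def test_silhouette_random_labels_near_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 4))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        labels = rng.integers(0, 2, size=100)
        assert abs(avg_silhouette(labels, D)) < 0.05

    @pytest.mark.parametrize("index", [wb_ratio, dunn_index, avg_silhouette])
    def test_indices_invariant_to_label_permutation(self, index):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        labels = rng.integers(0, 3, size=30)
        permuted = (labels + 1) % 3
        assert index(labels, D) == pytest.approx(index(permuted, D))


class TestChooseK:
    def _table(self, wb, dunn, sil, ks=(2, 3, 4)):
        return pd.DataFrame(
            {"wb_ratio": wb, "dunn": dunn, "silhouette": sil}, index=pd.Index(ks, name="k")
        )

    def test_unanimous_vote(self):
        t = self._table([0.9, 0.1, 0.5], [1, 9, 2], [0.1, 0.9, 0.3])
        assert choose_k(t) == 3

    def test_majority_vote(self):
        t = self._table([0.1, 0.5, 0.9], [1, 9, 2], [0.1, 0.9, 0.3])
        assert choose_k(t) == 3

    def test_three_way_tie_breaks_to_smallest_k(self):
        t = self._table([0.1, 0.5, 0.9], [1, 9, 2], [0.1, 0.3, 0.9])
        assert choose_k(t) == 2


class TestSweep:
    def test_one_embedding_yields_four_named_candidates(self):
        emb, _ = _blob_embedding(n=40, sep=6.0, seed=6)
        cands = run_stratification_process([emb], seed=0)
        assert [c.name for c in cands] == ["cuts_a_1", "cuts_b_1", "cuts_c_1", "cuts_d_1"]
        assert all(not c.failed for c in cands)

    def test_separated_blobs_choose_k_two_for_all_combos(self):
        hits = 0
        total = 0
        for seed in range(5):
            emb, _ = _blob_embedding(n=60, sep=8.0, seed=seed, depth=2, dims=4)
            for c in run_stratification_process([emb], seed=seed):
                total += 1
                hits += int(c.k == 2)
        assert hits / total >= 0.95

    def test_candidate_count_is_embeddings_times_combos(self):
        embs = [_blob_embedding(n=30, sep=4.0, seed=s, depth=s + 1)[0] for s in range(3)]
        cands = run_stratification_process(embs, seed=1)
        assert len(cands) == 12

    def test_rerun_with_same_seed_is_identical_across_worker_counts(self):
        embs = [_blob_embedding(n=30, sep=2.0, seed=s, depth=s + 1, dims=3)[0] for s in range(2)]
        runs = [
            run_stratification_process(embs, seed=9, n_jobs=w) for w in (1, 4)
        ]
        for a, b in zip(*runs):
            assert a.name == b.name and a.k == b.k
            assert np.array_equal(a.assignment, b.assignment)

    def test_failed_cell_is_flagged_not_raised(self):
        # a constant patient row makes correlation distance undefined; the
        # sweep must flag that cell and still evaluate the Gower cells
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 3))
        X[0] = 1.0  # zero-variance profile
        matrix = pd.DataFrame(X, columns=["u", "v", "w"])
        emb = Embedding(depth=1, groups=[["u"], ["v"], ["w"]], matrix=matrix)
        cands = run_stratification_process([emb], seed=0)
        by_code = {c.code: c for c in cands}
        assert len(cands) == 4
        assert by_code["a"].failed and "zero variance" in by_code["a"].error
        assert by_code["b"].failed
        assert not by_code["c"].failed and not by_code["d"].failed
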