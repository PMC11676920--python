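"""Stratification sweep: distances, clustering methods, internal indices.

Every embedding is clustered under four fixed distance/method pairings:

====  ============  =======================
code  distance      clustering method
====  ============  =======================
a     correlation   k-means
b     correlation   hierarchical (average)
c     Gower         k-medoids (PAM)
d     Gower         hierarchical (average)
====  ============  =======================

For each (embedding, combo) cell the cluster count k is swept over a
range (default 2..6) and the winner is chosen by majority vote of three
internal validation indices — WB-ratio (within/between dissimilarity,
lower better), Dunn index (higher better) and average silhouette width
(higher better) — with ties broken toward the smallest k. Each cell emits
one named candidate stratification ``cuts_{code}_{depth}``.

k-means is centroid-based and has no native notion of correlation
distance, so combo (a) runs Euclidean k-means on row-standardized patient
profiles (each row centered and scaled), which orders pairs the same way
correlation distance does; its validation indices are still computed on
the true correlation-distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from ._pam import pam
from ._seeds import STAGE_SP, as_int_seed, stream

# Table of method combinations; the code letters are part of candidate names.
COMBOS: dict[str, tuple[str, str]] = {
    "a": ("correlation", "kmeans"),
    "b": ("correlation", "hierarchical"),
    "c": ("gower", "kmedoids"),
    "d": ("gower", "hierarchical"),
}
COMBO_INDEX = {code: i for i, code in enumerate(COMBOS)}

__all__ = [
    "COMBOS",
    "StratificationCandidate",
    "pairwise_distance",
    "cluster_once",
    "wb_ratio",
    "dunn_index",
    "avg_silhouette",
    "choose_k",
    "evaluate_cell",
    "run_stratification_process",
]


@dataclass
class StratificationCandidate:
    """One partition labelled by (depth, distance, method, chosen k)."""

    name: str
    depth: int
    code: str
    distance: str
    method: str
    k: int | None = None
    assignment: np.ndarray | None = None  # labels 0..k-1
    indices: pd.DataFrame | None = None  # per-k wb_ratio / dunn / silhouette
    stability: float | None = None
    per_cluster_stability: list | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of first appearance (determinism)."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def pairwise_distance(matrix: np.ndarray, metric: str) -> np.ndarray:
    """Patient x patient dissimilarity matrix.

    ``correlation``: 1 - Pearson correlation between patient row profiles
    (range [0, 2]). ``gower``: range-normalised Manhattan — the mean over
    components of |x_i - x_j| / range; all embedding columns are numeric
    so this is the numeric special case of Gower's coefficient.
    """
    X = np.asarray(matrix, dtype=float)
    if metric == "correlation":
        sd = X.std(axis=1)
        if np.any(sd <= 1e-12):
            bad = np.flatnonzero(sd <= 1e-12)[:5].tolist()
            raise ValueError(
                f"correlation distance undefined: patient row(s) {bad} have zero variance"
            )
        D = 1.0 - np.corrcoef(X)
    elif metric == "gower":
        rng = X.max(axis=0) - X.min(axis=0)
        usable = rng > 0
        if not usable.any():
            raise ValueError("gower distance undefined: all components constant")
        Xu = X[:, usable] / rng[usable]
        D = np.zeros((X.shape[0], X.shape[0]))
        for j in range(Xu.shape[1]):
            D += np.abs(Xu[:, j, None] - Xu[None, :, j])
        D /= usable.sum()
    else:
        raise ValueError(f"unknown distance metric {metric!r}")
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    np.fill_diagonal(D, 0.0)
    return D


def row_standardize(matrix: np.ndarray) -> np.ndarray:
    """Center and scale each patient row (population SD)."""
    X = np.asarray(matrix, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd <= 1e-12):
        bad = np.flatnonzero(sd.ravel() <= 1e-12)[:5].tolist()
        raise ValueError(f"cannot row-standardize: patient row(s) {bad} have zero variance")
    return (X - mu) / sd


class ClusteringError(RuntimeError):
    pass


def cluster_once(
    matrix: np.ndarray,
    code: str,
    k: int,
    seed: int = 0,
    D: np.ndarray | None = None,
    restarts: int = 25,
    max_retries: int = 3,
) -> np.ndarray:
    """One clustering of the cohort under a given combo and k.

    k-means runs on the row-standardized embedding matrix with ``restarts``
    seeded restarts; PAM and hierarchical (average linkage, cut to k) run
    on the dissimilarity matrix. Returns canonical labels 0..k-1; an empty
    cluster triggers bounded re-seeding and then a ClusteringError.
    """
    metric, method = COMBOS[code]
    n = np.asarray(matrix).shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} outside [2, {n - 1}]")
    if D is None and method != "kmeans":
        D = pairwise_distance(matrix, metric)

    for attempt in range(max_retries):
        if method == "kmeans":
            km = KMeans(
                n_clusters=k,
                n_init=restarts,
                random_state=(int(seed) + attempt) & 0x7FFFFFFF,
            )
            with warnings.catch_warnings():
                # fewer distinct points than k is detected below and handled
                warnings.simplefilter("ignore")
                labels = km.fit_predict(row_standardize(matrix))
        elif method == "hierarchical":
            Z = linkage(squareform(D, checks=False), method="average")
            labels = fcluster(Z, t=k, criterion="maxclust") - 1
        elif method == "kmedoids":
            labels = pam(D, k)
        else:  # pragma: no cover - combo table is closed
            raise ValueError(f"unknown method {method!r}")
        if len(np.unique(labels)) == k:
            return _canonical_labels(labels)
        if method != "kmeans":
            break  # deterministic methods cannot be re-seeded out of it
    raise ClusteringError(f"method {method!r} produced fewer than k={k} non-empty clusters")


# ---------------------------------------------------------------------------
# internal validation indices


def _pair_masks(labels: np.ndarray):
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    return same[iu], iu


def wb_ratio(labels: np.ndarray, D: np.ndarray) -> float:
    """Mean within-cluster / mean between-cluster dissimilarity (lower better)."""
    same, iu = _pair_masks(labels)
    d = np.asarray(D)[iu]
    if not same.any():  # all singletons: no within pairs
        return 0.0
    within = d[same].mean()
    if not (~same).any():
        return 0.0
    between = d[~same].mean()
    if between <= 0:
        warnings.warn("degenerate data: zero between-cluster dissimilarity", stacklevel=2)
        return 0.0
    return float(within / between)


def dunn_index(labels: np.ndarray, D: np.ndarray) -> float:
    """Min between-cluster single-link distance / max cluster diameter."""
    labels = np.asarray(labels)
    D = np.asarray(D)
    uniq = np.unique(labels)
    diam = 0.0
    for c in uniq:
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            diam = max(diam, D[np.ix_(idx, idx)].max())
    sep = np.inf
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            sep = min(sep, D[np.ix_(labels == a, labels == b)].min())
    if diam <= 0:
        return np.inf  # all clusters are points: best possible
    return float(sep / diam)


def avg_silhouette(labels: np.ndarray, D: np.ndarray) -> float:
    """Mean silhouette width; patients in singleton clusters score 0."""
    labels = np.asarray(labels)
    D = np.asarray(D)
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    n = len(labels)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), inv] = 1.0
    counts = onehot.sum(axis=0)
    sums = D @ onehot  # total distance from each patient to each cluster
    own = inv
    a = np.where(counts[own] > 1, sums[np.arange(n), own] / np.maximum(counts[own] - 1, 1), 0.0)
    mean_other = sums / counts[None, :]
    mean_other[np.arange(n), own] = np.inf
    b = mean_other.min(axis=1)
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    s = np.where(counts[own] == 1, 0.0, s)  # singleton convention
    return float(s.mean())


def choose_k(index_table: pd.DataFrame) -> int:
    """Majority vote of the three indices over k; ties go to the smallest k.

    ``index_table`` is indexed by k with columns wb_ratio / dunn /
    silhouette. Each index votes for its best k (its own tie resolved
    toward the smallest k), then the most-voted k wins.
    """
    ks = np.asarray(index_table.index)
    votes = []
    for col, best in (("wb_ratio", "min"), ("dunn", "max"), ("silhouette", "max")):
        vals = index_table[col].to_numpy(dtype=float)
        target = vals.min() if best == "min" else vals.max()
        votes.append(int(ks[np.flatnonzero(vals == target)[0]]))  # ks ascending
    counts = pd.Series(votes).value_counts()
    top = counts[counts == counts.max()].index
    return int(min(top))


# ---------------------------------------------------------------------------
# the sweep


def evaluate_cell(
    embedding,
    code: str,
    k_range: tuple[int, int] = (2, 6),
    seed: int = 0,
    restarts: int = 25,
) -> StratificationCandidate:
    """Full evaluation of one (embedding x combo) cell: sweep k, vote, emit."""
    metric, method = COMBOS[code]
    X = embedding.matrix.to_numpy(dtype=float)
    n = X.shape[0]
    D = pairwise_distance(X, metric)
    k_min, k_max = k_range
    k_max = min(k_max, n - 1)
    rows, assignments = [], {}
    for k in range(k_min, k_max + 1):
        try:
            labels = cluster_once(
                X, code, k,
                seed=as_int_seed(stream(seed, STAGE_SP, embedding.depth, COMBO_INDEX[code], k)),
                D=D, restarts=restarts,
            )
        except ClusteringError:
            continue  # k infeasible on this embedding (e.g. too few distinct profiles)
        assignments[k] = labels
        rows.append(
            {
                "k": k,
                "wb_ratio": wb_ratio(labels, D),
                "dunn": dunn_index(labels, D),
                "silhouette": avg_silhouette(labels, D),
            }
        )
    if not assignments:
        raise ClusteringError(
            f"no k in [{k_min}, {k_max}] is feasible for cuts_{code}_{embedding.depth}"
        )
    table = pd.DataFrame(rows).set_index("k")
    k_star = choose_k(table)
    return StratificationCandidate(
        name=f"cuts_{code}_{embedding.depth}",
        depth=embedding.depth,
        code=code,
        distance=metric,
        method=method,
        k=k_star,
        assignment=assignments[k_star],
        indices=table,
    )


def _safe_cell(embedding, code, k_range, seed, restarts):
    try:
        return evaluate_cell(embedding, code, k_range=k_range, seed=seed, restarts=restarts)
    except Exception as exc:  # flagged, never aborts the sweep
        metric, method = COMBOS[code]
        return StratificationCandidate(
            name=f"cuts_{code}_{embedding.depth}",
            depth=embedding.depth,
            code=code,
            distance=metric,
            method=method,
            error=f"{type(exc).__name__}: {exc}",
        )


def run_stratification_process(
    embeddings,
    combos: str = "abcd",
    k_range: tuple[int, int] = (2, 6),
    seed: int = 0,
    restarts: int = 25,
    n_jobs: int = 1,
) -> list:
    """Sweep all (embedding x combo) cells; exactly one candidate per cell.

    Cells are independent; per-cell seed streams are derived from (seed,
    depth, combo), so the candidate set is identical for any worker count.
    """
    cells = [(emb, code) for emb in embeddings for code in combos]
    results = Parallel(n_jobs=n_jobs)(
        delayed(_safe_cell)(emb, code, k_range, seed, restarts) for emb, code in cells
    )
    return list(results)
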