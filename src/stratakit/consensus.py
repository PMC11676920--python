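"""Robustness filtering and consensus grouping of candidate stratifications.

Two distinct notions of robustness are applied in sequence:

* **population-based** — each candidate is re-derived on bootstrap
  resamples of the cohort; a candidate whose weakest cluster is not
  reliably recovered (mean set-Jaccard below 0.85) is discarded;
* **parameter-based** — the surviving candidates are compared pairwise
  with the pair-counting Jaccard index, grouped by complete-linkage
  agglomeration at a similarity threshold (default 0.7), and each group
  is summarised by its centroid member.

The pair-based Jaccard between two partitions counts unordered patient
pairs: J = n11 / (n11 + n10 + n01), where n11 is the number of pairs
co-clustered in both partitions and n10/n01 the pairs co-clustered in
exactly one. It is invariant to cluster relabelling and well defined for
partitions with different numbers of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._seeds import STAGE_BOOT, as_int_seed, stream
from .engine import COMBO_INDEX, cluster_once, pairwise_distance

__all__ = [
    "StabilityResult",
    "JaccardMatrix",
    "StratificationGroup",
    "partition_jaccard",
    "bootstrap_stability",
    "make_embedding_reclusterer",
    "filter_robust",
    "build_jaccard_matrix",
    "group_and_represent",
]


@dataclass
class StabilityResult:
    """Bootstrap recovery summary for one candidate."""

    candidate_name: str
    per_cluster_jaccard: list
    stability: float
    n_boot: int


@dataclass
class JaccardMatrix:
    """Pairwise partition similarity between robust candidates."""

    names: list
    values: np.ndarray  # symmetric, unit diagonal, in [0, 1]
    annotations: pd.DataFrame | None = None  # distance / method / depth per candidate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)


@dataclass
class StratificationGroup:
    """A set of mutually similar stratifications and its centroid."""

    members: list
    representative: str

    @property
    def size(self) -> int:
        return len(self.members)


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def partition_jaccard(a, b) -> float:
    """Pair-counting Jaccard similarity between two partitions.

    Computed from the contingency table, which is equivalent to
    enumerating all C(n, 2) patient pairs. Two all-singleton (or otherwise
    pair-free) partitions have an empty pair universe and score 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("assignments must cover the same patients")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1.0)
    n11 = _comb2(cont).sum()
    sa = _comb2(cont.sum(axis=1)).sum()
    sb = _comb2(cont.sum(axis=0)).sum()
    denom = sa + sb - n11
    if denom <= 0:
        return 1.0
    return float(n11 / denom)


def bootstrap_stability(
    assignment: np.ndarray,
    recluster,
    n_boot: int = 100,
    seed_seq: np.random.SeedSequence | None = None,
    summary: str = "min",
) -> StabilityResult:
    """Clusterwise bootstrap recovery of one candidate stratification.

    For each of ``n_boot`` resamples of patients (with replacement),
    ``recluster(row_indices, seed)`` re-derives a clustering of the
    resampled cohort with the candidate's own method and k. Each original
    cluster is matched to its best-overlapping bootstrap cluster by set
    Jaccard over the distinct resampled patients; its per-cluster score is
    the mean over replicates in which it appears. A replicate in which
    re-clustering fails scores 0 for every cluster.

    ``summary`` aggregates per-cluster scores into the scalar stability:
    ``min`` (a stratification is only as stable as its weakest cluster,
    the default) or ``mean``.
    """
    assignment = np.asarray(assignment)
    n = len(assignment)
    clusters = np.unique(assignment)
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(0)
    children = seed_seq.spawn(n_boot)
    sums = {c: 0.0 for c in clusters}
    counts = {c: 0 for c in clusters}
    members = {c: set(np.flatnonzero(assignment == c)) for c in clusters}
    for t in range(n_boot):
        rng = np.random.default_rng(children[t])
        idx = rng.integers(0, n, size=n)
        sampled = set(idx.tolist())
        present = {c: members[c] & sampled for c in clusters}
        try:
            boot_labels = np.asarray(recluster(idx, as_int_seed(children[t])))
        except Exception:
            for c in clusters:
                if present[c]:
                    sums[c] += 0.0
                    counts[c] += 1
            continue
        boot_sets = []
        for bc in np.unique(boot_labels):
            boot_sets.append(set(idx[boot_labels == bc]))
        for c in clusters:
            A = present[c]
            if not A:
                continue  # cluster absent from this resample
            best = max(len(A & B) / len(A | B) for B in boot_sets)
            sums[c] += best
            counts[c] += 1
    per_cluster = [sums[c] / counts[c] if counts[c] else 0.0 for c in clusters]
    if summary == "min":
        stability = float(min(per_cluster))
    elif summary == "mean":
        stability = float(np.mean(per_cluster))
    else:
        raise ValueError(f"unknown stability summary {summary!r}")
    return StabilityResult(
        candidate_name="", per_cluster_jaccard=per_cluster, stability=stability, n_boot=n_boot
    )


def make_embedding_reclusterer(matrix: np.ndarray, code: str, k: int, restarts: int = 25):
    """Re-clustering closure for scenario-I bootstrap: subset, re-derive."""
    X = np.asarray(matrix, dtype=float)

    def recluster(idx: np.ndarray, seed: int) -> np.ndarray:
        return cluster_once(X[idx], code, k, seed=seed, restarts=restarts)

    return recluster


def _stability_one(candidate, recluster, n_boot, seed, summary):
    seq = stream(seed, STAGE_BOOT, candidate.depth, COMBO_INDEX[candidate.code])
    res = bootstrap_stability(
        candidate.assignment, recluster, n_boot=n_boot, seed_seq=seq, summary=summary
    )
    res.candidate_name = candidate.name
    return res


def filter_robust(
    candidates,
    recluster_factory,
    n_boot: int = 100,
    threshold: float = 0.85,
    seed: int = 0,
    summary: str = "min",
    n_jobs: int = 1,
):
    """Score every non-failed candidate and keep those with stability >= threshold.

    ``recluster_factory(candidate)`` returns the re-clustering closure for
    that candidate (its embedding or consensus substrate). The threshold
    is inclusive: stability strictly below it is excluded. Returns
    (robust_candidates, stability_table).
    """
    scored = [c for c in candidates if not c.failed]
    results = Parallel(n_jobs=n_jobs)(
        delayed(_stability_one)(c, recluster_factory(c), n_boot, seed, summary) for c in scored
    )
    rows = []
    robust = []
    for cand, res in zip(scored, results):
        cand.stability = res.stability
        cand.per_cluster_stability = res.per_cluster_jaccard
        rows.append(
            {
                "name": cand.name,
                "depth": cand.depth,
                "combo": cand.code,
                "k": cand.k,
                "stability": res.stability,
                "robust": res.stability >= threshold,
            }
        )
        if res.stability >= threshold:
            robust.append(cand)
    table = pd.DataFrame(rows)
    return robust, table


def build_jaccard_matrix(candidates) -> JaccardMatrix:
    """All pairwise partition similarities among robust candidates."""
    if not candidates:
        raise ValueError("no robust candidates to compare")
    names = [c.name for c in candidates]
    n = len(candidates)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = partition_jaccard(
                candidates[i].assignment, candidates[j].assignment
            )
    annotations = pd.DataFrame(
        {
            "distance": [c.distance for c in candidates],
            "clustering": [c.method for c in candidates],
            "depth": [c.depth for c in candidates],
            "k": [c.k for c in candidates],
        },
        index=names,
    )
    return JaccardMatrix(names=names, values=values, annotations=annotations)


def group_and_represent(
    jaccard: JaccardMatrix, threshold: float = 0.7, min_size: int = 1
) -> list:
    """Group candidates by complete-linkage agglomeration on 1 - J.

    Cutting the complete-linkage tree at height 1 - threshold guarantees
    every within-group pair has J >= threshold. The representative of a
    group is the member with the highest mean similarity to the other
    members (ties broken by name). Groups smaller than ``min_size`` are
    dropped from the report; the default keeps all.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n = len(jaccard.names)
    if n == 0:
        return []
    if n == 1:
        groups_labels = np.array([1])
    else:
        diss = np.clip(1.0 - jaccard.values, 0.0, None)
        np.fill_diagonal(diss, 0.0)
        Z = linkage(squareform(diss, checks=False), method="complete")
        groups_labels = fcluster(Z, t=1.0 - threshold + 1e-12, criterion="distance")
    groups = []
    for g in np.unique(groups_labels):
        idx = np.flatnonzero(groups_labels == g)
        members = [jaccard.names[i] for i in idx]
        if len(idx) == 1:
            rep = members[0]
        else:
            sub = jaccard.values[np.ix_(idx, idx)]
            mean_sim = (sub.sum(axis=1) - 1.0) / (len(idx) - 1)
            best = mean_sim.max()
            tied = [members[i] for i in np.flatnonzero(np.isclose(mean_sim, best))]
            rep = min(tied)
        if len(members) >= min_size:
            groups.append(StratificationGroup(members=sorted(members), representative=rep))
    groups.sort(key=lambda g: (-g.size, g.representative))
    return groups
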