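"""Missing-data workflow: per-imputation sweeps and co-clustering consensus.

When the input table has missing values, the variable dendrogram is built
once from the original incomplete data (pairwise-complete correlations),
and the embedding + stratification sweep runs separately on each of the m
imputed copies. The m runs for a given (depth, combo) cell are then
consensed:

1. the optimal k is the mode of the m per-imputation choices (ties to
   the smallest k);
2. each imputation is re-clustered at that consensus k;
3. a patient x patient co-clustering matrix records the fraction of
   imputations in which each pair shares a cluster;
4. the final stratification for the cell is hierarchical clustering
   (average linkage) of the consensus-matrix rows under correlation
   distance, cut at the consensus k.

The resulting candidates enter the robustness/consensus stage exactly as
in the complete-data scenario, with bootstrap re-clustering performed on
the consensus-matrix rows.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._seeds import STAGE_SP, as_int_seed, stream
from .engine import (
    COMBO_INDEX,
    StratificationCandidate,
    _canonical_labels,
    cluster_once,
    evaluate_cell,
    pairwise_distance,
)
from .reduction import build_variable_dendrogram, compute_embeddings, standardize

__all__ = [
    "ConsensusMatrix",
    "consensus_k",
    "coclustering_matrix",
    "final_stratification",
    "make_consensus_reclusterer",
    "run_missing_pipeline",
]


@dataclass
class ConsensusMatrix:
    """Patient x patient co-clustering frequency across m imputations."""

    values: np.ndarray  # symmetric, unit diagonal, entries are multiples of 1/m
    m: int


def consensus_k(per_imputation_k) -> int:
    """Modal k across imputations; ties broken toward the smallest k."""
    ks = list(per_imputation_k)
    if not ks:
        raise ValueError("need at least one per-imputation k")
    counts = Counter(ks)
    top = max(counts.values())
    return int(min(k for k, c in counts.items() if c == top))


def coclustering_matrix(per_imputation_assignments) -> ConsensusMatrix:
    """Fraction of imputations in which each patient pair co-clusters."""
    assignments = [np.asarray(a) for a in per_imputation_assignments]
    if not assignments:
        raise ValueError("need at least one assignment")
    n = len(assignments[0])
    if any(len(a) != n for a in assignments):
        raise ValueError("assignments must cover the same patients")
    acc = np.zeros((n, n))
    for a in assignments:
        acc += (a[:, None] == a[None, :]).astype(float)
    acc /= len(assignments)
    np.fill_diagonal(acc, 1.0)
    return ConsensusMatrix(values=acc, m=len(assignments))


def _consensus_rows_cluster(values: np.ndarray, k: int) -> np.ndarray:
    sd = values.std(axis=1)
    if np.any(sd <= 1e-12):
        raise ValueError("degenerate consensus: constant co-clustering row")
    D = pairwise_distance(values, "correlation")
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    if len(np.unique(labels)) < k:
        raise ValueError(f"consensus clustering produced fewer than k={k} clusters")
    return _canonical_labels(labels)


def final_stratification(consensus: ConsensusMatrix, k: int) -> np.ndarray:
    """Consensus assignment: correlation-distance hierarchical cut at k.

    Each patient is represented by their row of co-clustering frequencies;
    rows that always (or never) co-cluster identically are grouped by
    hierarchical clustering under correlation distance.
    """
    return _consensus_rows_cluster(np.asarray(consensus.values, dtype=float), k)


def make_consensus_reclusterer(consensus: ConsensusMatrix, k: int):
    """Bootstrap re-clustering closure operating on consensus-matrix rows."""
    values = np.asarray(consensus.values, dtype=float)

    def recluster(idx: np.ndarray, seed: int) -> np.ndarray:
        return _consensus_rows_cluster(values[idx], k)

    return recluster


def _cell_consensus(depth, code, per_imp, k_range, seed, restarts):
    """Consense one (depth, combo) cell across imputations."""
    try:
        ks = [cand.k for cand in per_imp["candidates"]]
        k_c = consensus_k(ks)
        assignments = []
        for i, (cand, emb) in enumerate(zip(per_imp["candidates"], per_imp["embeddings"])):
            if cand.k == k_c:
                assignments.append(cand.assignment)
            else:
                cell_seed = as_int_seed(stream(seed, STAGE_SP, depth, COMBO_INDEX[code], k_c, i))
                assignments.append(
                    cluster_once(
                        emb.matrix.to_numpy(dtype=float), code, k_c,
                        seed=cell_seed, restarts=restarts,
                    )
                )
        consensus = coclustering_matrix(assignments)
        final = final_stratification(consensus, k_c)
        from .engine import COMBOS

        metric, method = COMBOS[code]
        cand = StratificationCandidate(
            name=f"cuts_{code}_{depth}",
            depth=depth,
            code=code,
            distance=metric,
            method=method,
            k=k_c,
            assignment=final,
        )
        return cand, consensus
    except Exception as exc:
        from .engine import COMBOS

        metric, method = COMBOS[code]
        return (
            StratificationCandidate(
                name=f"cuts_{code}_{depth}", depth=depth, code=code,
                distance=metric, method=method, error=f"{type(exc).__name__}: {exc}",
            ),
            None,
        )


def run_missing_pipeline(
    study,
    stack,
    combos: str = "abcd",
    k_range: tuple[int, int] = (2, 6),
    depths=None,
    max_depth: int | None = None,
    var_target: float | None = None,
    seed: int = 0,
    restarts: int = 25,
    n_jobs: int = 1,
):
    """Scenario II/III sweep: per-imputation SP, then per-cell consensus.

    Returns (candidates, consensus_matrices, dendrogram) where
    ``consensus_matrices`` maps candidate name -> ConsensusMatrix (the
    bootstrap substrate for the robustness stage).
    """
    if stack is None or stack.m < 1:
        raise ValueError("missing-data pipeline requires an imputation stack")
    for i, ds in enumerate(stack.datasets):
        if ds.isna().to_numpy().any():
            raise ValueError(f"imputation {i} is incomplete")

    # one dendrogram from the original incomplete data
    dendrogram = build_variable_dendrogram(study.encoded, max_depth=max_depth)
    if depths is None:
        depths = list(range(1, dendrogram.max_depth + 1))
    else:
        depths = sorted(set(int(d) for d in depths))

    # per-imputation embeddings and sweeps; imputations are independent
    def _one_imputation(i, ds):
        std = standardize(ds)
        embeddings = compute_embeddings(dendrogram, std, depths=depths, var_target=var_target)
        cells = {}
        for emb in embeddings:
            for code in combos:
                cand = evaluate_cell(
                    emb, code, k_range=k_range,
                    seed=as_int_seed(stream(seed, STAGE_SP, emb.depth, COMBO_INDEX[code], 0, i)),
                    restarts=restarts,
                )
                cells[(emb.depth, code)] = (cand, emb)
        return cells

    per_imp_cells = Parallel(n_jobs=n_jobs)(
        delayed(_one_imputation)(i, ds) for i, ds in enumerate(stack.datasets)
    )

    candidates = []
    consensus_matrices = {}
    for depth in depths:
        for code in combos:
            per_imp = {
                "candidates": [cells[(depth, code)][0] for cells in per_imp_cells],
                "embeddings": [cells[(depth, code)][1] for cells in per_imp_cells],
            }
            cand, consensus = _cell_consensus(depth, code, per_imp, k_range, seed, restarts)
            candidates.append(cand)
            if consensus is not None:
                consensus_matrices[cand.name] = consensus
    return candidates, consensus_matrices, dendrogram
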