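"""Data complexity reduction: variable dendrogram and per-depth embeddings.

Clinical tables are typically collinear: panels of related measurements
move together. Rather than selecting one representative variable per
panel, this step clusters the *variables* by absolute Pearson correlation
(dissimilarity ``1 - |r|``, average linkage) and, for every depth of the
resulting dendrogram, replaces each variable group with its leading
principal component(s). Cutting the tree at depth ``d`` yields ``d + 1``
groups, for ``d = 1 .. V - 2`` by default, so a table with V encoded
columns produces ``V - 2`` embeddings — one candidate view of the cohort
per plausible grouping of the variables.

Correlations are computed pairwise-complete, so the dendrogram is defined
even when the table has missing cells; the projection itself requires a
complete (imputed) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "VariableDendrogram",
    "Embedding",
    "standardize",
    "build_variable_dendrogram",
    "cut_at_depth",
    "embed_groups",
    "compute_embeddings",
]


def standardize(encoded: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean unit-variance columns, using observed cells only.

    Constant columns are rejected (they carry no grouping information and
    break correlation and PCA downstream).
    """
    mu = encoded.mean(skipna=True)
    sd = encoded.std(skipna=True, ddof=1)
    bad = sd[~(sd > 0)].index.tolist()
    if bad:
        raise ValueError(f"constant feature: zero variance in column(s) {bad}")
    return (encoded - mu) / sd


@dataclass
class VariableDendrogram:
    """Agglomeration tree over encoded columns."""

    linkage_: np.ndarray  # scipy linkage matrix
    columns: list
    max_depth: int

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_[:, 2]


@dataclass
class Embedding:
    """One reduced view of the cohort: patients x components at one depth."""

    depth: int
    groups: list  # list of lists of column names
    matrix: pd.DataFrame  # patients x components, complete
    provenance: dict = field(default_factory=dict)  # group index -> details


def build_variable_dendrogram(
    encoded: pd.DataFrame, max_depth: int | None = None, min_overlap: int = 3
) -> VariableDendrogram:
    """Average-linkage tree on variable dissimilarity ``1 - |corr|``.

    Works on the original (possibly incomplete) matrix using
    pairwise-complete Pearson correlations; a column pair with fewer than
    ``min_overlap`` joint observations is rejected. Deterministic for a
    fixed input.
    """
    V = encoded.shape[1]
    if V < 3:
        raise ValueError("at least 3 encoded columns are required")
    if encoded.shape[0] < 3:
        raise ValueError("at least 3 rows are required")
    corr = encoded.corr(method="pearson", min_periods=min_overlap)
    off = corr.to_numpy().copy()
    np.fill_diagonal(off, 1.0)
    if np.isnan(off).any():
        i, j = np.argwhere(np.isnan(off))[0]
        raise ValueError(
            f"insufficient overlap: columns {corr.columns[i]!r} and {corr.columns[j]!r} "
            f"share fewer than {min_overlap} observations"
        )
    diss = 1.0 - np.abs(off)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    Z = linkage(squareform(diss, checks=False), method="average")
    hard_cap = V - 2
    depth = hard_cap if max_depth is None else min(int(max_depth), hard_cap)
    if depth < 1:
        raise ValueError("max_depth must be >= 1")
    return VariableDendrogram(linkage_=Z, columns=list(encoded.columns), max_depth=depth)


def cut_at_depth(dendrogram: VariableDendrogram, d: int) -> list:
    """Partition of the columns into ``d + 1`` groups.

    Cuts are nested: every group at depth d is a union of groups at depth
    d + 1. Groups are ordered by first column occurrence.
    """
    if not 1 <= d <= dendrogram.max_depth:
        raise ValueError(f"depth {d} outside [1, {dendrogram.max_depth}]")
    labels = cut_tree(dendrogram.linkage_, n_clusters=d + 1).ravel()
    groups: dict[int, list] = {}
    for col, lab in zip(dendrogram.columns, labels):
        groups.setdefault(int(lab), []).append(col)
    ordered = sorted(groups.values(), key=lambda g: dendrogram.columns.index(g[0]))
    return ordered


def _group_pca(sub: np.ndarray, var_target: float | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores, loadings, and explained-variance ratios for one group.

    Returns the retained components only: a single leading component by
    default, or the smallest set reaching ``var_target`` cumulative
    explained variance. Component sign is fixed so the loading of the
    group's first member is non-negative (first non-zero loading if that
    one vanishes), making reruns and parallel workers agree exactly.
    """
    sub = sub - sub.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(sub, full_matrices=False)
    var = S**2
    ratio = var / var.sum() if var.sum() > 0 else var
    if var_target is None:
        ncomp = 1
    else:
        ncomp = int(np.searchsorted(np.cumsum(ratio), var_target) + 1)
        ncomp = min(ncomp, len(S))
    scores = U[:, :ncomp] * S[:ncomp]
    loadings = Vt[:ncomp]
    for j in range(ncomp):
        nz = np.flatnonzero(np.abs(loadings[j]) > 1e-12)
        pivot = nz[0] if nz.size else 0
        if loadings[j, pivot] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]
    return scores, loadings, ratio[:ncomp]


def embed_groups(
    std_matrix: pd.DataFrame, groups: list, depth: int, var_target: float | None = None
) -> Embedding:
    """Replace each variable group with its principal component(s).

    ``std_matrix`` must be complete and standardized. Singleton groups
    pass through unchanged (their standardized column); multi-column
    groups are projected onto their leading PC(s).
    """
    if std_matrix.isna().to_numpy().any():
        raise ValueError("embedding requires a complete (imputed) matrix")
    cols: dict[str, np.ndarray] = {}
    provenance: dict[int, dict] = {}
    for gi, members in enumerate(groups):
        if len(members) == 1:
            cols[members[0]] = std_matrix[members[0]].to_numpy(dtype=float)
            provenance[gi] = {"members": list(members), "n_components": 1, "passthrough": True}
        else:
            scores, loadings, explained = _group_pca(
                std_matrix[members].to_numpy(dtype=float), var_target
            )
            for j in range(scores.shape[1]):
                cols[f"g{gi + 1}pc{j + 1}"] = scores[:, j]
            provenance[gi] = {
                "members": list(members),
                "n_components": scores.shape[1],
                "loadings": loadings.tolist(),
                "explained_variance_ratio": explained.tolist(),
                "passthrough": False,
            }
    matrix = pd.DataFrame(cols, index=std_matrix.index)
    return Embedding(depth=depth, groups=groups, matrix=matrix, provenance=provenance)


def compute_embeddings(
    dendrogram: VariableDendrogram,
    std_matrix: pd.DataFrame,
    depths=None,
    var_target: float | None = None,
) -> list:
    """One embedding per requested depth (default: every depth 1..max)."""
    if depths is None:
        depths = range(1, dendrogram.max_depth + 1)
    return [
        embed_groups(std_matrix, cut_at_depth(dendrogram, d), d, var_target=var_target)
        for d in depths
    ]
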