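"""Partitioning Around Medoids (PAM) on a precomputed dissimilarity matrix.

Classic BUILD + SWAP k-medoids, fully deterministic: BUILD greedily seeds
medoids by total-cost reduction and SWAP applies the single best
(medoid, candidate) exchange per iteration, breaking ties toward the
lowest index. Local search can stall in a local optimum, so when the
medoid-set space is small enough to enumerate (C(n, k) up to a few
thousand) the globally optimal set is found by enumeration instead.
"""

from __future__ import annotations

from math import comb

import numpy as np

# enumerate medoid sets exactly when the search space is at most this big
_EXACT_LIMIT = 3000


def pam(D: np.ndarray, k: int, max_iter: int = 200, return_medoids: bool = False):
    """Cluster labels in 0..k-1 for an n x n dissimilarity matrix."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} outside [2, {n - 1}]")
    if comb(n, k) <= _EXACT_LIMIT:
        return pam_exhaustive(D, k, return_medoids=return_medoids)

    # BUILD: first medoid minimises total distance; each next medoid
    # maximises the cost reduction it brings.
    medoids = [int(np.argmin(D.sum(axis=0)))]
    nearest = D[medoids[0]].copy()  # distance to closest medoid per point
    while len(medoids) < k:
        # gain of adding candidate h: sum over j of max(0, nearest_j - D[h, j])
        gain = np.maximum(0.0, nearest[None, :] - D).sum(axis=1)
        gain[medoids] = -np.inf
        h = int(np.argmax(gain))
        medoids.append(h)
        nearest = np.minimum(nearest, D[h])

    medoids = np.asarray(sorted(medoids))
    for _ in range(max_iter):
        Dm = D[medoids]  # k x n
        order = np.argsort(Dm, axis=0)
        nearest_idx = order[0]
        d1 = Dm[nearest_idx, np.arange(n)]
        d2 = Dm[order[1], np.arange(n)]
        current = d1.sum()

        best = (0.0, None, None)
        for i in range(len(medoids)):
            mine = nearest_idx == i
            # cost after swapping medoid i for each candidate h:
            #   points nearest to i fall back to min(second-nearest, D[:, h]);
            #   other points may improve to D[:, h].
            cost = np.where(mine[None, :], np.minimum(d2, D), np.minimum(d1, D)).sum(axis=1)
            cost[medoids] = np.inf
            h = int(np.argmin(cost))
            delta = current - cost[h]
            if delta > best[0] + 1e-12:
                best = (delta, i, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        medoids = np.sort(medoids)

    labels = np.argmin(D[medoids], axis=0)
    labels[medoids] = np.arange(len(medoids))  # a medoid belongs to itself
    if return_medoids:
        return labels, medoids
    return labels


def pam_exhaustive(D: np.ndarray, k: int, return_medoids: bool = False):
    """Globally optimal medoids by enumeration (oracle for tiny n)."""
    from itertools import combinations

    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    best_cost, best_set = np.inf, None
    for subset in combinations(range(n), k):
        cost = D[list(subset)].min(axis=0).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_set = cost, subset
    medoids = np.asarray(best_set)
    labels = np.argmin(D[medoids], axis=0)
    labels[medoids] = np.arange(k)
    if return_medoids:
        return labels, medoids
    return labels
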