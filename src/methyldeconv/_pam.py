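"""Partitioning Around Medoids (PAM) on a precomputed distance matrix.

Classic BUILD + SWAP k-medoids. Deterministic for a given distance matrix:
BUILD greedily seeds medoids minimising total within-cluster cost, SWAP
exhaustively tries medoid/non-medoid exchanges and applies the best
improvement until convergence. Ties break on the lowest index.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pam"]


def _total_cost(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def pam(D: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, list[int]]:
    """Cluster ``n`` objects into ``k`` groups around medoids.

    Parameters
    ----------
    D
        Symmetric (n, n) pairwise distance matrix.
    k
        Number of clusters, ``2 <= k <= n``.

    Returns
    -------
    labels
        Array of length n with cluster indices in ``[0, k)`` (cluster i is
        the set of points closest to ``medoids[i]``).
    medoids
        Indices of the k medoid objects.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")

    # BUILD: first medoid minimises total distance; then greedy additions
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, -1
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - D[:, j], 0.0).sum()
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)

    # SWAP until no exchange lowers the total cost
    cost = _total_cost(D, medoids)
    for _ in range(max_iter):
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for j in range(n):
                if j in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = j
                delta = _total_cost(D, trial) - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, j)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        cost += best[0]

    medoids = sorted(medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, medoids
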