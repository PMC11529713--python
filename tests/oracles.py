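"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own code paths: O(n²) distance
scans, naive unweighted average-linkage agglomeration, and exhaustive
label-permutation enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_adjacency(coords: np.ndarray, radius: float) -> np.ndarray:
    """Dense boolean adjacency by full pairwise distance thresholding."""
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    adj = d <= radius
    np.fill_diagonal(adj, False)
    return adj


def brute_force_knn(coords: np.ndarray, ids, k: int) -> list[list[int]]:
    """k nearest points (self included), ties broken by id, via full sort."""
    ids = list(ids)
    out = []
    for i in range(len(coords)):
        d = np.sqrt(((coords - coords[i]) ** 2).sum(-1))
        order = sorted(range(len(coords)), key=lambda j: (d[j], ids[j]))
        out.append(order[:k])
    return out


def brute_force_average_linkage(points: np.ndarray
                                ) -> list[tuple[int, int, float]]:
    """Merge sequence of unweighted average-linkage agglomeration.

    Returns (rep_a, rep_b, distance) per merge, where a cluster's
    representative is the smallest original index it contains.
    """
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(points))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = float(np.mean([np.linalg.norm(points[i] - points[j])
                               for i in clusters[a] for j in clusters[b]]))
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        members = clusters.pop(a) + clusters.pop(b)
        clusters[min(a, b)] = members
    return merges


def enumerate_enrichment_pvalues(adjacency: np.ndarray, labels: list[str],
                                 focal: str, n_types: int,
                                 type_index: dict[str, int]):
    """Exact permutation p-values by enumerating all distinct label
    arrangements of the multiset (uniform probability each)."""
    from sympy.utilities.iterables import multiset_permutations

    labels = list(labels)
    n = len(labels)

    def stat(lab):
        focal_idx = [i for i in range(n) if lab[i] == focal]
        counts = np.zeros(n_types)
        for i in focal_idx:
            for j in range(n):
                if adjacency[i, j]:
                    counts[type_index[lab[j]]] += 1
        return counts / len(focal_idx)

    obs = stat(labels)
    tol = 1e-12
    ge = np.zeros(n_types)
    le = np.zeros(n_types)
    total = 0
    for arrangement in multiset_permutations(labels):
        s = stat(arrangement)
        ge += s >= obs - tol
        le += s <= obs + tol
        total += 1
    return obs, ge / total, le / total
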