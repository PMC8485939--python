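"""Independent brute-force reference implementations used only by tests.

These deliberately re-derive results by enumeration or naive recursion so
they share no code path with the package.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_hl_code(profile) -> str:
    """Mean-comparison H/L coding via explicit Python arithmetic."""
    values = list(profile)
    mean = sum(values) / len(values)
    return "".join("H" if v > mean else "L" for v in values)


def brute_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by enumerating all C(N, n) draws."""
    population = list(range(N))
    annotated = set(range(K))
    total = 0
    hits = 0
    for draw in combinations(population, n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return hits / total


def naive_agglomerate(dist: np.ndarray, method: str = "complete"):
    """Naive agglomerative clustering from a square distance matrix.

    Cluster-to-cluster distances are recomputed from the leaf matrix at
    every step (max / min / mean over cross pairs), with ties broken
    toward the lexicographically smallest cluster pair.

    Returns (heights, cophenetic, tie_free): the merge heights in order,
    the square cophenetic matrix, and whether every merge choice was
    unique (when ties occurred, other implementations may legitimately
    produce different cophenetic matrices).
    """
    reducers = {"complete": max, "single": min, "average": lambda v: sum(v) / len(v)}
    reduce = reducers[method]
    n = dist.shape[0]
    clusters = [tuple([i]) for i in range(n)]
    heights = []
    coph = np.zeros_like(dist, dtype=float)
    tie_free = True
    while len(clusters) > 1:
        best = None
        best_d = None
        n_best = 0
        for a, b in combinations(range(len(clusters)), 2):
            d = reduce(
                [dist[i, j] for i in clusters[a] for j in clusters[b]]
            )
            if best_d is None or d < best_d - 1e-12:
                best, best_d, n_best = (a, b), d, 1
            elif abs(d - best_d) <= 1e-12:
                n_best += 1
        if n_best > 1:
            tie_free = False
        a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = best_d
        merged = tuple(sorted(clusters[a] + clusters[b]))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
        heights.append(best_d)
    return heights, coph, tie_free
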