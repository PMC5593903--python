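"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — plain loops, exact rational
arithmetic, exhaustive merges — and shares no code with the package paths
it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def brute_column_frequency(rows: list[str], column: int, residue: str) -> float:
    """Frequency of one residue in one column by direct loop, gaps in denominator."""
    count = 0
    for row in rows:
        if row[column] == residue:
            count += 1
    return count / len(rows)


def exact_fisher_upper(k11: int, count_a: int, count_b: int, n: int) -> Fraction:
    """P[X >= k11] for X ~ Hypergeometric(n, count_a, count_b), exact rational.

    X is the co-occurrence count when count_b rows are drawn from n with
    count_a marked.
    """
    total = comb(n, count_b)
    upper = min(count_a, count_b)
    acc = Fraction(0)
    for x in range(k11, upper + 1):
        acc += Fraction(comb(count_a, x) * comb(n - count_a, count_b - x), total)
    return acc


def naive_agglomerative(
    dist: list[list[float]], cutoff: float, linkage: str
) -> list[frozenset[int]]:
    """Agglomerative clustering by repeated merging of the closest pair.

    Merges while the minimum inter-cluster linkage distance is <= cutoff.
    Linkage distances computed from the original matrix each step
    (furthest = max, average = mean, nearest = min over member pairs).
    """
    n = len(dist)
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]

    def d(c1: frozenset[int], c2: frozenset[int]) -> float:
        vals = [dist[i][j] for i in c1 for j in c2]
        if linkage == "furthest":
            return max(vals)
        if linkage == "nearest":
            return min(vals)
        return sum(vals) / len(vals)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dij = d(clusters[i], clusters[j])
                if best is None or dij < best[0]:
                    best = (dij, i, j)
        if best is None or best[0] > cutoff:
            break
        _, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return clusters
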