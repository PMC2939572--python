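"""Exhaustive ground truth for small instances.

Finding the optimal circular ordering is NP-hard, but for n <= 10 the
(n-1)!/2 distinct circular orderings can be enumerated outright.  The
enumeration fixes taxon 0 first (killing rotations) and keeps only tours
with ``perm[1] < perm[-1]`` (killing reflections), so each circular ordering
is visited exactly once, in canonical lexicographic order.  Used as the
oracle the heuristic search is measured against.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from .distmat import DistanceMatrix
from .ordering import CircularOrdering

__all__ = ["optimal_ordering_exhaustive", "count_circular_orderings"]

MAX_EXHAUSTIVE_N = 10


def count_circular_orderings(n: int) -> int:
    """(n-1)!/2 — the number of distinct circular orderings of n >= 3 taxa."""
    out = 1
    for k in range(2, n):
        out *= k
    return out // 2


def optimal_ordering_exhaustive(d: DistanceMatrix) -> tuple[CircularOrdering, float]:
    """Globally optimal circular ordering by brute force (n <= 10).

    Ties are broken toward the lexicographically smallest canonical
    permutation.  Returns the ordering and its tour energy.
    """
    n = d.n
    if n > MAX_EXHAUSTIVE_N:
        raise ValueError(
            f"exhaustive search refused for n={n} > {MAX_EXHAUSTIVE_N} "
            f"({count_circular_orderings(n)} orderings)"
        )
    D = d.values
    best_perm: tuple[int, ...] | None = None
    best_e = np.inf
    for rest in permutations(range(1, n)):
        if rest[0] > rest[-1]:
            continue  # reflection of an ordering already visited
        perm = (0,) + rest
        e = D[0, rest[0]] + D[rest[-1], 0]
        for a, b in zip(rest, rest[1:]):
            e += D[a, b]
        if e < best_e:
            best_e = e
            best_perm = perm
    assert best_perm is not None
    return CircularOrdering(best_perm), float(best_e)
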