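"""Circular orderings of taxa, the tour-length energy, and the greedy seed.

A circular ordering sigma is a cyclic arrangement of the taxa, interpreted
as the closed tour ``x_sigma(1) -> x_sigma(2) -> ... -> x_sigma(n) ->
x_sigma(1)``.  Its *energy* is the tour length

    eta(sigma) = d(x_sigma(1), x_sigma(n)) + sum_k d(x_sigma(k), x_sigma(k+1)),

and an ordering minimizing eta is an optimal circular ordering.  Finding one
is NP-hard (it is a travelling-salesman tour), which is why the search is
heuristic: a greedy construction (`initial_ordering`) followed by simulated
annealing (:mod:`mcnet.anneal`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distmat import DistanceMatrix

__all__ = ["CircularOrdering", "energy", "initial_ordering"]


@dataclass(frozen=True)
class CircularOrdering:
    """A permutation of ``0..n-1`` read as a closed tour.

    Equality and hashing act on the permutation itself so that the n-2
    annealing neighbours of an ordering stay distinct objects; use
    :meth:`canonical` / :meth:`circularly_equal` when two orderings should be
    compared as *circular* arrangements (invariant under rotation and
    reversal).  The canonical representative starts at taxon 0 and has
    ``perm[1] < perm[-1]``.
    """

    perm: tuple[int, ...]

    def __post_init__(self) -> None:
        perm = tuple(int(p) for p in self.perm)
        n = len(perm)
        if sorted(perm) != list(range(n)):
            raise ValueError(f"perm must be a permutation of 0..{n - 1}: {perm}")
        object.__setattr__(self, "perm", perm)

    @property
    def n(self) -> int:
        return len(self.perm)

    def canonical(self) -> "CircularOrdering":
        """Rotate/reflect so that ``perm[0] == 0`` and ``perm[1] < perm[-1]``."""
        perm = self.perm
        i = perm.index(0)
        rotated = perm[i:] + perm[:i]
        if rotated[1] > rotated[-1]:
            rotated = (rotated[0],) + tuple(reversed(rotated[1:]))
        return CircularOrdering(rotated)

    def circularly_equal(self, other: "CircularOrdering") -> bool:
        return self.canonical().perm == other.canonical().perm

    def __iter__(self):
        return iter(self.perm)


def energy(d: DistanceMatrix, sigma: CircularOrdering) -> float:
    """Closed-tour length of ``sigma`` under the distances ``d``.

    Invariant under rotation and reversal of the permutation; zero iff all
    consecutive tour distances are zero.
    """
    perm = np.asarray(sigma.perm)
    if perm.size != d.n:
        raise ValueError(f"ordering over {perm.size} taxa but matrix has {d.n}")
    return float(d.values[perm, np.roll(perm, -1)].sum())


def initial_ordering(d: DistanceMatrix) -> CircularOrdering:
    """Greedy construction of a starting circular ordering.

    Seeds a path with the closest pair of taxa, then repeatedly picks the
    unplaced taxon closest to either end of the path and attaches it there
    (prepend if the closest end is the head, append if the tail), until all
    taxa are placed.  The closed tour through the resulting path is returned.

    Deterministic tie-breaking: the seed is the lexicographically first pair
    attaining the minimum off-diagonal distance; when several unplaced taxa
    attain the minimum the smallest index wins; when both ends tie for that
    taxon it is appended to the tail.
    """
    n = d.n
    D = d.values
    best = np.inf
    seed = (0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] < best:
                best = D[i, j]
                seed = (i, j)
    path = [seed[0], seed[1]]
    remaining = [x for x in range(n) if x not in seed]
    while remaining:
        best_val = np.inf
        best_x = -1
        best_end = "tail"
        for x in remaining:  # ascending index order: first strict winner kept
            d_head = D[x, path[0]]
            d_tail = D[x, path[-1]]
            if d_head < d_tail:
                val, end = d_head, "head"
            else:  # tail preferred on ties
                val, end = d_tail, "tail"
            if val < best_val:
                best_val, best_x, best_end = val, x, end
        remaining.remove(best_x)
        if best_end == "head":
            path.insert(0, best_x)
        else:
            path.append(best_x)
    return CircularOrdering(tuple(path))
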