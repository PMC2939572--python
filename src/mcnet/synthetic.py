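"""Seeded generators for the matrix classes the method is tested on.

Three generators cover the interesting regimes:

* *treelike* (additive) metrics — patristic distances on a random unrooted
  binary tree, where the method should recover the tree's 2n-3 splits with
  their branch lengths exactly;
* *circular* (Kalmanson) metrics — phyletic distances of a circular split
  system with positive weights, the widest class the method fits exactly;
* noise-perturbed variants of either, where the non-negative fit becomes a
  genuine approximation.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np

from .distmat import DistanceMatrix
from .ordering import CircularOrdering
from .splits import Split, build_design_matrix, circular_splits

__all__ = ["random_tree_metric", "random_circular_metric", "perturb"]


def _labels(n: int) -> tuple[str, ...]:
    return tuple(f"x{i + 1}" for i in range(n))


def _random_topology(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Random unrooted binary tree on leaves 0..n-1 by leaf attachment.

    Starts from the 3-leaf star and attaches each further leaf to a
    uniformly chosen edge, subdividing it.  Returns the 2n-3 edges; internal
    nodes are numbered from n upward.
    """
    edges = [(0, n), (1, n), (2, n)]
    next_internal = n + 1
    for leaf in range(3, n):
        idx = int(rng.integers(len(edges)))
        u, v = edges.pop(idx)
        m = next_internal
        next_internal += 1
        edges.extend([(u, m), (m, v), (leaf, m)])
    return edges


def _edge_splits(edges: list[tuple[int, int]], n: int) -> list[Split]:
    """The split each edge induces on the leaf set (one per edge)."""
    adjacency: dict[int, list[int]] = {}
    for u, v in edges:
        adjacency.setdefault(u, []).append(v)
        adjacency.setdefault(v, []).append(u)
    splits = []
    for u, v in edges:
        # leaves on the v-side of edge (u, v)
        stack, seen = [v], {u, v}
        side = []
        while stack:
            node = stack.pop()
            if node < n:
                side.append(node)
            for nb in adjacency[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        splits.append(Split.from_members(side, n))
    return splits


def random_tree_metric(
    n: int,
    branch_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
) -> tuple[DistanceMatrix, list[tuple[Split, float]]]:
    """Additive metric from a random weighted binary tree.

    Branch lengths are drawn uniformly from ``branch_range``; the returned
    ground truth pairs each of the 2n-3 tree splits with its branch length.
    The matrix satisfies the four-point condition exactly.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    lo, hi = branch_range
    if not 0 < lo <= hi:
        raise ValueError(f"branch_range must satisfy 0 < lo <= hi, got {branch_range}")
    rng = np.random.default_rng(seed)
    edges = _random_topology(n, rng)
    splits = _edge_splits(edges, n)
    weights = rng.uniform(lo, hi, size=len(edges))
    design, _ = build_design_matrix(splits, n)
    dvec = design @ weights
    values = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    values[iu, ju] = dvec
    values += values.T
    dm = DistanceMatrix(_labels(n), values)
    return dm, list(zip(splits, weights.tolist()))


def random_circular_metric(
    n: int,
    n_splits: int | None = None,
    weight_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
) -> tuple[DistanceMatrix, CircularOrdering, list[tuple[Split, float]]]:
    """Kalmanson metric from a random weighted circular split system.

    A random cycle is drawn, ``n_splits`` of its arc splits are sampled —
    always including all ``n`` trivial splits, so distinct taxa stay at
    positive distance — and given positive uniform weights.  The distances
    are the phyletic distances ``d = A w``.  Default ``n_splits`` is
    ``min(2n, n(n-1)/2)``: the trivial splits plus as many internal arcs,
    a moderately reticulate system.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    max_splits = n * (n - 1) // 2
    if n_splits is None:
        n_splits = min(2 * n, max_splits)
    if not n <= n_splits <= max_splits:
        raise ValueError(f"n_splits must be in [{n}, {max_splits}], got {n_splits}")
    lo, hi = weight_range
    if not 0 < lo <= hi:
        raise ValueError(f"weight_range must satisfy 0 < lo <= hi, got {weight_range}")
    rng = np.random.default_rng(seed)
    cycle = CircularOrdering(tuple(int(x) for x in rng.permutation(n))).canonical()
    all_splits = circular_splits(cycle)
    trivial = [s for s in all_splits if s.is_trivial]
    nontrivial = [s for s in all_splits if not s.is_trivial]
    extra = n_splits - len(trivial)
    chosen_idx = rng.choice(len(nontrivial), size=extra, replace=False)
    splits = trivial + [nontrivial[i] for i in sorted(chosen_idx)]
    weights = rng.uniform(lo, hi, size=len(splits))
    design, _ = build_design_matrix(splits, n)
    dvec = design @ weights
    values = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    values[iu, ju] = dvec
    values += values.T
    dm = DistanceMatrix(_labels(n), values)
    return dm, cycle, list(zip(splits, weights.tolist()))


def perturb(d: DistanceMatrix, noise_sd: float, seed: int = 0) -> DistanceMatrix:
    """Add symmetric Gaussian noise to the off-diagonal entries.

    Noise is drawn once per unordered pair, applied symmetrically, and the
    resulting entries are truncated at zero; the diagonal stays zero.
    ``noise_sd = 0`` returns an identical matrix.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = d.n
    noise = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    noise[iu, ju] = rng.normal(0.0, noise_sd, size=iu.size) if noise_sd > 0 else 0.0
    noise += noise.T
    values = np.clip(d.values + noise, 0.0, None)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(d.labels, values)
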