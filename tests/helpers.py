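"""Shared helpers for the test suite."""

import numpy as np

from mcnet import DistanceMatrix


def random_metric(n: int, seed: int) -> DistanceMatrix:
    """A generic random symmetric dissimilarity matrix (not additive)."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.1, 2.0, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(tuple(f"t{i}" for i in range(n)), v)


def four_point_violation(values: np.ndarray) -> float:
    """Largest violation of the four-point condition over all quartets.

    For an additive (treelike) metric, of the three pairings of any four
    taxa the two largest sums are equal; returns the worst gap.
    """
    n = values.shape[0]
    worst = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                for l in range(k + 1, n):
                    sums = sorted([
                        values[i, j] + values[k, l],
                        values[i, k] + values[j, l],
                        values[i, l] + values[j, k],
                    ])
                    worst = max(worst, sums[2] - sums[1])
    return worst
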