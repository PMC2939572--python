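import numpy as np
import pytest

from mcnet import DistanceMatrix


@pytest.fixture
def cycle4() -> DistanceMatrix:
    """Distances of a 4-cycle: adjacent pairs at 1, opposite pairs at 2."""
    values = np.array(
        [[0, 1, 2, 1],
         [1, 0, 1, 2],
         [2, 1, 0, 1],
         [1, 2, 1, 0]], dtype=float)
    return DistanceMatrix(("A", "B", "C", "D"), values)


@pytest.fixture
def quartet() -> DistanceMatrix:
    """Additive metric of the quartet tree ((A,B),(C,D)), all branches 1.

    Cherry pairs are at distance 2, cross pairs at 3.  The ground truth is
    five unit-weight splits: the four trivial ones plus AB|CD.
    """
    values = np.array(
        [[0, 2, 3, 3],
         [2, 0, 3, 3],
         [3, 3, 0, 2],
         [3, 3, 2, 0]], dtype=float)
    return DistanceMatrix(("A", "B", "C", "D"), values)


@pytest.fixture
def equal4() -> DistanceMatrix:
    """All off-diagonal distances equal to 1 (every tour ties)."""
    values = np.ones((4, 4)) - np.eye(4)
    return DistanceMatrix(("A", "B", "C", "D"), values)
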