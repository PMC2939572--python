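"""Symmetric taxon-labelled distance matrices.

The whole pipeline starts from a matrix of pairwise dissimilarities
``d(x_i, x_j)`` over ``n >= 4`` taxa — substitutions per site, MLST allele
mismatch counts, or any other non-negative dissimilarity.  The container
below stores the full square matrix (symmetrized, zero diagonal) together
with the taxon labels in input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistanceMatrix",
    "DataError",
    "ParseError",
    "ASYMMETRY_AVERAGE_TOL",
    "ASYMMETRY_ERROR_TOL",
]

#: asymmetries up to this magnitude are silently averaged away (text-format
#: rounding); anything between this and ASYMMETRY_ERROR_TOL is averaged too,
#: beyond it the input is rejected as corrupt.
ASYMMETRY_AVERAGE_TOL = 1e-9
ASYMMETRY_ERROR_TOL = 1e-6


class DataError(ValueError):
    """The input data violate a contract (asymmetry, negativity, duplicates...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


@dataclass(frozen=True)
class DistanceMatrix:
    """An ``n x n`` symmetric dissimilarity matrix with taxon labels.

    Invariants (enforced at construction):

    * ``values`` is square, symmetric, non-negative, zero on the diagonal;
    * ``labels`` are unique and match the matrix dimension;
    * ``n >= 4`` (smaller taxon sets admit no non-trivial circular ordering).
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise DataError(f"distance matrix must be square, got shape {values.shape}")
        n = values.shape[0]
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != n:
            raise DataError(f"{len(labels)} labels for a {n}x{n} matrix")
        if len(set(labels)) != n:
            raise DataError("duplicate taxon labels")
        if n < 4:
            raise DataError(f"need at least 4 taxa, got {n}")
        asym = np.abs(values - values.T).max() if n else 0.0
        if asym > ASYMMETRY_ERROR_TOL:
            raise DataError(
                f"matrix asymmetry {asym:g} exceeds tolerance {ASYMMETRY_ERROR_TOL:g}"
            )
        values = (values + values.T) / 2.0
        if np.abs(np.diag(values)).max() > ASYMMETRY_AVERAGE_TOL:
            raise DataError("non-zero diagonal entries")
        np.fill_diagonal(values, 0.0)
        if values.min() < 0:
            raise DataError("negative distances are not allowed")
        values.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def condensed(self) -> np.ndarray:
        """The upper-triangle vector ``(d_12, d_13, ..., d_(n-1)n)``.

        Row order is lexicographic over pairs ``(i, j)`` with ``i < j`` — the
        same order used for the rows of the split design matrix.
        """
        iu, ju = np.triu_indices(self.n, k=1)
        return self.values[iu, ju]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DistanceMatrix(n={self.n}, labels={self.labels[:3]}...)"
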