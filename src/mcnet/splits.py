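"""Circular splits of an ordering and their least-squares weighting.

A *split* is a bipartition A|B of the taxon set; it is *circular* with
respect to an ordering sigma when each side is a contiguous arc of the tour.
An ordering induces exactly ``n(n-1)/2`` distinct circular splits, including
the ``n`` trivial (single-taxon) ones.

Weights are estimated by least squares against the observed distances.  With
``A`` the 0/1 pair-by-split incidence matrix (``A[ij, k] = 1`` iff taxa ``i``
and ``j`` lie on opposite sides of split ``k``), ``b`` the weight vector and
``d`` the condensed distance vector, the phyletic distances are ``p = A b``.
Ordinary least squares ``b = (A'A)^{-1} A'd`` can go negative, which has no
phylogenetic meaning and inflates the remaining weights if the negative
splits are simply discarded; the pipeline therefore fits ``min ||Ab - d||_2``
subject to ``b >= 0`` with an active-set NNLS solver and drops the exactly
zero weights afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .distmat import DistanceMatrix
from .ordering import CircularOrdering

__all__ = [
    "Split",
    "WeightedSplitSystem",
    "circular_splits",
    "build_design_matrix",
    "distance_vector",
    "fit_ols",
    "fit_nnls",
    "weight_splits",
    "filter_splits",
    "fit_norm",
    "kkt_residuals",
    "DEFAULT_WEIGHT_THRESHOLD",
]

#: weights at or below this are treated as exact zeros from the active-set
#: solver plus float noise, and dropped when filtering.
DEFAULT_WEIGHT_THRESHOLD = 1e-10


@dataclass(frozen=True)
class Split:
    """A bipartition of ``{0, ..., n-1}`` in canonical form.

    Only the side *not* containing taxon 0 is stored (sorted); the
    complement is implied.  This deduplicates A|B versus B|A.
    """

    side: tuple[int, ...]
    n: int

    def __post_init__(self) -> None:
        side = tuple(sorted(int(x) for x in self.side))
        if not 0 < len(side) < self.n:
            raise ValueError("split sides must both be non-empty")
        if 0 in side:
            raise ValueError("canonical side must exclude taxon 0")
        if len(set(side)) != len(side) or side[-1] >= self.n:
            raise ValueError(f"invalid split side {side} for n={self.n}")
        object.__setattr__(self, "side", side)

    @classmethod
    def from_members(cls, members, n: int) -> "Split":
        """Canonicalize an arbitrary side (taking the complement if needed)."""
        members = set(int(x) for x in members)
        if 0 in members:
            members = set(range(n)) - members
        return cls(tuple(sorted(members)), n)

    @property
    def is_trivial(self) -> bool:
        return len(self.side) in (1, self.n - 1)

    def separates(self, i: int, j: int) -> bool:
        return (i in self.side) != (j in self.side)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        rest = sorted(set(range(self.n)) - set(self.side))
        return f"{set(self.side)}|{set(rest)}"


def circular_splits(sigma: CircularOrdering) -> list[Split]:
    """All ``n(n-1)/2`` distinct splits whose sides are arcs of ``sigma``.

    Every contiguous arc ``{x_sigma(i), ..., x_sigma(j)}`` against its
    complement; complements deduplicated via the canonical form.  The set is
    invariant under rotation and reversal of the ordering.
    """
    perm = sigma.perm
    n = len(perm)
    if n < 4:
        raise ValueError("circular splits defined for n >= 4")
    seen: dict[Split, None] = {}
    for start in range(n):
        for length in range(1, n):
            arc = [perm[(start + k) % n] for k in range(length)]
            seen.setdefault(Split.from_members(arc, n), None)
    return list(seen)


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def build_design_matrix(splits: list[Split], n: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """The pair-by-split 0/1 incidence matrix and its row index.

    Rows run lexicographically over pairs ``(i, j)``, ``i < j`` — aligned
    with ``DistanceMatrix.condensed()``.  Entry ``(ij, k)`` is 1 iff split
    ``k`` separates ``i`` from ``j``.
    """
    iu, ju = _pair_indices(n)
    A = np.zeros((iu.size, len(splits)))
    for k, s in enumerate(splits):
        mask = np.zeros(n, dtype=bool)
        mask[list(s.side)] = True
        A[:, k] = mask[iu] ^ mask[ju]
    return A, list(zip(iu.tolist(), ju.tolist()))


def distance_vector(d: DistanceMatrix) -> np.ndarray:
    """Condensed distances in design-matrix row order."""
    return d.condensed()


def fit_ols(design: np.ndarray, dvec: np.ndarray) -> np.ndarray:
    """Unconstrained least-squares weights (possibly negative).

    Equivalent to the normal-equation solution ``(A'A)^{-1} A'd`` when the
    design has full column rank; raises if it does not (circular split
    systems always do).
    """
    sol, _, rank, _ = np.linalg.lstsq(design, np.asarray(dvec, float), rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix rank {rank} < {design.shape[1]} columns"
        )
    return sol


def fit_nnls(design: np.ndarray, dvec: np.ndarray) -> np.ndarray:
    """Non-negative least-squares weights via the active-set method.

    Solves ``min ||A b - d||_2  s.t.  b >= 0``.  At the solution the KKT
    conditions hold: the gradient ``A'(Ab - d)`` is ~0 on positive weights
    and >= 0 on zero weights (see :func:`kkt_residuals`).
    """
    sol, _ = _scipy_nnls(design, np.asarray(dvec, float))
    return sol


def kkt_residuals(design: np.ndarray, dvec: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """KKT violations of an NNLS solution.

    Returns ``(stationarity, dual_feasibility)``: the largest
    ``|gradient|`` over positive weights and the most negative gradient over
    zero weights (clipped at 0).  Both are ~0 at a true NNLS optimum.
    """
    weights = np.asarray(weights, float)
    grad = design.T @ (design @ weights - np.asarray(dvec, float))
    pos = weights > 0
    stationarity = float(np.abs(grad[pos]).max()) if pos.any() else 0.0
    dual = float(max(0.0, -(grad[~pos].min())) if (~pos).any() else 0.0)
    return stationarity, dual


@dataclass(frozen=True)
class WeightedSplitSystem:
    """Splits with fitted non-negative weights and their generating cycle.

    ``design`` and ``dvec`` (the fitted incidence matrix and condensed input
    distances) are kept so the fit can be scored after filtering.
    """

    splits: tuple[Split, ...]
    weights: np.ndarray
    cycle: CircularOrdering
    design: np.ndarray
    dvec: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, float)
        if weights.shape != (len(self.splits),):
            raise ValueError("one weight per split required")
        if self.design.shape != (self.dvec.shape[0], len(self.splits)):
            raise ValueError("design shape inconsistent with splits/dvec")
        object.__setattr__(self, "splits", tuple(self.splits))
        object.__setattr__(self, "weights", weights)
        labels = tuple(self.labels) or tuple(f"x{i + 1}" for i in range(self.cycle.n))
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.cycle.n

    def phyletic_distances(self) -> np.ndarray:
        """``p = A b``, the distances implied by the weighted splits."""
        return self.design @ self.weights

    def to_table(self) -> str:
        """TSV report (weight, member labels of the canonical side)."""
        lines = ["weight\tside"]
        for s, w in zip(self.splits, self.weights):
            members = " ".join(self.labels[i] for i in s.side)
            lines.append(f"{w:.12g}\t{members}")
        return "\n".join(lines) + "\n"


def weight_splits(
    d: DistanceMatrix,
    sigma: CircularOrdering,
    method: str = "nnls",
) -> WeightedSplitSystem:
    """Extract the circular splits of ``sigma`` and fit their weights to ``d``."""
    splits = circular_splits(sigma)
    design, _ = build_design_matrix(splits, d.n)
    dvec = distance_vector(d)
    if method == "nnls":
        w = fit_nnls(design, dvec)
    elif method == "ols":
        w = fit_ols(design, dvec)
    else:
        raise ValueError(f"unknown fitting method {method!r}")
    return WeightedSplitSystem(
        splits=tuple(splits), weights=w, cycle=sigma,
        design=design, dvec=dvec, labels=d.labels,
    )


def filter_splits(
    system: WeightedSplitSystem,
    threshold: float = DEFAULT_WEIGHT_THRESHOLD,
) -> WeightedSplitSystem:
    """Drop splits with weight <= ``threshold``.

    The active-set solver returns exact zeros on inactive splits, so the
    default threshold only guards against float noise.  The condensed
    distance vector is retained so :func:`fit_norm` still scores the reduced
    system against the original data.
    """
    keep = np.flatnonzero(system.weights > threshold)
    return WeightedSplitSystem(
        splits=tuple(system.splits[i] for i in keep),
        weights=system.weights[keep],
        cycle=system.cycle,
        design=system.design[:, keep],
        dvec=system.dvec,
        labels=system.labels,
    )


def fit_norm(system: WeightedSplitSystem) -> float:
    """Euclidean norm ``||A b - d||_2`` of the fit residual."""
    return float(np.linalg.norm(system.phyletic_distances() - system.dvec))
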