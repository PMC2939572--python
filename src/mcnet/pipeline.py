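"""End-to-end construction: distances -> ordering -> weighted splits."""

from __future__ import annotations

from dataclasses import replace

from .anneal import AnnealResult, AnnealSchedule, run_mcnet_ordering
from .distmat import DistanceMatrix
from .ordering import CircularOrdering
from .splits import (
    DEFAULT_WEIGHT_THRESHOLD,
    WeightedSplitSystem,
    filter_splits,
    weight_splits,
)

__all__ = ["build_split_network"]


def build_split_network(
    d: DistanceMatrix,
    schedule: AnnealSchedule | None = None,
    init: str = "greedy",
    given_sigma: CircularOrdering | None = None,
    restarts: int = 1,
    threshold: float = DEFAULT_WEIGHT_THRESHOLD,
) -> tuple[AnnealResult, WeightedSplitSystem]:
    """Run the full method on a distance matrix.

    Anneals ``restarts`` independent chains (seeds ``seed, seed+1, ...``),
    keeps the lowest-energy ordering, extracts its circular splits, fits
    non-negative weights and drops the zero ones.  Returns the winning
    annealing result and the filtered split system.
    """
    schedule = schedule or AnnealSchedule()
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best: AnnealResult | None = None
    for r in range(restarts):
        sched_r = replace(schedule, seed=schedule.seed + r)
        result = run_mcnet_ordering(d, init=init, given_sigma=given_sigma,
                                    schedule=sched_r)
        if best is None or result.energy_value < best.energy_value:
            best = result
    assert best is not None
    system = filter_splits(weight_splits(d, best.ordering), threshold)
    return best, system
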