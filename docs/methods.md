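# Methods

## The model

`mcnet` constructs *circular split networks* from pairwise distances.  A
split A|B of the taxon set X is circular with respect to a cyclic ordering
sigma of X when both sides are contiguous arcs of the cycle; a collection of
circular splits with positive weights can always be drawn as a planar split
network (by SplitsTree), and subsumes trees: the splits of any tree are
circular for a suitable ordering.

The method runs in two stages.

**Stage 1 — find a circular ordering.**  The target is the ordering
minimizing the closed-tour length

    eta(sigma) = d(x_sigma(1), x_sigma(n)) + sum_{k=1}^{n-1} d(x_sigma(k), x_sigma(k+1)),

the *energy* of the ordering.  Minimizing eta over cyclic orderings is a
travelling-salesman problem and NP-hard, so the search is heuristic:

1. *Greedy seed.*  Start a path with the closest pair of taxa; repeatedly
   attach the unplaced taxon closest to either end of the path at that end.
   Ties break deterministically (lexicographically smallest seed pair,
   smallest taxon index, tail before head) so the seed is reproducible.
2. *Simulated annealing.*  The single move type extracts the taxon at an
   interior position k (1-based 2..n-1) and appends it at the end; each
   state thus has exactly n-2 neighbours.  A move with energy change
   delta <= 0 is always accepted; an uphill move is accepted with
   probability exp(-delta/T).  After `reps_per_temp` moves the temperature
   is multiplied by `cooling`, until it falls below `t_low`.  The best
   ordering seen anywhere in the walk is returned (the raw final chain
   state is available with `return_best=False`).

**Stage 2 — weight the splits.**  The chosen ordering induces n(n-1)/2
circular splits (all contiguous arcs, deduplicated across complements,
including the n trivial single-taxon splits).  With A the 0/1 incidence
matrix over (pair, split) — `A[ij,k] = 1` iff split k separates i from j —
and d the condensed distance vector in lexicographic (i<j) order, weights
are fitted by non-negative least squares,

    min_b || A b - d ||_2   subject to  b >= 0,

using scipy's active-set NNLS solver.  Unconstrained OLS
(`b = (A'A)^{-1} A'd`) is exposed for comparison, but discarding its
negative weights grossly inflates the remainder, which is why the
constrained fit is the pipeline default.  Splits with weight below a small
threshold (1e-10, guarding only float noise: the active-set solver returns
exact zeros) are dropped; the survivors and their weights are what the
NEXUS output reports, together with the generating cycle.

## Parameters and defaults

| parameter        | default            | meaning / rationale |
|------------------|--------------------|---------------------|
| `t_initial`      | `eta(sigma_0)/n`   | mean tour-edge length of the start; gives ~50% initial uphill acceptance on typical inputs |
| `cooling`        | 0.9                | geometric cooling factor; quality/runtime balance point |
| `reps_per_temp`  | `100 * n`          | many sweeps of the (n-2)-move neighbourhood per temperature |
| `t_low`          | 1e-4               | stopping temperature; quality saturates below ~1e-3 |
| `seed`           | 0                  | one PCG64 generator drives neighbour choice, then the acceptance draw, per iteration |
| filter threshold | 1e-10              | drops the solver's exact zeros plus float noise |
| `restarts` (CLI) | 1                  | independent chains with seeds seed, seed+1, ...; off by default |

Units: temperatures are on the scale of the input distances (energy deltas
divide by T directly); weights are in the same units as the distances.

## The synthetic generators

The package tests itself on generated matrices rather than shipped data.

* `random_tree_metric(n, branch_range=(0.5, 2.0), seed)` draws a random
  unrooted binary topology by sequential leaf attachment, uniform branch
  lengths, and returns the patristic distances plus the ground-truth 2n-3
  splits.  The range (0.5, 2.0) gives a 4:1 spread of branch lengths —
  enough heterogeneity to be non-trivial while keeping all pairs well
  separated.
* `random_circular_metric(n, n_splits, weight_range=(0.5, 2.0), seed)`
  draws a random cycle and a subset of its arc splits (always including the
  n trivial splits so distinct taxa stay at positive distance), positive
  uniform weights, and returns `d = A w` with the ground truth.  The default
  `n_splits = min(2n, n(n-1)/2)` produces a moderately reticulate system.
* `perturb(d, noise_sd, seed)` adds symmetric Gaussian noise per unordered
  pair, truncated so distances stay non-negative.

What these do **not** emulate: estimation noise with distance-dependent
variance (model-based corrections), missing data, and near-ties between
distinct topologies as produced by real alignments.  Passing the recovery
tests shows the search and the fit are correct on their own terms, not that
the method resolves weak phylogenetic signal.

## Verification

* **Exhaustive oracle.**  For n <= 10 all (n-1)!/2 circular orderings are
  enumerated (first taxon fixed, reflection killed by `perm[1] < perm[-1]`),
  giving the true optimum.  On 70 noisy circular matrices at n = 7, 8 the
  annealer's agreement rate with the oracle is the headline search
  statistic (>= 95% expected under the defaults).
* **Exact-recovery identities.**  For a circular metric generated from a
  cycle with weights w, any tour crosses each split's two arc boundaries at
  least once each, so eta >= 2*sum(w) with equality exactly at compatible
  orderings; NNLS at such an ordering recovers w exactly (the incidence
  matrix of a full circular split system is invertible).  The tests assert
  both, at 1e-8/1e-6.
* **Fit optimality.**  Every NNLS solve in the suite is checked against its
  KKT conditions (gradient ~0 on the support, >= 0 off it), against OLS
  (whose residual it can never beat), and — on the 6-split quartet system —
  against an exhaustive search over all feasible supports.

## Numerical choices

* Energy deltas in the annealing loop are computed in O(1) from the three
  affected tour edges; the reported energy is recomputed from scratch at
  the end so drift cannot accumulate into results.
* Distance matrices are symmetrized on read; asymmetry up to 1e-6 is
  treated as text rounding and averaged, beyond that it is a data error.
* Circular orderings compare canonically (rotate taxon 0 first, orient by
  `perm[1] < perm[-1]`); annealing neighbours, however, are kept as raw
  permutations because the move set is defined on sequences.
* Degenerate inputs: an all-zero-energy start sets `t_initial = eta/n = 0`,
  which is below `t_low`, so the annealer returns the start unchanged — the
  correct fixed point.

## Known limitations

* The extract-and-append move is weak near good tours: from a near-optimal
  ordering almost every move is strongly uphill (the appended taxon joins
  unrelated neighbours), so a good greedy seed is also a strong attractor.
  In practice the search is reliable to n ~ 12-13 and recovers trees
  exactly in roughly 80-90% of runs at n = 14-20 under the default
  schedule; longer chains help only marginally.  Multiple restarts
  (`--restarts`) or seeding with an ordering from another method
  (`init="given"`) are the practical mitigations.
* The neighbourhood is not symmetric as a relation (the inverse of a move
  is not itself a move), although the classical convergence argument for
  annealing assumes symmetry; the move set is implemented exactly as
  defined rather than symmetrized.
* The exhaustive oracle refuses n > 10; beyond that only the 2*sum(w)
  identity is available as ground truth, and only for circular inputs.
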