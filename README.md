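# mcnet

Circular split networks from distance matrices.

Phylogenetic trees force every data set into a strictly branching history;
split *networks* relax this, displaying conflicting signals (recombination,
hybridization, model misfit) as bands of parallel edges.  `mcnet` builds the
weighted split system such a network is drawn from, starting from nothing
but a matrix of pairwise distances over `n >= 4` taxa.  It is aimed at
anyone who has a distance matrix (corrected sequence distances, MLST allele
profiles, ...) and wants a SplitsTree-renderable network out of it.

## The method

1. **Circular ordering.**  Find a cyclic arrangement σ of the taxa
   minimizing the closed-tour length

   η(σ) = d(x_σ(1), x_σ(n)) + Σ_{k=1}^{n−1} d(x_σ(k), x_σ(k+1)),

   via a greedy seed (grow a path from the closest pair, always attaching
   the nearest unplaced taxon to an end) refined by Monte-Carlo simulated
   annealing: uphill moves of size Δ are accepted with probability
   exp(−Δ/T) under a geometrically cooling temperature.
2. **Split weights.**  The ordering induces n(n−1)/2 circular splits (all
   contiguous arcs of the cycle).  With `A` the pair-by-split incidence
   matrix, weights solve the non-negative least-squares problem
   min‖Ab − d‖₂ s.t. b ≥ 0; zero-weight splits are dropped and the rest
   are written as a NEXUS SPLITS block (with the cycle) that SplitsTree
   opens directly.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

The quartet tree ((A,B),(C,D)) with all five branches of length 1 gives
cherry-pair distances 2 and cross-pair distances 3:

```sh
cat > quartet.dist <<EOF
4
A 0 2 3 3
B 2 0 3 3
C 3 3 0 2
D 3 3 2 0
EOF
mcnet run quartet.dist quartet.nex
```

prints

```json
{
  "accepted_uphill": 849,
  "energy": 10.0,
  "fit_norm": 0.0,
  "init": "greedy",
  "input": "quartet.dist",
  "iterations": 38800,
  "n": 4,
  "n_splits": 5,
  "output": "quartet.nex",
  "restarts": 1,
  "schedule": {"cooling": 0.9, "reps_per_temp": null, "t_initial": null, "t_low": 0.0001},
  "seed": 0
}
```

`energy` 10.0 is the optimal tour length — exactly twice the total branch
length, since an ordering compatible with the tree crosses each branch's
split twice.  `n_splits` 5 are the quartet's 2n−3 tree splits (four trivial
ones plus AB|CD), each recovered with weight 1, and `fit_norm` 0.0 says the
weighted splits reproduce the input distances exactly.  `quartet.nex`
contains the TAXA block, the cycle `1 2 3 4` and the five weighted splits;
opening it in SplitsTree draws the quartet tree.

The library mirrors the CLI:

```python
import mcnet
d = mcnet.read_distance_matrix("quartet.dist")
result, system = mcnet.build_split_network(d)
result.energy_value        # 10.0
len(system.splits)         # 5
mcnet.fit_norm(system)     # 0.0
```

`mcnet sweep in.dist out.csv --cooling 0.5,0.9 --tlow 1e-2,1e-4 --seeds 0,1,2`
runs the full factorial grid and reports the attained energy and move count
per cell, for schedule calibration.

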