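# Methods

## The flow model

All algorithms in this package iterate a column-stochastic *flow matrix*
M over a weighted undirected graph G = (V, E). Entry M(i, j) is the
probability flow from node j to node i; the starting point is
M_G = A·D⁻¹, where A is the adjacency matrix with self-loops added and D
its diagonal degree matrix. Because the graph is loaded from an edge
list, node ids are assigned by first appearance and every iteration order
derives from them, so runs are exactly reproducible for a fixed input and
seed.

One iteration applies, column by column:

1. a multiplication step — Expand (M·M) for classic MCL, Regularize
   (M·M_G) for R-MCL, or the balanced regularizer
   M_R = column_normal(diag(M⊤·mass)^(−b)·M_G) with mass(i) = Σⱼ M(i, j);
2. Inflate — entrywise power r followed by column renormalization, which
   concentrates each column's flow onto its strongest destinations;
3. Prune — entries below a threshold are dropped and the survivors
   renormalized, keeping the matrix sparse.

Nodes whose columns share an attractor row at convergence form one
cluster. Assignment takes each column's largest entry (ties to the
smallest row) and links attractors through union-find.

### Self-loop weights

The initial adjacency receives a self-loop of weight
max(1, max incident edge weight) on every node. This keeps a node's
self-influence comparable to its strongest tie: with a too-small loop,
flow drains out of weakly attached nodes in one step and singletons
proliferate. The rule is a configurable choice; any positive loop weight
yields a valid column-stochastic M_G.

## Coarsening

The multilevel driver first shrinks the graph. Super nodes carry node
weights Z′ (sum of member weights, i.e. member counts when the input is
unweighted), cross edges sum the fine cross-edge weights, and each super
node gets a self-loop equal to its total internal edge weight — so total
edge weight and total node weight are conserved exactly at every level
(both are asserted in tests as integer identities on integer-weighted
fixtures).

**Heavy edge matching (HEM)** pairs each unmatched node with its heaviest
unmatched neighbor. Because a super node has at most two children, a
k-leaf star needs k − 1 passes to collapse: on hub-heavy graphs — the
typical degree profile of protein interaction networks — the hierarchy
shrinks very slowly and each level buys little.

**Shotgun coarsening (SC)** visits each node once (skipping it with
probability p, one Bernoulli draw per node in visit order) and merges it
toward the group it is most heavily attached to *given the merges already
made in the same pass*: candidate weights are sums of the node's edge
weights into each current group. This within-pass aggregation is what
makes the scheme behave like its name — satellites glom onto growing
centers — and it is essential on unweighted graphs, where a selection
from the static weights faces ties on every edge and would nominate
module-bridging edges in proportion to their count, welding unrelated
modules together. Ties on aggregated weight break to the smallest group
weight Z (resisting massive super nodes), then to the candidate sharing
the most neighbors with the visited node (a within-module neighbor shares
many, a bridge endpoint almost none), then uniformly at random from the
seeded generator. The returned merge-edge set F is exactly reproduced by
connected components of (V, F).

Two guards bound the damage coarsening can do, because **clustering can
never split what coarsening has merged** (see Projection below):

- `max_super_weight` (driver default ⌈√n⌉) refuses merges that would push
  a group's weight past the cap. Without it, a dense module that has
  exhausted its internal merges has only other modules as candidates, and
  depth-3 coarsening of small graphs welds completed modules pairwise.
  At the network sizes the method targets (10⁴–10⁵ nodes at depth 3) the
  cap is slack.
- `min_coarse_nodes` (driver default ⌈√n⌉) drops trailing hierarchy
  levels smaller than the floor. The projected flow's support is one
  representative row per coarsest-level super node, so the coarsest size
  is a hard ceiling on the number of recoverable clusters.

## The multilevel driver

With hierarchy (G₀, …, G_ℓ): start at G_ℓ with M = M_G(G_ℓ), run
`iters_per_level` iterations (default 4 — enough to let structure form,
few enough that the coarse flow is not yet fully concentrated), project
to the next finer level, repeat, and run to convergence on G₀
(max absolute entrywise change ≤ `conv_tol`).

**Projection** re-expresses the coarse flow on the finer node set: every
fine node's column is its super node's column, with each coarse row's
mass placed on one *designated child* of that super node. Columns stay
exactly stochastic. The extracted clustering is invariant to which child
is designated (tested by brute force over all assignments on toy
hierarchies), but numerically the driver designates the child with the
largest weighted degree: the best-connected child receives the most
return flow from its neighbors, making the attractor robust. With an
arbitrary (e.g. lowest-id) designation, a module whose representative is
a peripheral node can lose its attractor during the finest-level
convergence and be absorbed by a neighbor.

Since every column of M is always a linear combination of existing
columns, the support of the projected flow — one representative row per
coarsest super node — can never grow. This is the formal reason
coarsening errors are unrecoverable downstream, and the reason for the
two guards above.

The balancing factor applies at every level, including the coarse ones.

## Parallel execution contract

Computing column j of the next flow matrix — sparse product
c = M · regularizer(:, j), Inflate, Prune — is independent of every other
column, and assembly writes each column into a storage region computed up
front from the column lengths, so regions are disjoint. Consequently the
result is bit-identical for any worker count; the thread-pool execution
is a determinism contract, not a throughput claim, and tests compare the
serialized output of 1-, 2- and 4-worker runs byte for byte. Within a
column, accumulation runs over the regularizer column's entries in
ascending index, fixing the floating-point result.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| r (`inflation`) | 2.0 | inflation exponent; > 1, larger ⇒ smaller clusters |
| b (`balance`) | 1.5 (multilevel), 0 (plain) | attractor-mass penalty; 0 = plain R-MCL; 1–1.5 gives complex-like size spreads |
| p (`skip_rate`) | 0.5 | per-node probability of skipping merge selection in SC |
| ℓ (`depth`) | 3 | coarsening levels |
| `iters_per_level` | 4 | flow iterations at each coarse level |
| `prune_threshold` | 1e-4 | per-column drop cutoff; an all-pruned column keeps its largest entry |
| `max_iters` / `conv_tol` | 200 / 1e-6 | convergence loop bounds |
| `max_super_weight` | ⌈√n⌉ | cap on super-node weight during coarsening |
| `min_coarse_nodes` | ⌈√n⌉ | resolution floor of the hierarchy |

## Numerical choices

- Values below 1e-15 in magnitude are dropped during canonicalization to
  stop rounding noise from filling in the sparsity pattern.
- Duplicate entries are summed at construction (standard sparse
  convention).
- In the balanced regularizer, a row with zero aggregated inbound mass
  (v_i = 0) is left unscaled; v_i^(−b) would be undefined and such a row
  carries nothing to penalize.
- Pruning a column whose entries all fall below the threshold keeps the
  single largest entry (ties to the smallest row) with value 1, so no
  column ever empties.
- NCut is computed on whichever graph is passed; the CLI evaluates on the
  self-looped transformed graph by default (consistent with what the
  clustering itself saw; self-loops never cross a cut and enter only the
  degree sums) and on the raw graph with `--raw-weights`.
- Accuracy (SST/PPV/ACC) restricts predicted clusters to the reference
  node universe by default, the usual protein-complex benchmark
  convention, since reference complex sets cover only part of a network.

## What the synthetic generators emulate — and what they do not

`fixtures` provides stars (hub-heavy coarsening behavior), rings of
cliques (planted modules with closed-form cuts), planted partitions
(statistically controlled recovery tests) and `ppi_like`, a clique ring
with a small satellite star per clique that mimics the dense-module-plus-
periphery topology on which classic MCL fragments. All are pure
functions of their parameters and seed. They do not reproduce real PPI
degree distributions, weight distributions from mass-spectrometry
confidence scores, or inter-complex overlap; passing tests demonstrate
the algorithmic properties (recovery, conservation, determinism,
fragmentation contrast) at desk scale, not biological accuracy on any
particular organism's interactome. Test problem sizes (96–500 nodes) are
chosen so the full suite runs in seconds while still exercising every
code path, including multi-level hierarchies and parallel assembly.

## Known limitations

- Clusters are hard partitions; overlapping complexes (shared subunits)
  are out of scope.
- Quality is bounded by the hierarchy: a merge error at any coarsening
  level cannot be undone by the flow iteration. The two coarsening guards
  make such errors rare on modular graphs but cannot exclude them.
- HEM mode at depth ≥ 2 can chain bridge matches across modules on
  tie-heavy unweighted graphs — the documented weakness of pairwise
  matching that shotgun coarsening exists to fix.
- The thread-based parallelism does not speed up pure-Python workloads;
  the `n_workers` surface exists to honor and test the determinism
  contract.
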