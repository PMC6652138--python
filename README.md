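# psmcl — multilevel regularized Markov clustering for weighted networks

`psmcl` detects modules — protein complexes, disease modules, functional
units — in weighted undirected interaction networks using flow-based
(Markov) clustering. It implements the full MCL family on one shared
sparse-flow engine:

- **MCL**: iterate a column-stochastic flow matrix *M* by *Expand*
  (*M ← M·M*), *Inflate* (*M<sub>ij</sub> ← M<sub>ij</sub><sup>r</sup> / Σ<sub>k</sub> M<sub>kj</sub><sup>r</sup>*, r > 1)
  and *Prune* (drop entries below a threshold, renormalize). Attractor rows
  at convergence define clusters. MCL is accurate but fragments: it emits
  many clusters of size 1–3, while biological complexes are typically 5–20.
- **R-MCL**: replace Expand with *Regularize* (*M ← M·M<sub>G</sub>*), where
  *M<sub>G</sub> = AD<sup>−1</sup>* is the initial flow matrix of the
  self-looped adjacency — the graph structure informs every iteration.
  The **balanced** variant computes *mass(i) = Σ<sub>j</sub> M<sub>ij</sub>* and regularizes with
  *M<sub>R</sub> = column_normal(diag(M<sup>⊤</sup>·mass)<sup>−b</sup> · M<sub>G</sub>)*;
  the balancing factor *b* ≥ 0 penalizes nodes already attracting much flow
  and steers cluster sizes toward a common scale (*b* = 0 recovers plain R-MCL).
- **PS-MCL** (the headline method): run balanced R-MCL through a multilevel
  hierarchy built by **shotgun coarsening** (SC) — each node merges toward
  the super node it is most heavily attached to, so whole stars and dense
  modules collapse in one pass, unlike heavy edge matching (HEM) which
  merges at most pairs. A skip rate *p* (one Bernoulli draw per node)
  tempers the reduction. A few flow iterations run at each coarse level,
  the flow is projected down by assigning each super node's flow to one
  child, and the finest level runs to convergence. All per-column work
  (sparse product, Inflate, Prune) runs over a compressed sparse column
  (CSC) representation and parallelizes across columns with bit-identical
  results for any worker count.

Quality is measured internally by the average normalized cut
(NCut(c) = cut(c)/degree(c), lower is better) and externally against
reference complexes by sensitivity (SST), positive predictive value (PPV)
and their geometric mean (ACC).

## Worked example

```python
from psmcl import MultilevelMCL, MarkovClustering
from psmcl.fixtures import ppi_like
from psmcl.evaluation import size_histogram, accuracy

graph, truth = ppi_like(45, 8, 2)          # 495 nodes: 45 dense modules,
                                           # each with a satellite star
ps = MultilevelMCL(balance=1.5, depth=3, skip_rate=0.5, random_state=0)
ps.fit(graph)
print(ps.n_clusters_)                      # 55
print(size_histogram(ps.clustering_))
# {'1-3': 36, '4': 8, '5-10': 96, '11-20': 311, '21-50': 44, '51+': 0}

baseline = MarkovClustering().fit(graph)
print(size_histogram(baseline.clustering_))
# {'1-3': 135, '4': 0, '5-10': 360, '11-20': 0, '21-50': 0, '51+': 0}

print(accuracy(truth, ps.clustering_)[2] > accuracy(truth, baseline.clustering_)[2])
```

Classic MCL strands every satellite star in its own tiny cluster — 135 of
495 nodes end up in clusters of size 1–3 — where PS-MCL keeps satellites
attached to their modules (36 nodes in tiny clusters, most nodes in
clusters of size 11–20, the biologically plausible range).

The estimators follow the scikit-learn clusterer protocol (`fit`,
`fit_predict`, `labels_`, `get_params`/`set_params`) and accept either a
`WeightedGraph` or a square symmetric affinity matrix (dense or scipy
sparse). `MarkovClustering`, `RegularizedMCL(balance=...)` and
`MultilevelMCL(scheme="sc" | "hem")` cover the family; the module-level
functions `psmcl.mcl`, `psmcl.r_mcl`, `psmcl.ps_mcl` and `psmcl.mlr_mcl`
are thin wrappers.

## Command line

```bash
psmcl generate ring --cliques 4 --clique-size 5 -o ring.txt --truth-out truth.txt
psmcl cluster ring.txt --algo ps-mcl -b 1.0 --depth 1 --seed 7 -o out.clusters --report run.json
psmcl evaluate ring.txt out.clusters --truth truth.txt
```

Edge lists are whitespace-separated `u v [w]` lines (`#` comments);
cluster files hold one cluster per line, tab-separated. Every command
honors `--seed`, and `--workers` never changes any output, only timing.

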