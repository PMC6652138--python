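"""Clustering quality metrics.

Internal quality is the normalized cut: for a cluster ``c``,

    NCut(c) = sum of edge weight leaving c / sum of weighted degrees in c,

averaged over clusters (lower is better; 0 means no external edges).
External accuracy against reference complexes uses the overlap table
``T[g, c] = |g ∩ c|``: sensitivity SST rewards ground-truth clusters that
are covered by some predicted cluster, positive predictive value PPV
rewards predicted clusters dominated by one ground-truth cluster, and ACC
is their geometric mean.  The size histogram counts nodes per cluster-size
band and is the lens on the fragmentation problem (many size 1-3 clusters).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .graph_io import Clustering, WeightedGraph

__all__ = [
    "ncut",
    "average_ncut",
    "size_histogram",
    "overlap_table",
    "accuracy",
    "DEFAULT_SIZE_BINS",
]

# Size bands conventional for complex-size reporting; last band open-ended.
DEFAULT_SIZE_BINS: tuple[tuple[int, float], ...] = (
    (1, 3),
    (4, 4),
    (5, 10),
    (11, 20),
    (21, 50),
    (51, float("inf")),
)


def ncut(g: WeightedGraph, cluster: set[str] | frozenset[str]) -> float:
    """Normalized cut of one node set: external edge weight over degree sum.

    Self-loops never cross the boundary, so they appear only in the
    denominator (each node's weighted degree counts its self-loop once).
    The metric is computed on the graph as given; pass the raw or the
    self-looped graph depending on which weighting is wanted.
    """
    if not cluster:
        raise ValueError("NCut of an empty cluster is undefined")
    ids = {g.node_id(lab) for lab in cluster}
    cut = 0.0
    degree_sum = 0.0
    for u in ids:
        degree_sum += g.weighted_degree(u)
        for v, w in g.neighbors(u).items():
            if v not in ids:
                cut += w
    if degree_sum == 0:
        return 0.0
    return cut / degree_sum


def average_ncut(g: WeightedGraph, clustering: Clustering) -> float:
    """Arithmetic mean of per-cluster NCut over the partition."""
    if clustering.n_clusters == 0:
        raise ValueError("average NCut of an empty clustering is undefined")
    return float(np.mean([ncut(g, c) for c in clustering.clusters]))


def size_histogram(
    clustering: Clustering,
    bins: Sequence[tuple[int, float]] = DEFAULT_SIZE_BINS,
) -> dict[str, int]:
    """Nodes per cluster-size band: a cluster of size s adds s to s's band."""
    out: dict[str, int] = {}
    keys = []
    for lo, hi in bins:
        key = f"{lo}" if lo == hi else (f"{lo}+" if hi == float("inf") else f"{lo}-{int(hi)}")
        keys.append((lo, hi, key))
        out[key] = 0
    for s in clustering.sizes():
        for lo, hi, key in keys:
            if lo <= s <= hi:
                out[key] += s
                break
        else:
            raise ValueError(f"cluster size {s} not covered by bins")
    return out


def overlap_table(
    truth: Clustering, pred: Clustering, restrict_to_truth: bool = True
) -> tuple[np.ndarray, list[frozenset[str]], list[frozenset[str]]]:
    """Overlap counts T[g, c] = |g ∩ c|.

    With ``restrict_to_truth`` (the usual protein-complex benchmark
    convention) predicted clusters are first intersected with the union of
    the reference clusters, and predicted clusters that then become empty
    are dropped — reference complex sets cover only part of a network.
    """
    if truth.n_clusters == 0 or pred.n_clusters == 0:
        raise ValueError("accuracy requires non-empty truth and prediction")
    truth_sets = list(truth.clusters)
    pred_sets = list(pred.clusters)
    if restrict_to_truth:
        universe = truth.nodes
        pred_sets = [frozenset(c & universe) for c in pred_sets]
        pred_sets = [c for c in pred_sets if c]
        if not pred_sets:
            raise ValueError("no predicted cluster overlaps the reference node set")
    T = np.array(
        [[len(gset & cset) for cset in pred_sets] for gset in truth_sets],
        dtype=np.int64,
    )
    return T, truth_sets, pred_sets


def accuracy(
    truth: Clustering, pred: Clustering, restrict_to_truth: bool = True
) -> tuple[float, float, float]:
    """(SST, PPV, ACC) from the overlap table.

    SST = sum_g max_c T[g,c] / sum_g |g|;
    PPV = sum_c max_g T[g,c] / sum_c |c|;
    ACC = sqrt(SST * PPV).
    """
    T, truth_sets, pred_sets = overlap_table(truth, pred, restrict_to_truth)
    sst = T.max(axis=1).sum() / sum(len(s) for s in truth_sets)
    ppv = T.max(axis=0).sum() / sum(len(s) for s in pred_sets)
    return float(sst), float(ppv), float(np.sqrt(sst * ppv))
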