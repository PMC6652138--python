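"""Multilevel driver: coarsen, iterate flow at each level, project down.

The driver builds a hierarchy (G_0, ..., G_l), runs a few R-MCL iterations
on the coarsest graph, projects the partially converged flow down one level
at a time — re-running a few iterations at each — and finally iterates to
convergence on the original graph.  With shotgun coarsening this is PS-MCL;
with heavy edge matching it is MLR-MCL, the baseline it improves on.

Flow projection assigns all of a super node's flow to one designated child
(the smallest-id child here); the extracted clustering is invariant to which
child is designated, since the subsequent regularization redistributes flow
along the fine graph's own edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coarsening import Hierarchy, NodeMap, Scheme, build_hierarchy
from .graph_io import Clustering, WeightedGraph, add_self_loops, initial_flow_matrix
from .rmcl_engine import (
    FlowState,
    RmclParams,
    extract_clusters,
    rmcl_step,
    run_to_convergence,
)
from .sparse_core import CscMatrix, SparseColumn, assemble

__all__ = ["DriverConfig", "project_flow", "ps_mcl", "mlr_mcl", "run_multilevel"]


@dataclass(frozen=True)
class DriverConfig:
    """Configuration of a multilevel run.

    depth : number of coarsening levels (0 disables coarsening).
    scheme : 'sc' (PS-MCL) or 'hem' (MLR-MCL).
    p : shotgun-coarsening skip rate in [0, 1); ignored by HEM.
    params : flow-iteration parameters; the balancing factor applies at
        every level.
    seed : seeds the coarsening skip draws; the flow iteration itself is
        deterministic.
    min_coarse_nodes : resolution floor — levels coarser than this many
        super nodes are dropped before iterating.  The projected flow's
        support is one representative row per coarsest super node, so the
        coarsest size is a hard cap on the number of recoverable clusters;
        the floor keeps that cap from binding on small graphs.  ``None``
        uses ``ceil(sqrt(n))``.
    max_super_weight : cap on the aggregate node weight of any super node
        during coarsening.  Clustering cannot split what coarsening has
        merged, and a dense module with no internal merges left would
        otherwise be welded onto a neighboring module; the cap refuses such
        merges.  ``None`` uses ``ceil(sqrt(n))``, which leaves the cap
        slack at the network sizes the method targets while protecting
        small graphs.
    """

    depth: int = 3
    scheme: Scheme = "sc"
    p: float = 0.5
    params: RmclParams = field(default_factory=lambda: RmclParams(b=1.5))
    seed: int = 0
    n_workers: int = 1
    min_coarse_nodes: int | None = None
    max_super_weight: float | None = None


def project_flow(
    M_coarse: CscMatrix,
    node_map: NodeMap,
    designated: dict[int, int] | None = None,
) -> CscMatrix:
    """Re-express a coarse flow matrix on the finer node set.

    Every fine node's column is the column of its super node, with each
    coarse row's mass placed on that super node's designated child (smallest
    id unless ``designated`` overrides); all other fine rows are zero.
    Columns remain exactly stochastic because mass is moved, never rescaled.
    """
    n_super = node_map.n_super
    if M_coarse.n_rows != n_super or M_coarse.n_cols != n_super:
        raise ValueError(
            f"coarse matrix {M_coarse.shape} does not match {n_super} super nodes"
        )
    if designated is None:
        rep = [members[0] for members in node_map.children]
    else:
        rep = [designated[s] for s in range(n_super)]
        for s, u in enumerate(rep):
            if node_map.fine_to_super[u] != s:
                raise ValueError(f"designated child {u} not in super node {s}")
    n_fine = node_map.n_fine
    cols = []
    super_cols: list[SparseColumn] = []
    for s in range(n_super):
        col = M_coarse.column(s)
        fine_rows = np.array([rep[t] for t in col.rows], dtype=np.int64)
        order = np.argsort(fine_rows)
        super_cols.append(SparseColumn(n_fine, fine_rows[order], col.values[order]))
    for u in range(n_fine):
        cols.append(super_cols[node_map.fine_to_super[u]])
    return assemble(cols, n_fine, n_fine)


def run_multilevel(g: WeightedGraph, cfg: DriverConfig) -> tuple[Clustering, dict]:
    """Full multilevel run; returns the clustering and a run report.

    The report carries per-level node counts and the iteration count at the
    finest level, the observables that distinguish the coarsening schemes.
    """
    if g.n_nodes == 0:
        raise ValueError("cannot cluster an empty graph")
    rng = np.random.default_rng(cfg.seed)
    gl = g if g.has_self_loops() else add_self_loops(g)
    z_cap = cfg.max_super_weight
    if z_cap is None:
        z_cap = float(np.ceil(np.sqrt(gl.n_nodes)))
    hierarchy = build_hierarchy(gl, cfg.depth, cfg.scheme, cfg.p, rng, z_cap)
    floor = cfg.min_coarse_nodes
    if floor is None:
        floor = int(np.ceil(np.sqrt(gl.n_nodes)))
    levels = list(hierarchy.levels)
    while levels and levels[-1].graph.n_nodes < floor:
        levels.pop()
    hierarchy = Hierarchy(gl, tuple(levels))
    clustering, info = _iterate_hierarchy(hierarchy, cfg)
    info["n_clusters"] = clustering.n_clusters
    return clustering, info


def _iterate_hierarchy(hierarchy: Hierarchy, cfg: DriverConfig) -> tuple[Clustering, dict]:
    params = cfg.params
    depth = hierarchy.depth
    coarsest = hierarchy.graph_at(depth)
    M_G = initial_flow_matrix(coarsest)
    state = FlowState(M_G, M_G)
    for i in range(depth, 0, -1):
        for _ in range(params.iters_per_level):
            state = rmcl_step(state, params, cfg.n_workers)
        finer = hierarchy.graph_at(i - 1)
        node_map = hierarchy.levels[i - 1].map
        # The clustering is invariant to which child carries the flow, but
        # numerically the best-connected child makes the sturdiest
        # attractor: its neighbors route the most flow back to it.
        designated = {
            s: max(members, key=lambda u: (finer.weighted_degree(u), -u))
            for s, members in enumerate(node_map.children)
        }
        M_fine = project_flow(state.M, node_map, designated)
        state = FlowState(M_fine, initial_flow_matrix(finer))
    state = run_to_convergence(state, params, cfg.n_workers)
    clustering = extract_clusters(state.M, hierarchy.base.labels)
    info = {
        "level_node_counts": hierarchy.node_counts(),
        "n_iters_finest": state.n_iters,
    }
    return clustering, info


def ps_mcl(g: WeightedGraph, cfg: DriverConfig | None = None, **overrides) -> Clustering:
    """PS-MCL: multilevel balanced R-MCL with shotgun coarsening."""
    cfg = _with_scheme(cfg, "sc", overrides)
    return run_multilevel(g, cfg)[0]


def mlr_mcl(g: WeightedGraph, cfg: DriverConfig | None = None, **overrides) -> Clustering:
    """MLR-MCL: multilevel R-MCL with heavy edge matching (the baseline)."""
    cfg = _with_scheme(cfg, "hem", overrides)
    return run_multilevel(g, cfg)[0]


def _with_scheme(cfg: DriverConfig | None, scheme: Scheme, overrides: dict) -> DriverConfig:
    from dataclasses import replace

    cfg = cfg if cfg is not None else DriverConfig()
    return replace(cfg, scheme=scheme, **overrides)
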