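"""The flow-iteration core of MCL-family clustering.

A column-stochastic flow matrix ``M`` is iterated to a fixed point by
alternating an expansion-type step with *Inflate* (entrywise power ``r``
followed by column renormalization, concentrating flow on attractors) and
*Prune* (dropping negligible entries to keep the matrix sparse).  Classic
MCL expands with ``M @ M``; regularized MCL (R-MCL) instead multiplies by
the fixed initial flow matrix ``M_G``, so the graph's adjacency structure
informs every iteration.  The balanced variant penalizes rows that already
attract much flow: with ``mass = row sums of M`` the regularizer becomes

    M_R = column_normal( diag(M^T @ mass)^(-b) @ M_G ),

where ``b >= 0`` steers cluster sizes toward a common scale and ``b = 0``
recovers plain R-MCL exactly.

All per-column work (the sparse product ``c = M @ regularizer[:, j]``,
Inflate, Prune) is independent across columns and written into disjoint
storage regions, so the iteration parallelizes over columns with a result
that is bit-identical for any worker count.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, replace

import numpy as np

from .graph_io import Clustering, WeightedGraph, add_self_loops, initial_flow_matrix
from .sparse_core import CscMatrix, SparseColumn, assemble, csc_from_entries, spmspv

__all__ = [
    "RmclParams",
    "FlowState",
    "expand",
    "regularize",
    "balanced_regularizer",
    "inflate_column",
    "prune_column",
    "rmcl_step",
    "run_to_convergence",
    "extract_clusters",
    "mcl",
    "r_mcl",
]


@dataclass(frozen=True)
class RmclParams:
    """Tunable parameters of the flow iteration.

    r : inflation exponent, > 1 (sharper flow concentration for larger r).
    b : balancing factor, >= 0; 0 disables balancing.
    prune_threshold : per-column cutoff below which entries are dropped.
    max_iters : hard cap on iterations of the convergence loop.
    conv_tol : stop when the max absolute entrywise change falls below this.
    iters_per_level : R-MCL steps run at each coarse level of a hierarchy.
    """

    r: float = 2.0
    b: float = 0.0
    prune_threshold: float = 1e-4
    max_iters: int = 200
    conv_tol: float = 1e-6
    iters_per_level: int = 4

    def __post_init__(self) -> None:
        if self.r <= 1:
            raise ValueError("inflation exponent r must be > 1")
        if self.b < 0:
            raise ValueError("balancing factor b must be >= 0")
        if not 0 <= self.prune_threshold < 1:
            raise ValueError("prune_threshold must be in [0, 1)")
        if self.conv_tol <= 0:
            raise ValueError("conv_tol must be positive")


@dataclass(frozen=True)
class FlowState:
    """Current flow matrix plus the fixed initial flow matrix M_G.

    When ``b > 0`` the effective regularizer M_R is recomputed from the
    current M every iteration; M_G itself never changes.
    """

    M: CscMatrix
    regularizer: CscMatrix
    n_iters: int = 0


def _check_square(M: CscMatrix) -> None:
    if M.n_rows != M.n_cols:
        raise ValueError(f"flow matrix must be square, got {M.shape}")


def _matmul(A: CscMatrix, B: CscMatrix, n_workers: int = 1) -> CscMatrix:
    """A @ B, computed column-by-column via spmspv and reassembled."""
    if A.n_cols != B.n_rows:
        raise ValueError(f"dimension mismatch: {A.shape} @ {B.shape}")
    cols = _map_columns(lambda j: spmspv(A, B.column(j)), B.n_cols, n_workers)
    return assemble(cols, A.n_rows, B.n_cols)


def _map_columns(fn, n_cols: int, n_workers: int) -> list[SparseColumn]:
    if n_workers <= 1 or n_cols < 2:
        return [fn(j) for j in range(n_cols)]
    with ThreadPoolExecutor(max_workers=n_workers) as pool:
        return list(pool.map(fn, range(n_cols)))


def expand(M: CscMatrix, n_workers: int = 1) -> CscMatrix:
    """Classic MCL expansion, M @ M."""
    _check_square(M)
    return _matmul(M, M, n_workers)


def regularize(M: CscMatrix, M_G: CscMatrix, n_workers: int = 1) -> CscMatrix:
    """R-MCL regularization, M @ M_G."""
    return _matmul(M, M_G, n_workers)


def balanced_regularizer(M: CscMatrix, M_G: CscMatrix, b: float) -> CscMatrix:
    """M_R = column_normal(diag(M^T @ mass)^(-b) @ M_G).

    ``mass[i]`` is the total flow currently entering node i (row sum of M);
    ``v = M^T @ mass`` aggregates it along each node's outgoing flow, and
    rows of M_G are damped by ``v^(-b)`` before renormalizing columns.  A
    zero ``v[i]`` (no inbound mass to penalize) leaves row i unscaled.
    With b = 0 the result is M_G exactly.
    """
    if b < 0:
        raise ValueError("balancing factor b must be >= 0")
    if b == 0:
        return M_G
    _check_square(M)
    mass = M.row_sums()
    v = np.zeros(M.n_cols)
    for j in range(M.n_cols):
        col = M.column(j)
        v[j] = float(np.dot(col.values, mass[col.rows]))
    scale = np.ones_like(v)
    nz = v > 0
    scale[nz] = v[nz] ** (-b)
    cols = []
    for j in range(M_G.n_cols):
        col = M_G.column(j)
        scaled = col.values * scale[col.rows]
        total = scaled.sum()
        if total > 0:
            scaled = scaled / total
        cols.append(SparseColumn(col.length, col.rows, scaled))
    return assemble(cols, M_G.n_rows, M_G.n_cols)


def inflate_column(c: SparseColumn, r: float) -> SparseColumn:
    """Entrywise power r followed by renormalization to sum 1."""
    if c.nnz == 0:
        raise ValueError("cannot inflate an all-zero column")
    powered = c.values**r
    return SparseColumn(c.length, c.rows, powered / powered.sum())


def prune_column(c: SparseColumn, threshold: float) -> SparseColumn:
    """Drop entries below ``threshold`` and renormalize survivors to sum 1.

    If every entry falls below the threshold the single largest entry (ties
    to the smallest row) is retained with value 1, so no column ever
    becomes empty.
    """
    keep = c.values >= threshold
    if not keep.any():
        best = int(np.argmax(c.values))  # argmax takes the first = smallest row
        return SparseColumn(c.length, c.rows[best : best + 1], np.ones(1))
    vals = c.values[keep]
    return SparseColumn(c.length, c.rows[keep], vals / vals.sum())


def rmcl_step(state: FlowState, params: RmclParams, n_workers: int = 1) -> FlowState:
    """One R-MCL iteration: per column, regularize then inflate then prune.

    When ``params.b > 0`` the balanced regularizer M_R is recomputed from
    the current M first.  Per-column computations are independent and each
    column's storage region in the assembled result is disjoint, so the
    output is identical for any worker count.
    """
    M = state.M
    reg = balanced_regularizer(M, state.regularizer, params.b)

    def one_column(j: int) -> SparseColumn:
        c = spmspv(M, reg.column(j))
        return prune_column(inflate_column(c, params.r), params.prune_threshold)

    cols = _map_columns(one_column, M.n_cols, n_workers)
    return replace(state, M=assemble(cols, M.n_rows, M.n_cols), n_iters=state.n_iters + 1)


def _mcl_step(M: CscMatrix, params: RmclParams, n_workers: int = 1) -> CscMatrix:
    """One classic MCL iteration: expand then inflate then prune."""

    def one_column(j: int) -> SparseColumn:
        c = spmspv(M, M.column(j))
        return prune_column(inflate_column(c, params.r), params.prune_threshold)

    cols = _map_columns(one_column, M.n_cols, n_workers)
    return assemble(cols, M.n_rows, M.n_cols)


def _max_abs_diff(A: CscMatrix, B: CscMatrix) -> float:
    delta: dict[tuple[int, int], float] = {}
    for i, j, x in A.entries():
        delta[(i, j)] = x
    for i, j, x in B.entries():
        delta[(i, j)] = delta.get((i, j), 0.0) - x
    return max((abs(d) for d in delta.values()), default=0.0)


def run_to_convergence(
    state: FlowState, params: RmclParams, n_workers: int = 1
) -> FlowState:
    """Iterate rmcl_step until the flow matrix stops changing.

    Convergence is declared when the max absolute entrywise change drops to
    ``conv_tol`` or below, or after ``max_iters`` iterations.
    """
    for _ in range(params.max_iters):
        new = rmcl_step(state, params, n_workers)
        change = _max_abs_diff(new.M, state.M)
        state = new
        if change <= params.conv_tol:
            break
    return state


def extract_clusters(M: CscMatrix, labels: list[str]) -> Clustering:
    """Read a clustering off a converged flow matrix.

    Each column (node) is assigned to the attractor row holding its largest
    entry, ties to the smallest row; nodes sharing an attractor — directly
    or through chains of attractor columns — form one cluster.
    """
    _check_square(M)
    n = M.n_cols
    if len(labels) != n:
        raise ValueError("label count must match matrix size")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j in range(n):
        col = M.column(j)
        if col.nnz == 0:
            raise ValueError(f"column {j} is empty; matrix is not a converged flow")
        attractor = int(col.rows[np.argmax(col.values)])  # first max = smallest row
        ru, rv = find(j), find(attractor)
        if ru != rv:
            parent[max(ru, rv)] = min(ru, rv)
    return Clustering.from_labels(labels, [find(j) for j in range(n)])


def r_mcl(
    g: WeightedGraph, params: RmclParams = RmclParams(), n_workers: int = 1
) -> Clustering:
    """(Balanced) R-MCL on a graph: self-loops, M = M_G, iterate, extract."""
    gl = g if g.has_self_loops() else add_self_loops(g)
    M_G = initial_flow_matrix(gl)
    state = run_to_convergence(FlowState(M_G, M_G), params, n_workers)
    return extract_clusters(state.M, g.labels)


def mcl(
    g: WeightedGraph, params: RmclParams = RmclParams(), n_workers: int = 1
) -> Clustering:
    """Classic MCL (expand/inflate/prune), the comparison baseline."""
    gl = g if g.has_self_loops() else add_self_loops(g)
    M = initial_flow_matrix(gl)
    for _ in range(params.max_iters):
        new = _mcl_step(M, params, n_workers)
        change = _max_abs_diff(new, M)
        M = new
        if change <= params.conv_tol:
            break
    return extract_clusters(M, g.labels)
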