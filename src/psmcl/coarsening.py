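"""Graph coarsening: heavy edge matching and shotgun coarsening.

Both schemes shrink a graph by merging nodes into weighted super nodes; the
coarse graph carries node weights ``Z'`` (merged-node counts), cross-edge
weights summed from the fine graph, and a self-loop per super node holding
the total intra-super-node edge weight.  Heavy edge matching (HEM) merges at
most pairs, so hub-heavy graphs — stars, the signature motif of
protein-interaction networks — shrink by only one node per hub per level.
Shotgun coarsening (SC) lets every node nominate one merge edge and takes
connected components of the nominations, collapsing a whole star in a single
level; a per-node skip probability ``p`` damps the reduction so super nodes
do not grow without bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .graph_io import WeightedGraph

__all__ = [
    "NodeMap",
    "CoarseLevel",
    "Hierarchy",
    "hem_match",
    "sc_select_merge_edges",
    "sc_partition",
    "build_coarse_graph",
    "coarsen",
    "build_hierarchy",
]

Scheme = Literal["hem", "sc"]


@dataclass(frozen=True)
class NodeMap:
    """Total map from fine-node id to super-node id, with child lists."""

    fine_to_super: tuple[int, ...]
    children: tuple[tuple[int, ...], ...]  # children[S] sorted ascending

    @classmethod
    def from_assignment(cls, assignment: list[int]) -> "NodeMap":
        """Relabel super nodes densely, ordered by smallest member id."""
        groups: dict[int, list[int]] = {}
        for u, s in enumerate(assignment):
            groups.setdefault(s, []).append(u)
        ordered = sorted(groups.values(), key=lambda g: g[0])
        fine_to_super = [0] * len(assignment)
        for sid, members in enumerate(ordered):
            for u in members:
                fine_to_super[u] = sid
        return cls(tuple(fine_to_super), tuple(tuple(sorted(g)) for g in ordered))

    @classmethod
    def identity(cls, n: int) -> "NodeMap":
        return cls(tuple(range(n)), tuple((u,) for u in range(n)))

    @property
    def n_fine(self) -> int:
        return len(self.fine_to_super)

    @property
    def n_super(self) -> int:
        return len(self.children)


@dataclass(frozen=True)
class CoarseLevel:
    """A coarsened graph together with the map from the finer level."""

    graph: WeightedGraph
    map: NodeMap


@dataclass(frozen=True)
class Hierarchy:
    """(G_0, CoarseLevel_1, ..., CoarseLevel_l), finest first."""

    base: WeightedGraph
    levels: tuple[CoarseLevel, ...]

    @property
    def depth(self) -> int:
        return len(self.levels)

    def graph_at(self, i: int) -> WeightedGraph:
        return self.base if i == 0 else self.levels[i - 1].graph

    def node_counts(self) -> list[int]:
        return [self.graph_at(i).n_nodes for i in range(self.depth + 1)]


def hem_match(
    g: WeightedGraph,
    rng: np.random.Generator | None = None,
    max_super_weight: float | None = None,
) -> NodeMap:
    """Heavy edge matching: each node pairs with its heaviest unmatched
    neighbor; super nodes have at most two children.

    Nodes are visited in ascending id; ties on edge weight break to the
    smallest neighbor id.  ``max_super_weight`` refuses pairs whose
    combined node weight would exceed the cap.  ``rng`` is accepted for
    interface symmetry with SC but HEM as implemented is deterministic.
    """
    n = g.n_nodes
    mate = [-1] * n
    for u in range(n):
        if mate[u] != -1:
            continue
        best_v, best_w = -1, 0.0
        for v, w in g.neighbors(u).items():
            if mate[v] != -1:
                continue
            if max_super_weight is not None and g.Z[u] + g.Z[v] > max_super_weight:
                continue
            if w > best_w or (w == best_w and (best_v == -1 or v < best_v)):
                best_v, best_w = v, w
        if best_v != -1:
            mate[u] = best_v
            mate[best_v] = u
    assignment = [u if mate[u] == -1 else min(u, mate[u]) for u in range(n)]
    return NodeMap.from_assignment(assignment)


def sc_select_merge_edges(
    g: WeightedGraph,
    p: float,
    rng: np.random.Generator,
    max_super_weight: float | None = None,
) -> set[tuple[int, int]]:
    """Select the merge-edge set F of shotgun coarsening.

    Each node ``u`` is visited in id order; with probability ``p`` (one
    Bernoulli draw per node, consumed in visit order) selection is skipped.
    Otherwise ``u`` merges toward the *current* super node it is most
    heavily attached to: candidate weights aggregate ``u``'s edge weights
    over the groups already formed earlier in the pass, so a node with two
    unit edges into a growing super node prefers it over a single unit edge
    to a lone neighbor.  This within-pass aggregation is what makes the
    scheme shotgun-like — satellites glom onto centers — and keeps super
    nodes cohesive; selecting from the static weights instead lets the
    many ties of an unweighted graph nominate bridge edges and weld
    unrelated regions together.  Ties on aggregated weight are broken by
    the smallest aggregated node weight ``Z`` (resisting massive super
    nodes), then by the largest shared-neighbor count with the candidate
    edge's endpoint (a neighbor inside ``u``'s own dense module shares many
    neighbors with it, a bridge endpoint almost none), and finally by a
    uniform draw from the seeded source.
    ``max_super_weight`` caps the aggregate weight of a group: merges that
    would exceed it are refused and the next-best candidate is taken, so a
    fully coarsened dense module cannot be welded onto another one merely
    because it has no internal merges left.

    Returns the merge-edge set F: one edge (u, best-attached neighbor in
    the chosen group) per merging node; connected components of (V, F)
    reproduce exactly the groups formed in the pass.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"skip rate must be in [0, 1), got {p}")
    parent = list(range(g.n_nodes))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    group_z: dict[int, int] = {u: g.Z[u] for u in range(g.n_nodes)}
    F: set[tuple[int, int]] = set()
    for u in range(g.n_nodes):
        skip = rng.random() < p
        if skip:
            continue
        nb = g.neighbors(u)
        if not nb:
            continue
        ru = find(u)
        # aggregate u's attachment per current group, tracking the heaviest
        # single edge into each group as the representative merge edge
        attach: dict[int, float] = {}
        rep_edge: dict[int, tuple[float, int]] = {}
        for v, w in nb.items():
            rv = find(v)
            if rv == ru:
                continue
            attach[rv] = attach.get(rv, 0.0) + w
            if rv not in rep_edge or (w, -v) > rep_edge[rv]:
                rep_edge[rv] = (w, -v)
        if max_super_weight is not None:
            zu = group_z[ru]
            attach = {r: w for r, w in attach.items()
                      if zu + group_z[r] <= max_super_weight}
        if not attach:
            continue
        wmax = max(attach.values())
        cand = [r for r, w in attach.items() if w == wmax]
        if len(cand) > 1:
            zmin = min(group_z[r] for r in cand)
            cand = [r for r in cand if group_z[r] == zmin]
        if len(cand) > 1:
            u_nb = set(nb)
            shared = {r: len(u_nb & g.neighbors(-rep_edge[r][1]).keys()) for r in cand}
            smax = max(shared.values())
            cand = [r for r in cand if shared[r] == smax]
        if len(cand) > 1:
            cand_ids = sorted(-rep_edge[r][1] for r in cand)
            pick = int(cand_ids[rng.integers(len(cand_ids))])
            best_root = find(pick)
        else:
            best_root = cand[0]
        best = -rep_edge[best_root][1]
        F.add((u, best) if u <= best else (best, u))
        z_new = group_z[ru] + group_z[best_root]
        parent[max(ru, best_root)] = min(ru, best_root)
        group_z[min(ru, best_root)] = z_new
    return F


def sc_partition(n_nodes: int, F: set[tuple[int, int]]) -> NodeMap:
    """Super nodes = connected components of the merge-edge graph (V, F)."""
    parent = list(range(n_nodes))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in F:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[max(ru, rv)] = min(ru, rv)
    return NodeMap.from_assignment([find(u) for u in range(n_nodes)])


def build_coarse_graph(g: WeightedGraph, node_map: NodeMap) -> WeightedGraph:
    """Aggregate G along a node map.

    ``Z'(S)`` sums the member node weights; ``W'(S, S)`` sums all intra-S
    edge weights of G including G's own self-loops; ``W'(S, T)`` sums the
    S–T cross edges, present only when at least one such edge exists.
    """
    coarse = WeightedGraph()
    for members in node_map.children:
        sid = coarse.add_node("+".join(g.labels[u] for u in members))
        coarse.Z[sid] = sum(g.Z[u] for u in members)
    f2s = node_map.fine_to_super
    self_w: dict[int, float] = {}
    for (u, v), w in g.W.items():
        su, sv = f2s[u], f2s[v]
        if su == sv:
            self_w[su] = self_w.get(su, 0.0) + w
        else:
            coarse.add_edge(su, sv, w)
    for s, w in self_w.items():
        coarse.set_self_loop(s, w)
    return coarse


def coarsen(
    g: WeightedGraph,
    scheme: Scheme = "sc",
    p: float = 0.5,
    rng: np.random.Generator | None = None,
    max_super_weight: float | None = None,
) -> CoarseLevel:
    """One coarsening step with the chosen scheme."""
    if rng is None:
        rng = np.random.default_rng(0)
    if scheme == "hem":
        node_map = hem_match(g, rng, max_super_weight)
    elif scheme == "sc":
        F = sc_select_merge_edges(g, p, rng, max_super_weight)
        node_map = sc_partition(g.n_nodes, F)
    else:
        raise ValueError(f"unknown coarsening scheme {scheme!r}")
    return CoarseLevel(build_coarse_graph(g, node_map), node_map)


def build_hierarchy(
    g: WeightedGraph,
    depth: int,
    scheme: Scheme = "sc",
    p: float = 0.5,
    rng: np.random.Generator | None = None,
    max_super_weight: float | None = None,
) -> Hierarchy:
    """Coarsen repeatedly up to ``depth`` levels.

    Stops early (truncating the hierarchy) as soon as a step fails to reduce
    the node count, so the coarsest graph is never a trivial copy.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    levels: list[CoarseLevel] = []
    current = g
    for _ in range(depth):
        level = coarsen(current, scheme, p, rng, max_super_weight)
        if level.graph.n_nodes >= current.n_nodes:
            break
        levels.append(level)
        current = level.graph
    return Hierarchy(g, tuple(levels))
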