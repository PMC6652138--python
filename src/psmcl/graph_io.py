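"""Weighted-graph data model and the plain-text formats around it.

Graphs come in as whitespace-separated edge lists (``u v [w]``, ``#``
comments), the format shared by the MCL family of tools.  Clusterings are
one cluster per line, tab-separated labels.  The module also owns the two
transformations every run starts with: self-loop addition and construction
of the column-stochastic initial flow matrix ``M_G = A D^{-1}``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

from .sparse_core import CscMatrix, csc_from_entries

__all__ = [
    "WeightedGraph",
    "Clustering",
    "GraphFormatError",
    "read_edge_list",
    "write_edge_list",
    "add_self_loops",
    "initial_flow_matrix",
    "read_clusters",
    "write_clusters",
]


class GraphFormatError(ValueError):
    """Malformed edge-list or cluster file."""


@dataclass
class WeightedGraph:
    """Undirected weighted graph with node weights and optional self-loops.

    Nodes carry string labels, internally mapped to dense integer ids in
    insertion order; every iteration order in the package derives from these
    ids, which makes runs reproducible for a fixed input.  ``W`` maps an
    ordered id pair ``(min, max)`` (or ``(u, u)`` for a self-loop) to a
    positive weight; ``Z`` holds positive integer node weights, identically 1
    on a freshly loaded graph and equal to merged-node counts on coarsened
    graphs.
    """

    labels: list[str] = field(default_factory=list)
    W: dict[tuple[int, int], float] = field(default_factory=dict)
    Z: dict[int, int] = field(default_factory=dict)
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _adj: dict[int, dict[int, float]] = field(default_factory=dict, repr=False)

    # -- construction ------------------------------------------------------

    def add_node(self, label: str) -> int:
        if label in self._index:
            return self._index[label]
        u = len(self.labels)
        self.labels.append(label)
        self._index[label] = u
        self.Z[u] = 1
        self._adj[u] = {}
        return u

    def node_id(self, label: str) -> int:
        return self._index[label]

    def add_edge(self, u: int, v: int, w: float) -> None:
        """Add weight ``w`` to edge (u, v); repeated edges accumulate."""
        if w <= 0 or not np.isfinite(w):
            raise ValueError(f"edge weight must be positive and finite, got {w}")
        key = (u, v) if u <= v else (v, u)
        self.W[key] = self.W.get(key, 0.0) + w
        if u == v:
            return
        self._adj[u][v] = self.W[key]
        self._adj[v][u] = self.W[key]

    def set_self_loop(self, u: int, w: float) -> None:
        self.W[(u, u)] = float(w)

    # -- queries -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.W)

    def neighbors(self, u: int) -> dict[int, float]:
        """Adjacent node ids and edge weights, excluding ``u`` itself."""
        return self._adj[u]

    def self_loop(self, u: int) -> float:
        return self.W.get((u, u), 0.0)

    def has_self_loops(self) -> bool:
        return any(u == v for u, v in self.W)

    def weighted_degree(self, u: int) -> float:
        """Sum of incident edge weights, self-loop counted once."""
        return sum(self._adj[u].values()) + self.self_loop(u)

    def total_edge_weight(self) -> float:
        """Sum of W over all edges, self-loops counted once."""
        return sum(self.W.values())

    def total_node_weight(self) -> int:
        return sum(self.Z.values())

    def edges(self) -> Iterable[tuple[int, int, float]]:
        return ((u, v, w) for (u, v), w in self.W.items())

    def copy(self) -> "WeightedGraph":
        g = WeightedGraph()
        g.labels = list(self.labels)
        g._index = dict(self._index)
        g.W = dict(self.W)
        g.Z = dict(self.Z)
        g._adj = {u: dict(nb) for u, nb in self._adj.items()}
        return g


def read_edge_list(stream: IO[str] | str) -> WeightedGraph:
    """Parse a whitespace-separated edge list (``u v [w]``; ``#`` comments).

    Repeated (and reversed) edges have their weights summed; node ids are
    assigned by first appearance.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    g = WeightedGraph()
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise GraphFormatError(f"line {lineno}: expected 'u v [w]', got {line!r}")
        if len(tokens) > 3:
            raise GraphFormatError(f"line {lineno}: too many fields in {line!r}")
        w = 1.0
        if len(tokens) == 3:
            try:
                w = float(tokens[2])
            except ValueError:
                raise GraphFormatError(f"line {lineno}: bad weight {tokens[2]!r}") from None
        if w <= 0 or not np.isfinite(w):
            raise GraphFormatError(f"line {lineno}: weight must be positive, got {w}")
        u = g.add_node(tokens[0])
        v = g.add_node(tokens[1])
        g.add_edge(u, v, w)
    return g


def write_edge_list(g: WeightedGraph, stream: IO[str], include_self_loops: bool = False) -> None:
    """Canonical edge-list dump: labels sorted within and across lines."""
    lines = []
    for (u, v), w in g.W.items():
        if u == v and not include_self_loops:
            continue
        a, b = sorted((g.labels[u], g.labels[v]))
        lines.append((a, b, format(w, ".12g")))
    for a, b, wtxt in sorted(lines):
        stream.write(f"{a}\t{b}\t{wtxt}\n")


def add_self_loops(g: WeightedGraph) -> WeightedGraph:
    """Return a copy where every node has a self-loop.

    The loop weight is ``max(1, max incident edge weight)``: the weight
    transformation applied before building the initial flow matrix keeps a
    node's self-influence comparable to its strongest tie, so flow does not
    drain instantly out of weakly attached nodes.  Existing self-loops are
    overwritten.
    """
    out = g.copy()
    for u in range(out.n_nodes):
        nb = out.neighbors(u)
        w = max(nb.values()) if nb else 1.0
        out.set_self_loop(u, max(1.0, w))
    return out


def initial_flow_matrix(g: WeightedGraph) -> CscMatrix:
    """Column-stochastic ``M_G = A D^{-1}`` from the self-looped adjacency.

    Column ``j`` holds the transition probabilities out of node ``j``:
    ``M_ij = A_ij / sum_k A_kj``.  Requires a self-loop on every node so no
    column is zero.
    """
    n = g.n_nodes
    entries: list[tuple[int, int, float]] = []
    for j in range(n):
        loop = g.self_loop(j)
        nb = g.neighbors(j)
        deg = loop + sum(nb.values())
        if deg <= 0:
            raise ValueError(
                f"node {g.labels[j]!r} has zero weighted degree; add self-loops first"
            )
        if loop > 0:
            entries.append((j, j, loop / deg))
        entries.extend((i, j, w / deg) for i, w in nb.items())
    return csc_from_entries(entries, n, n)


@dataclass(frozen=True)
class Clustering:
    """A partition of node labels into disjoint, non-empty clusters."""

    clusters: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster")
            if seen & c:
                raise ValueError("overlapping clusters")
            seen |= c

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[str]]) -> "Clustering":
        return cls(tuple(frozenset(s) for s in sets))

    @classmethod
    def from_labels(cls, node_labels: Iterable[str], assignment: Iterable[int]) -> "Clustering":
        groups: dict[int, set[str]] = {}
        for lab, a in zip(node_labels, assignment):
            groups.setdefault(a, set()).add(lab)
        return cls.from_sets(groups.values())

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset().union(*self.clusters) if self.clusters else frozenset()

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def membership(self) -> dict[str, int]:
        return {lab: k for k, c in enumerate(self.clusters) for lab in c}

    def canonical(self) -> list[list[str]]:
        """Clusters by decreasing size then lexicographic first label."""
        ordered = [sorted(c) for c in self.clusters]
        ordered.sort(key=lambda c: (-len(c), c[0]))
        return ordered

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Clustering):
            return NotImplemented
        return set(self.clusters) == set(other.clusters)

    def __hash__(self) -> int:
        return hash(frozenset(self.clusters))


def write_clusters(clustering: Clustering, stream: IO[str]) -> None:
    """One cluster per line, tab-separated labels, big clusters first."""
    for cluster in clustering.canonical():
        stream.write("\t".join(cluster) + "\n")


def read_clusters(stream: IO[str] | str) -> Clustering:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    sets: list[set[str]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(stream, start=1):
        labels = line.split()
        if not labels:
            continue
        s = set(labels)
        if len(s) != len(labels) or seen & s:
            raise GraphFormatError(f"line {lineno}: overlapping cluster members")
        seen |= s
        sets.append(s)
    return Clustering.from_sets(sets)
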