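"""Deterministic synthetic graphs with known ground truth.

Every generator is a pure function of its arguments (seed included), so
tests and benchmarks are self-contained: stars probe hub-heavy coarsening,
rings of cliques provide planted communities with closed-form cuts,
planted partitions give statistically controlled community structure, and
``ppi_like`` combines a clique ring with peripheral stars as a small-scale
stand-in for the modular-core-plus-satellite topology of protein
interaction networks.  Real PPI degree distributions are not modelled
beyond that.
"""

from __future__ import annotations

import numpy as np

from .graph_io import Clustering, WeightedGraph

__all__ = [
    "star",
    "ring_of_cliques",
    "planted_partition",
    "bridged_triangles",
    "ppi_like",
]


def star(k: int) -> WeightedGraph:
    """Center ``c`` plus leaves ``l1..lk``, unit weights."""
    if k < 1:
        raise ValueError("star needs at least one leaf")
    g = WeightedGraph()
    c = g.add_node("c")
    for i in range(1, k + 1):
        leaf = g.add_node(f"l{i}")
        g.add_edge(c, leaf, 1.0)
    return g


def ring_of_cliques(
    n_cliques: int, clique_size: int, bridge_weight: float = 1.0
) -> tuple[WeightedGraph, Clustering]:
    """Unit-weight cliques joined in a ring by single bridges.

    Bridges run from the last node of clique i to the first node of clique
    i+1 (mod n).  Returns the graph and the planted clustering (one cluster
    per clique).
    """
    if n_cliques < 2 or clique_size < 2:
        raise ValueError("need at least 2 cliques of size >= 2")
    g = WeightedGraph()
    members: list[list[str]] = []
    for q in range(n_cliques):
        labels = [f"q{q}n{i}" for i in range(clique_size)]
        ids = [g.add_node(lab) for lab in labels]
        for a in range(clique_size):
            for b in range(a + 1, clique_size):
                g.add_edge(ids[a], ids[b], 1.0)
        members.append(labels)
    for q in range(n_cliques):
        u = g.node_id(members[q][-1])
        v = g.node_id(members[(q + 1) % n_cliques][0])
        g.add_edge(u, v, bridge_weight)
    return g, Clustering.from_sets(members)


def planted_partition(
    n_blocks: int,
    block_size: int,
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> tuple[WeightedGraph, Clustering]:
    """Standard planted-partition draw with unit weights.

    Within-block pairs are edges with probability ``p_in``, cross-block
    pairs with ``p_out`` (requires ``p_in > p_out``).  A node that drew no
    within-block edge is reattached to a random in-block partner so every
    block stays internally connected enough to be recoverable in principle.
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    block = np.repeat(np.arange(n_blocks), block_size)
    g = WeightedGraph()
    ids = [g.add_node(f"n{i}") for i in range(n)]
    in_block_deg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if block[i] == block[j] else p_out
            if rng.random() < p:
                g.add_edge(ids[i], ids[j], 1.0)
                if block[i] == block[j]:
                    in_block_deg[i] += 1
                    in_block_deg[j] += 1
    for i in range(n):
        if in_block_deg[i] == 0:
            mates = [j for j in range(n) if block[j] == block[i] and j != i]
            j = int(rng.choice(mates))
            g.add_edge(ids[i], ids[j], 1.0)
            in_block_deg[i] += 1
            in_block_deg[j] += 1
    truth = Clustering.from_sets(
        [{f"n{i}" for i in range(n) if block[i] == q} for q in range(n_blocks)]
    )
    return g, truth


def bridged_triangles() -> WeightedGraph:
    """Two unit triangles {a,b,c} and {d,e,f} joined by the bridge c-d."""
    g = WeightedGraph()
    ids = {lab: g.add_node(lab) for lab in "abcdef"}
    for tri in ("abc", "def"):
        for x, y in ((0, 1), (0, 2), (1, 2)):
            g.add_edge(ids[tri[x]], ids[tri[y]], 1.0)
    g.add_edge(ids["c"], ids["d"], 1.0)
    return g


def ppi_like(
    n_cliques: int = 24,
    clique_size: int = 8,
    star_leaves: int = 2,
) -> tuple[WeightedGraph, Clustering]:
    """Clique ring with a small star hanging off each clique.

    Each clique contributes one anchor node to which a hub with
    ``star_leaves`` pendant leaves is attached, emulating the dense modules
    plus sparse satellite periphery of protein interaction networks.  The
    planted clustering assigns each satellite star to its anchor clique.
    Defaults give 24 * (8 + 3) = 264 nodes; scale ``n_cliques`` for larger
    instances.
    """
    g, planted = ring_of_cliques(n_cliques, clique_size, 1.0)
    sets = [set(c) for c in planted.canonical()]
    for q in range(n_cliques):
        anchor_lab = f"q{q}n{clique_size // 2}"
        anchor = g.node_id(anchor_lab)
        hub = g.add_node(f"q{q}hub")
        g.add_edge(anchor, hub, 1.0)
        home = next(s for s in sets if anchor_lab in s)
        home.add(f"q{q}hub")
        for i in range(star_leaves):
            leaf = g.add_node(f"q{q}leaf{i}")
            g.add_edge(hub, leaf, 1.0)
            home.add(f"q{q}leaf{i}")
    return g, Clustering.from_sets(sets)
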