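"""Molecular-complex detection (MCODE) on protein-interaction graphs.

The method finds densely interconnected regions of a network in three
stages:

1. **Vertex weighting** — every node ``v`` with degree >= ``degree_cutoff``
   is scored by the highest k-core of the subgraph induced by its closed
   neighborhood: ``weight(v) = k_max * density(k_max-core)``.  Nodes below
   the degree cutoff weigh 0.
2. **Complex prediction** — starting from the highest-weight unassigned
   node as seed, neighbors are included breadth-first when their weight is
   within ``node_score_cutoff`` of the seed's (``w >= w_seed * (1 -
   node_score_cutoff)``), never revisiting a node already claimed by an
   earlier cluster, to a maximum BFS depth.
3. **Post-processing** — clusters lacking a ``k_core``-core are discarded;
   with ``haircut`` on, singly-connected nodes are shaved off; with
   ``fluff`` on, unassigned boundary nodes whose closed-neighborhood
   density exceeds ``fluff_density`` are pulled in.

A cluster's score is its density times its node count, ``2E/(N(N-1)) * N``,
with ``E`` the number of edges its nodes induce in the parent network; a
clique of N nodes therefore scores exactly N.  Defaults (degree cutoff 2,
node score cutoff 0.2, k-core 2, max depth 100, haircut on, fluff off)
match the conventional defaults of the Cytoscape app.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx

__all__ = ["MCODEParams", "Module", "vertex_weights", "find_clusters", "module_score", "filter_modules"]

#: modules at or above this score are conventionally reported as significant
MIN_SCORE_DEFAULT = 5.0


@dataclass
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.5

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0 or self.k_core < 0 or self.max_depth < 1:
            raise ValueError("invalid MCODE parameters")
        if not 0 <= self.node_score_cutoff <= 1:
            raise ValueError("node_score_cutoff must be in [0, 1]")


@dataclass
class Module:
    module_id: int
    nodes: set[str]
    n_nodes: int
    n_edges: int
    score: float
    seed_gene: str = ""
    members: list[str] = field(default_factory=list)


def _highest_k_core(graph: nx.Graph) -> tuple[int, set]:
    """(k_max, nodes of the k_max-core) by iterative peeling; (0, all) if edgeless."""
    best_k, best_nodes = 0, set(graph.nodes)
    k = 1
    while True:
        h = graph.copy()
        changed = True
        while changed and h.number_of_nodes():
            low = [v for v, d in h.degree() if d < k]
            changed = bool(low)
            h.remove_nodes_from(low)
        if h.number_of_nodes() == 0:
            return best_k, best_nodes
        best_k, best_nodes = k, set(h.nodes)
        k += 1


def _density(graph: nx.Graph, nodes: set) -> float:
    n = len(nodes)
    if n < 2:
        return 0.0
    e = graph.subgraph(nodes).number_of_edges()
    return 2.0 * e / (n * (n - 1))


def vertex_weights(graph: nx.Graph, degree_cutoff: int = 2) -> dict[str, float]:
    """Core-based node weights: k_max of N[v]'s densest core times its density."""
    weights: dict[str, float] = {}
    for v in graph.nodes:
        if graph.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = set(graph[v]) | {v}
        sub = graph.subgraph(closed)
        k_max, core_nodes = _highest_k_core(sub)
        weights[v] = k_max * _density(sub, core_nodes)
    return weights


def module_score(n_nodes: int, n_edges: int) -> float:
    """Density times node count: 2E/(N(N-1)) * N = 2E/(N-1)."""
    if n_nodes < 2:
        raise ValueError("module score is undefined for fewer than 2 nodes")
    if n_edges < 0 or n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError(f"n_edges={n_edges} impossible for {n_nodes} nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1)) * n_nodes


def find_clusters(graph: nx.Graph, params: MCODEParams | None = None) -> list[Module]:
    """Seeded expansion over the vertex-weighted graph; scored, sorted modules.

    Returned clusters are vertex-disjoint (a node joins at most one;
    ``fluff`` may re-use boundary nodes, as in the original method) and
    each contains a ``params.k_core``-core.  Sorted by score descending,
    ties broken by node count descending then seed gene.
    """
    params = params or MCODEParams()
    if graph.number_of_nodes() == 0:
        return []
    weights = vertex_weights(graph, params.degree_cutoff)

    assigned: set = set()
    raw: list[tuple[str, set]] = []
    for seed in sorted(graph.nodes, key=lambda v: (-weights[v], v)):
        if seed in assigned:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        cluster = {seed}
        frontier = deque([(seed, 0)])
        while frontier:
            v, depth = frontier.popleft()
            if depth >= params.max_depth:
                continue
            for w in sorted(graph[v]):
                if w in cluster or w in assigned:
                    continue
                if weights[w] >= threshold:
                    cluster.add(w)
                    frontier.append((w, depth + 1))
        assigned |= cluster
        raw.append((seed, cluster))

    modules: list[Module] = []
    for seed, cluster in raw:
        sub = graph.subgraph(cluster)
        k_max, core_nodes = _highest_k_core(sub)
        if k_max < params.k_core:
            continue
        nodes = set(cluster)
        if params.haircut:
            sub = graph.subgraph(nodes)
            nodes = {v for v in nodes if sub.degree(v) >= 2}
        if params.fluff:
            boundary = set()
            for v in nodes:
                for w in graph[v]:
                    if w in nodes or w in boundary:
                        continue
                    closed = set(graph[w]) | {w}
                    if _density(graph, closed) > params.fluff_density:
                        boundary.add(w)
            nodes |= boundary
        if len(nodes) < 2:
            continue
        n_edges = graph.subgraph(nodes).number_of_edges()
        modules.append(
            Module(
                module_id=0,
                nodes=nodes,
                n_nodes=len(nodes),
                n_edges=n_edges,
                score=module_score(len(nodes), n_edges),
                seed_gene=seed,
                members=sorted(nodes),
            )
        )

    modules.sort(key=lambda m: (-m.score, -m.n_nodes, m.seed_gene))
    for i, m in enumerate(modules, start=1):
        m.module_id = i
    return modules


def filter_modules(modules: list[Module], min_score: float = MIN_SCORE_DEFAULT) -> list[Module]:
    """Keep modules with score >= min_score, preserving rank order."""
    return [m for m in modules if m.score >= min_score]
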