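"""Node centralities and degree-indexed topology profiles.

Centralities computed per node:

degree ``k``
    adjacency count.
betweenness ``C_B``
    Brandes' single-source accumulation over shortest-path DAGs, endpoints
    excluded, normalized by the undirected pair count (n-1)(n-2)/2 so a
    star center scores exactly 1.
closeness ``Cc``
    (number of reachable nodes) / (sum of shortest-path distances to them);
    0 for a node with no reachable partner.  On a connected graph this is
    the usual (n-1)/Σd; on a disconnected one it is the reciprocal of the
    mean distance within the node's component, which avoids infinities.
bottleneck ``BN``
    for each root s, one deterministic breadth-first shortest-path tree is
    grown (parent = lexicographically smallest candidate); a non-root node
    whose subtree holds more than a quarter of the tree's nodes is a
    bottleneck for that root, and BN(v) counts the roots for which v is one.

Degree profiles: P(k) the degree distribution, C(k) the mean clustering
coefficient of degree-k nodes, C_N(k) their mean neighbor degree.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import pandas as pd

__all__ = [
    "brandes_betweenness",
    "closeness_scores",
    "bottleneck_scores",
    "compute_node_metrics",
    "compute_degree_profiles",
]


def brandes_betweenness(graph: nx.Graph) -> dict[str, float]:
    """Pair-normalized betweenness centrality, endpoints excluded."""
    nodes = list(graph.nodes)
    n = len(nodes)
    cb = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        # single-source shortest-path DAG (BFS: unweighted)
        stack: list = []
        pred: dict = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0.0)
        dist = dict.fromkeys(nodes, -1)
        sigma[s], dist[s] = 1.0, 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in graph[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # back-propagate pair dependencies
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                cb[w] += delta[w]
    norm = (n - 1) * (n - 2) if n > 2 else 1  # each undirected pair visited twice
    return {v: cb[v] / norm for v in nodes}


def closeness_scores(graph: nx.Graph) -> dict[str, float]:
    """Reachable-count over distance-sum closeness (0 when nothing is reachable)."""
    out: dict[str, float] = {}
    for v in graph.nodes:
        lengths = nx.single_source_shortest_path_length(graph, v)
        total = sum(lengths.values())
        reachable = len(lengths) - 1
        out[v] = reachable / total if total > 0 else 0.0
    return out


def _bfs_tree_children(graph: nx.Graph, root) -> tuple[dict, list]:
    """Deterministic BFS shortest-path tree: parent = smallest labeled candidate."""
    parent = {root: None}
    order = [root]
    frontier = [root]
    while frontier:
        nxt = {}
        for v in frontier:
            for w in sorted(graph[v]):
                if w not in parent and w not in nxt:
                    nxt[w] = v
                elif w in nxt and v < nxt[w]:
                    nxt[w] = v
        for w in sorted(nxt):
            parent[w] = nxt[w]
            order.append(w)
        frontier = sorted(nxt)
    children: dict = {v: [] for v in parent}
    for v, p in parent.items():
        if p is not None:
            children[p].append(v)
    return children, order


def bottleneck_scores(graph: nx.Graph) -> dict[str, int]:
    """BN(v): number of BFS shortest-path trees in which v's subtree exceeds |T|/4.

    One tree is grown per root over that root's component; the root itself
    is never a bottleneck candidate.  Subtree size counts v and every node
    whose tree path to the root passes through v.
    """
    bn = dict.fromkeys(graph.nodes, 0)
    for s in graph.nodes:
        children, order = _bfs_tree_children(graph, s)
        tree_n = len(order)
        subtree = dict.fromkeys(order, 1)
        for v in reversed(order):  # leaves first
            for c in children[v]:
                subtree[v] += subtree[c]
        for v in order:
            if v != s and subtree[v] > tree_n / 4:
                bn[v] += 1
    return bn


def compute_node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness and bottleneck table."""
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(columns=["gene", "degree", "betweenness", "closeness", "bottleneck"])
    betw = brandes_betweenness(graph)
    close = closeness_scores(graph)
    bn = bottleneck_scores(graph)
    rows = [
        {
            "gene": v,
            "degree": graph.degree(v),
            "betweenness": betw[v],
            "closeness": close[v],
            "bottleneck": bn[v],
        }
        for v in sorted(graph.nodes)
    ]
    return pd.DataFrame(rows)


def compute_degree_profiles(graph: nx.Graph) -> pd.DataFrame:
    """P(k), C(k) and C_N(k) indexed by degree k.

    The clustering coefficient of a node with fewer than two neighbors is 0.
    """
    n = graph.number_of_nodes()
    if n == 0:
        return pd.DataFrame(columns=["k", "p_k", "c_k", "cn_k"])

    clustering: dict = {}
    neighbor_deg: dict = {}
    for v in graph.nodes:
        nbrs = list(graph[v])
        k = len(nbrs)
        if k < 2:
            clustering[v] = 0.0
        else:
            links = sum(1 for i, a in enumerate(nbrs) for b in nbrs[i + 1 :] if graph.has_edge(a, b))
            clustering[v] = 2.0 * links / (k * (k - 1))
        neighbor_deg[v] = sum(graph.degree(w) for w in nbrs) / k if k else 0.0

    rows = []
    by_degree: dict[int, list] = {}
    for v in graph.nodes:
        by_degree.setdefault(graph.degree(v), []).append(v)
    for k in sorted(by_degree):
        members = by_degree[k]
        rows.append(
            {
                "k": k,
                "p_k": len(members) / n,
                "c_k": sum(clustering[v] for v in members) / len(members),
                "cn_k": sum(neighbor_deg[v] for v in members) / len(members),
            }
        )
    return pd.DataFrame(rows)
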