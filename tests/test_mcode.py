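"""Molecular-complex detection: weights, scores, cluster recovery."""

import networkx as nx
import pytest

from orthonet.mcode import (
    MCODEParams,
    filter_modules,
    find_clusters,
    module_score,
    vertex_weights,
)
from orthonet.network import EdgeRecord, build_network
from orthonet.synthetic import generate_network


def oracle_weights(g: nx.Graph, degree_cutoff: int = 2) -> dict:
    """Independent route: networkx core decomposition of each closed neighborhood."""
    out = {}
    for v in g.nodes:
        if g.degree(v) < degree_cutoff:
            out[v] = 0.0
            continue
        sub = g.subgraph(set(g[v]) | {v})
        core_numbers = nx.core_number(sub)
        k_max = max(core_numbers.values())
        core = sub.subgraph([u for u, c in core_numbers.items() if c >= k_max])
        out[v] = k_max * nx.density(core)
    return out


class TestVertexWeights:
    def test_below_degree_cutoff_weighs_zero(self):
        g = nx.Graph([("A", "B")])
        assert vertex_weights(g, 2) == {"A": 0.0, "B": 0.0}

    def test_k5_vertices_weigh_four(self):
        g = nx.complete_graph(5)
        assert all(w == pytest.approx(4.0) for w in vertex_weights(g).values())

    def test_star_center_weight_is_neighborhood_density(self):
        g = nx.star_graph(4)  # N[center] has 5 nodes, 4 edges
        w = vertex_weights(g)
        assert w[0] == pytest.approx(1 * nx.density(g))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_core_decomposition_oracle(self, seed):
        g = nx.gnp_random_graph(25, 0.2, seed=seed)
        mine = vertex_weights(g)
        ref = oracle_weights(g)
        for v in g.nodes:
            assert mine[v] == pytest.approx(ref[v], abs=1e-12)


class TestModuleScore:
    @pytest.mark.parametrize(
        "n_nodes,n_edges,expected",
        [(24, 276, 24.000), (49, 361, 15.042), (17, 114, 14.250), (8, 25, 7.143)],
    )
    def test_printed_module_triples(self, n_nodes, n_edges, expected):
        assert round(module_score(n_nodes, n_edges), 3) == expected

    @pytest.mark.parametrize("n", range(2, 30))
    def test_clique_scores_exactly_n(self, n):
        assert module_score(n, n * (n - 1) // 2) == pytest.approx(float(n))

    def test_undefined_below_two_nodes(self):
        with pytest.raises(ValueError):
            module_score(1, 0)

    def test_impossible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            module_score(4, 7)


class TestFindClusters:
    def test_two_disjoint_cliques_found_with_score_five(self):
        g = nx.Graph()
        for offset in (0, 10):
            g.update(nx.relabel_nodes(nx.complete_graph(5), lambda v, o=offset: v + o))
        g.add_edge(100, 101)  # chaff
        modules = find_clusters(g)
        assert len(modules) == 2
        assert all(m.score == pytest.approx(5.0) for m in modules)
        assert {frozenset(m.nodes) for m in modules} == {
            frozenset(range(5)), frozenset(range(10, 15))
        }

    def test_empty_graph(self):
        assert find_clusters(nx.Graph()) == []

    def test_clusters_disjoint_and_contain_k_core(self):
        g = nx.gnp_random_graph(60, 0.12, seed=2)
        modules = find_clusters(g)
        seen = set()
        for m in modules:
            assert not (m.nodes & seen)
            seen |= m.nodes
            core_max = max(nx.core_number(g.subgraph(m.nodes)).values())
            assert core_max >= 2

    def test_planted_clique_recovered_from_noise(self):
        table, truth = generate_network(
            224, "planted_modules",
            {"module_sizes": [24], "noise_edge_prob": 0.02}, seed=11,
        )
        records = [
            EdgeRecord(a, b, s) for a, b, s in
            zip(table.gene_a, table.gene_b, table.score)
        ]
        g, _ = build_network(records, normalize=None)
        top = find_clusters(g)[0]
        assert top.nodes == truth.planted_modules[0]
        assert top.score == pytest.approx(24.0)
        assert (top.n_nodes, top.n_edges) == (24, 276)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MCODEParams(node_score_cutoff=1.5)


class TestFilterModules:
    def make(self, scores):
        from orthonet.mcode import Module
        return [
            Module(module_id=i + 1, nodes=set(), n_nodes=0, n_edges=0, score=s)
            for i, s in enumerate(scores)
        ]

    def test_threshold_count(self):
        kept = filter_modules(self.make([24.0, 15.042, 14.25, 7.143, 4.9]), 5.0)
        assert len(kept) == 4
        assert [m.module_id for m in kept] == [1, 2, 3, 4]

    def test_zero_threshold_is_identity(self):
        mods = self.make([3.0, 1.0])
        assert filter_modules(mods, 0.0) == mods

    def test_all_below_threshold(self):
        assert filter_modules(self.make([1.0, 2.0]), 5.0) == []
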