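"""Generator contracts: determinism, planted-structure bookkeeping, formats."""


import numpy as np
import pandas as pd
import pytest

from orthonet.synthetic import (
    generate_annotations,
    generate_expression,
    generate_network,
    generate_ortholog_table,
)


class TestGenerateExpression:
    def test_nothing_planted_means_empty_truth(self):
        _, truth = generate_expression(100, 5, 5, n_de=0, seed=1)
        assert truth.de_genes == set()

    def test_seed_determinism(self):
        ds1, _ = generate_expression(50, 4, 4, 5, seed=7)
        ds2, _ = generate_expression(50, 4, 4, 5, seed=7)
        pd.testing.assert_frame_equal(ds1.matrix, ds2.matrix)

    def test_planted_log2fc_matches_generative_model(self):
        # Monte-Carlo: mean estimated log2FC over planted up-genes ~ effect size
        ds, truth = generate_expression(
            1000, 20, 20, 100, effect_size=1.0, sigma=0.5, seed=7
        )
        up = [g for g in truth.de_genes if truth.de_directions[g] == "up"]
        case = ds.samples_in("case")
        ctrl = ds.samples_in("control")
        lfc = ds.matrix.loc[up, case].mean(axis=1) - ds.matrix.loc[up, ctrl].mean(axis=1)
        tol = 3 * (0.5 * np.sqrt(2 / 20)) / np.sqrt(len(up))
        assert abs(lfc.mean() - 1.0) < tol

    def test_direction_consistent_across_datasets(self):
        # the same gene planted in two different DE sets shifts the same way
        _, t1 = generate_expression(100, 4, 4, 50, seed=1)
        _, t2 = generate_expression(100, 4, 4, 80, seed=2)
        shared = t1.de_genes & t2.de_genes
        assert shared
        assert all(t1.de_directions[g] == t2.de_directions[g] for g in shared)

    @pytest.mark.parametrize("kwargs", [
        {"n_genes": 0, "n_case": 2, "n_control": 2, "n_de": 0},
        {"n_genes": 10, "n_case": 0, "n_control": 2, "n_de": 0},
        {"n_genes": 10, "n_case": 2, "n_control": 2, "n_de": 11},
        {"n_genes": 10, "n_case": 2, "n_control": 2, "n_de": 1, "sigma": 0.0},
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            generate_expression(**kwargs, seed=0)


class TestGenerateNetwork:
    def test_single_clique_no_noise_has_choose2_edges(self):
        table, truth = generate_network(
            5, "planted_modules",
            {"module_sizes": [5], "noise_edge_prob": 0.0}, seed=0,
        )
        assert len(table) == 10
        assert len(truth.planted_modules[0]) == 5

    def test_planted_24_clique_induces_276_edges(self):
        table, truth = generate_network(
            224, "planted_modules",
            {"module_sizes": [24], "noise_edge_prob": 0.02}, seed=11,
        )
        members = truth.planted_modules[0]
        induced = table[table.gene_a.isin(members) & table.gene_b.isin(members)]
        assert len(induced) == 276

    def test_no_self_loops_or_duplicate_pairs(self):
        for model, params in [
            ("scale_free", {"m": 3}),
            ("planted_modules", {"module_sizes": [10], "noise_edge_prob": 0.05}),
        ]:
            table, _ = generate_network(100, model, params, seed=3)
            assert (table.gene_a != table.gene_b).all()
            pairs = {frozenset(p) for p in zip(table.gene_a, table.gene_b)}
            assert len(pairs) == len(table)
            assert table.score.between(0, 1).all()

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown network model"):
            generate_network(10, "smallworld", {}, seed=0)

    def test_seed_determinism(self):
        t1, _ = generate_network(60, "scale_free", {"m": 2}, seed=5)
        t2, _ = generate_network(60, "scale_free", {"m": 2}, seed=5)
        pd.testing.assert_frame_equal(t1, t2)


class TestGenerateOrthologTable:
    def test_zero_coverage_empty(self):
        table = generate_ortholog_table([f"G{i}" for i in range(10)], coverage=0.0, seed=0)
        assert table.empty

    def test_full_coverage_one_to_one(self):
        table = generate_ortholog_table(
            [f"G{i}" for i in range(10)], coverage=1.0, one_to_many_rate=0.0, seed=0
        )
        assert len(table) == 10
        assert table.target_gene.nunique() == 10

    def test_full_one_to_many_doubles_pairs(self):
        table = generate_ortholog_table(
            [f"G{i}" for i in range(10)], coverage=1.0, one_to_many_rate=1.0, seed=0
        )
        assert len(table) == 20

    def test_always_map_guarantee(self):
        genes = [f"G{i}" for i in range(100)]
        table = generate_ortholog_table(
            genes, coverage=0.3, one_to_many_rate=0.0, seed=4, always_map=genes[:20]
        )
        assert set(genes[:20]) <= set(table.source_gene)
        assert table.source_gene.nunique() == 30


class TestGenerateAnnotations:
    def test_no_planted_terms_empty_truth(self):
        rows, truth = generate_annotations([f"G{i}" for i in range(100)], 10, (5, 20), seed=0)
        assert truth.enriched_terms == set()
        assert len({r[0] for r in rows}) == 10  # unique term ids

    def test_planted_terms_overlap_target(self):
        universe = [f"G{i}" for i in range(200)]
        target = set(universe[:40])
        rows, truth = generate_annotations(
            universe, 20, (20, 30), planted_terms=5, target_set=target, seed=1
        )
        assert len(truth.enriched_terms) == 5
        for term_id, _, members in rows[:5]:
            frac = len(set(members) & target) / len(members)
            assert frac > 0.5  # far above the 20% a uniform draw gives

    def test_planted_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            generate_annotations([f"G{i}" for i in range(50)], 3, (5, 10),
                                 planted_terms=4, target_set={"G1"}, seed=0)

    def test_seed_determinism(self):
        a = generate_annotations([f"G{i}" for i in range(50)], 5, (5, 10), seed=9)
        b = generate_annotations([f"G{i}" for i in range(50)], 5, (5, 10), seed=9)
        assert a[0] == b[0]
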