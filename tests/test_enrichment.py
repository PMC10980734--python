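"""Hypergeometric enrichment against enumeration oracles; BH; cross-species."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from orthonet.enrichment import (
    GeneSetTerm,
    bh_adjust,
    compare_species,
    enrich,
    kegg_crosswalk,
    read_gmt,
)


def term(term_id, members, category="pathway"):
    return GeneSetTerm(term_id, term_id, category, frozenset(members))


def oracle_tail_p(M, K, n, k):
    """P(overlap >= k) by enumeration over all C(M, n) draws."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(M), n):
        total += 1
        hits += len(marked & set(draw)) >= k
    return hits / total


class TestReadGmt:
    def test_duplicate_members_collapse(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("T1\tdesc\tA\tB\tA\n")
        terms = read_gmt(p)
        assert terms[0].members == frozenset({"A", "B"})

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("")
        with pytest.raises(ValueError):
            read_gmt(p)

    def test_duplicate_term_id_is_error(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("T1\td\tA\tB\nT1\td\tC\tD\n")
        with pytest.raises(ValueError, match="T1"):
            read_gmt(p)

    def test_short_rows_skipped(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("T1\tdesc\nT2\tdesc\tA\tB\n")
        terms = read_gmt(p)
        assert [t.term_id for t in terms] == ["T2"]


class TestEnrich:
    def test_closed_form_full_overlap(self):
        background = {f"g{i}" for i in range(20)}
        members = {f"g{i}" for i in range(5)}
        res = enrich(members, [term("T", members)], background)
        assert res.loc[0, "p_value"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)
        assert res.loc[0, "fold_enrichment"] == pytest.approx(4.0)

    def test_zero_overlap_p_is_one(self):
        background = {f"g{i}" for i in range(20)}
        res = enrich({"g0", "g1"}, [term("T", {"g10", "g11"})], background)
        assert res.loc[0, "p_value"] == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            M = int(rng.integers(5, 16))
            K = int(rng.integers(1, M + 1))
            n = int(rng.integers(1, M + 1))
            background = {f"g{i}" for i in range(M)}
            members = {f"g{i}" for i in range(K)}
            query = set(rng.choice(sorted(background), size=n, replace=False))
            k = len(query & members)
            res = enrich(query, [term("T", members)], background)
            assert res.loc[0, "p_value"] == pytest.approx(
                oracle_tail_p(M, K, n, k), abs=1e-9
            )

    def test_ease_is_more_conservative(self):
        background = {f"g{i}" for i in range(30)}
        members = {f"g{i}" for i in range(8)}
        query = {f"g{i}" for i in range(2, 12)}
        p_std = enrich(query, [term("T", members)], background).loc[0, "p_value"]
        p_ease = enrich(query, [term("T", members)], background, ease=True).loc[0, "p_value"]
        assert p_ease >= p_std

    def test_p_nonincreasing_in_overlap(self):
        background = {f"g{i}" for i in range(50)}
        members = {f"g{i}" for i in range(10)}
        prev = 1.1
        for k in range(1, 6):
            query = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(20, 27)}
            p = enrich(query, [term("T", members)], background).loc[0, "p_value"]
            assert p <= prev
            prev = p

    def test_bh_within_category(self):
        background = {f"g{i}" for i in range(40)}
        query = {f"g{i}" for i in range(10)}
        terms = [
            term("B1", {f"g{i}" for i in range(10)}, "BP"),
            term("B2", {f"g{i}" for i in range(20, 30)}, "BP"),
            term("P1", {f"g{i}" for i in range(5, 15)}, "pathway"),
        ]
        res = enrich(query, terms, background).set_index("term_id")
        # each category adjusted independently: a category of one keeps adj=p
        assert res.loc["P1", "adj_p"] == pytest.approx(res.loc["P1", "p_value"])


class TestBhAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_step_up_hand_computation(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_adjusted_at_least_raw_and_monotone(self):
        raw = [0.001, 0.01, 0.04, 0.2, 0.9]
        adj = bh_adjust(raw)
        assert all(a >= r for a, r in zip(adj, raw))
        assert adj == sorted(adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestCompareSpecies:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["term_id", "name", "p_value", "adj_p"])

    def test_term_significant_in_both_included_with_both_ps(self):
        a = self.frame([("hsa04010", "MAPK", 0.001, 0.002)])
        b = self.frame([("cel04010", "MAPK", 0.01, 0.02)])
        out = compare_species(a, b)
        assert len(out) == 1
        assert out.loc[0, "p_a"] == 0.001
        assert out.loc[0, "p_b"] == 0.01

    def test_one_sided_significance_excluded(self):
        a = self.frame([("hsa04010", "MAPK", 0.001, 0.002)])
        b = self.frame([("cel04010", "MAPK", 0.5, 0.6)])
        assert compare_species(a, b).empty

    def test_constructed_nine_common_pathways(self):
        ids = [f"{4000 + i:05d}" for i in range(12)]
        a = self.frame([(f"hsa{s}", s, 0.01, 0.02) for s in ids])
        b = self.frame(
            [(f"cel{s}", s, 0.01 if i < 9 else 0.9, 0.02 if i < 9 else 0.95)
             for i, s in enumerate(ids)]
        )
        assert len(compare_species(a, b)) == 9

    def test_empty_crosswalk_is_error(self):
        a = self.frame([("GO:1", "x", 0.01, 0.02)])
        b = self.frame([("GO:2", "y", 0.01, 0.02)])
        with pytest.raises(ValueError):
            compare_species(a, b, crosswalk={})

    def test_kegg_crosswalk_strips_species_prefix(self):
        cw = kegg_crosswalk(["hsa04010", "hsa00071"], ["cel04010", "cel99999"])
        assert cw == {"hsa04010": "cel04010"}
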