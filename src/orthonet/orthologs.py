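"""Ortholog table handling and cross-species gene-set projection.

Ortholog tables are two-column TSVs (source gene, target gene) such as an
OrthoList-style human-to-worm compendium export.  Tables from several
sources are merged by unioning pairs and their evidence labels; a human
query set is projected to the union of its targets with one-to-many
mappings fully expanded (no best-hit collapsing) and a mapping report.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_ortholog_table",
    "merge_ortholog_tables",
    "project_genes",
]


def read_ortholog_table(path: str | Path, source_label: str = "table") -> pd.DataFrame:
    """Read a >=2-column TSV of (source_gene, target_gene) pairs.

    Pairs are tagged with ``source_label`` as their evidence; duplicate rows
    collapse to one.  A header row is tolerated when its first field is
    'source_gene'.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: ortholog table needs >= 2 columns")
    if str(df.iloc[0, 0]).lower() in ("source_gene", "source", "human_gene"):
        df = df.iloc[1:]
    df = df.iloc[:, :2]
    df.columns = ["source_gene", "target_gene"]
    df = df.dropna().drop_duplicates().reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path}: no ortholog pairs")
    df["evidence"] = [frozenset([source_label])] * len(df)
    return df


def merge_ortholog_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of pair lists; evidence sets are unioned for shared pairs.

    Idempotent: merging a merged table with itself changes nothing.
    """
    if not tables:
        raise ValueError("merge_ortholog_tables requires at least one table")
    combined = pd.concat(tables, ignore_index=True)
    merged = (
        combined.groupby(["source_gene", "target_gene"], sort=True)["evidence"]
        .apply(lambda ev: frozenset().union(*ev))
        .reset_index()
    )
    return merged


def project_genes(query: set[str], table: pd.DataFrame) -> tuple[set[str], dict]:
    """Project a source-species gene set through the ortholog table.

    Returns the union of target genes of every mapped query gene (one-to-many
    mappings fully expanded) and a report with the counts a mapping log needs.
    """
    sub = table[table["source_gene"].isin(query)]
    targets = set(sub["target_gene"])
    mapped = set(sub["source_gene"])
    report = {
        "n_query": len(query),
        "mapped": len(mapped),
        "unmapped": len(query) - len(mapped),
        "n_targets": len(targets),
    }
    return targets, report
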