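"""Gene-set over-representation analysis and cross-species term comparison.

The test is the upper-tail hypergeometric: drawing ``n`` query genes from a
background of ``M``, of which ``K`` belong to the term, the p-value is
P(overlap >= k).  The optional EASE variant decrements the observed
overlap by one before taking the tail, which penalizes single-gene
overlaps the way DAVID's EASE score does.  Fold enrichment is
``(k/n) / (K/M)``.  Benjamini–Hochberg adjustment is applied within each
term category (BP/CC/MF/pathway) separately.

Cross-species comparison intersects the significant term lists of two
analyses through an identifier crosswalk; for KEGG-style identifiers the
crosswalk is identity on the numeric suffix after stripping the 3–4 letter
species prefix (``hsa04010`` ↔ ``cel04010``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetTerm",
    "read_gmt",
    "enrich",
    "bh_adjust",
    "kegg_crosswalk",
    "compare_species",
]

ALPHA_DEFAULT = 0.05
_KEGG_PREFIX = re.compile(r"^[a-zA-Z]{3,4}(?=\d)")


@dataclass(frozen=True)
class GeneSetTerm:
    term_id: str
    name: str
    category: str  # BP / CC / MF / pathway
    members: frozenset[str]


def read_gmt(path: str | Path, category: str = "pathway") -> list[GeneSetTerm]:
    """Parse a GMT file (term, description, then members, tab-separated).

    Rows with fewer than three fields are skipped with a warning; duplicate
    member entries within a term collapse; a duplicated term id is an error.
    """
    terms: list[GeneSetTerm] = []
    seen: set[str] = set()
    skipped = 0
    with open(path) as fh:
        for line in fh:
            fields = [f for f in line.rstrip("\n").split("\t")]
            if len(fields) < 3 or not fields[0]:
                if line.strip():
                    skipped += 1
                continue
            term_id, desc, members = fields[0], fields[1], fields[2:]
            if term_id in seen:
                raise ValueError(f"{path}: duplicate term id {term_id!r}")
            seen.add(term_id)
            terms.append(
                GeneSetTerm(term_id, desc, category, frozenset(m for m in members if m))
            )
    if skipped:
        logger.warning("%s: skipped %d malformed GMT row(s)", path, skipped)
    if not terms:
        raise ValueError(f"{path}: no valid GMT rows")
    return terms


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    for p in p_values:
        if not 0 < p <= 1:
            raise ValueError(f"p-values must be in (0, 1]; got {p}")
    if not p_values:
        return []
    return multipletests(p_values, method="fdr_bh")[1].tolist()


def enrich(
    query: set[str],
    terms: list[GeneSetTerm],
    background: set[str] | None = None,
    ease: bool = False,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` against each term.

    ``background`` defaults to the union of all term members.  Query genes
    outside the background are dropped with a warning.  BH adjustment runs
    within each term category; rows come back sorted by p ascending.
    """
    if background is None:
        background = set().union(*(t.members for t in terms)) if terms else set()
    if len(background) < 2:
        raise ValueError("background must contain at least 2 genes")
    stray = query - background
    if stray:
        logger.warning(
            "%d query gene(s) outside the background dropped: %s",
            len(stray), sorted(stray)[:10],
        )
    query = query & background
    if not query:
        logger.warning("empty query after background restriction")
        return pd.DataFrame(
            columns=["term_id", "name", "category", "k_overlap", "n_query",
                     "K_term", "M_background", "fold_enrichment", "p_value", "adj_p"]
        )

    M, n = len(background), len(query)
    rows = []
    for t in terms:
        members = t.members & background
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        k_eff = max(k - 1, 0) if ease else k
        p = float(hypergeom.sf(k_eff - 1, M, K, n)) if k_eff > 0 else 1.0
        fold = (k / n) / (K / M)
        rows.append(
            {
                "term_id": t.term_id,
                "name": t.name,
                "category": t.category,
                "k_overlap": k,
                "n_query": n,
                "K_term": K,
                "M_background": M,
                "fold_enrichment": fold,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["adj_p"] = []
        return out
    out["adj_p"] = 1.0
    for cat, idx in out.groupby("category").groups.items():
        out.loc[idx, "adj_p"] = bh_adjust(out.loc[idx, "p_value"].tolist())
    return out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)


def kegg_crosswalk(ids_a: list[str], ids_b: list[str]) -> dict[str, str]:
    """Map KEGG-style ids of collection A to ids of B by shared numeric suffix."""
    def suffix(term_id: str) -> str:
        return _KEGG_PREFIX.sub("", term_id)

    by_suffix_b = {suffix(t): t for t in ids_b}
    return {t: by_suffix_b[suffix(t)] for t in ids_a if suffix(t) in by_suffix_b}


def compare_species(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    crosswalk: dict[str, str] | None = None,
    alpha: float = ALPHA_DEFAULT,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Terms significant in both species, with both p-values side by side.

    ``crosswalk`` maps term ids of A to ids of B; if omitted, the KEGG
    suffix rule is applied to the two id sets.  A degenerate (empty)
    crosswalk is an error.
    """
    if crosswalk is None:
        crosswalk = kegg_crosswalk(results_a["term_id"].tolist(), results_b["term_id"].tolist())
    if not crosswalk:
        raise ValueError("empty term-id crosswalk")
    p_col = "adj_p" if use_adjusted else "p_value"
    sig_a = results_a[results_a[p_col] <= alpha]
    sig_b = results_b[results_b[p_col] <= alpha].set_index("term_id")
    rows = []
    for rec in sig_a.itertuples(index=False):
        mapped = crosswalk.get(rec.term_id)
        if mapped is not None and mapped in sig_b.index:
            rows.append(
                {
                    "term_a": rec.term_id,
                    "term_b": mapped,
                    "name": rec.name,
                    "p_a": rec.p_value,
                    "p_b": sig_b.loc[mapped, "p_value"],
                    "adj_p_a": rec.adj_p,
                    "adj_p_b": sig_b.loc[mapped, "adj_p"],
                }
            )
    return pd.DataFrame(rows, columns=["term_a", "term_b", "name", "p_a", "p_b", "adj_p_a", "adj_p_b"])
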