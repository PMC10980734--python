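"""Construction of clean simple undirected PPI graphs from scored edge tables.

Edge tables are 3-column TSVs (protein_a, protein_b, confidence score in
[0, 1]) in the style of a STRING export.  Building a network applies, in
order: optional restriction to a gene whitelist, self-loop removal,
duplicate-pair collapsing (keeping the maximum score) and isolated-node
removal, and reports how many records each rule dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["EdgeRecord", "read_edge_table", "build_network", "write_edge_list"]

#: STRING-style "medium confidence" default
SCORE_MIN_DEFAULT = 0.4


@dataclass(frozen=True)
class EdgeRecord:
    gene_a: str
    gene_b: str
    score: float


def read_edge_table(path: str | Path, score_min: float = SCORE_MIN_DEFAULT) -> list[EdgeRecord]:
    """Parse a scored edge TSV, keeping rows with score >= ``score_min``.

    A single header row is tolerated (detected by an unparseable score
    field on line 1).  Other malformed rows are skipped and reported with
    their line numbers.  Self-pairs survive reading — removing them is the
    responsibility of :func:`build_network`.
    """
    records: list[EdgeRecord] = []
    bad: list[int] = []
    n_parsed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                bad.append(lineno)
                continue
            try:
                score = float(fields[2])
            except ValueError:
                if lineno == 1:
                    continue  # header
                bad.append(lineno)
                continue
            n_parsed += 1
            if score >= score_min:
                records.append(EdgeRecord(fields[0].strip(), fields[1].strip(), score))
    if bad:
        logger.warning("%s: skipped %d malformed row(s) at lines %s", path, len(bad), bad[:20])
    if n_parsed == 0:
        raise ValueError(f"{path}: no parseable edge rows")
    return records


def build_network(
    edges: list[EdgeRecord],
    node_whitelist: set[str] | None = None,
    normalize: str | None = None,
) -> tuple[nx.Graph, dict]:
    """Assemble a clean simple graph from edge records.

    ``normalize="upper"`` upper-cases gene symbols (the convention for human
    inputs); ``None`` leaves them verbatim (worm genes are conventionally
    lower-case, e.g. ``pmk-1``).  The whitelist, if given, is normalized the
    same way.  Cleanup drops, in order, edges outside the whitelist,
    self-loops and duplicate unordered pairs (keeping the maximum score);
    nodes left without any edge are excluded, so every node in the result
    has degree >= 1.  An empty result is a legitimate empty graph, not an
    error.

    Returns ``(graph, report)`` where the report counts records dropped per
    rule.
    """
    if normalize not in (None, "upper"):
        raise ValueError(f"normalize must be None or 'upper'; got {normalize!r}")

    def norm(g: str) -> str:
        return g.upper() if normalize == "upper" else g

    whitelist = {norm(g) for g in node_whitelist} if node_whitelist is not None else None

    report = {
        "input_edges": len(edges),
        "dropped_whitelist": 0,
        "dropped_self_loops": 0,
        "dropped_duplicates": 0,
    }
    best: dict[tuple[str, str], float] = {}
    for rec in edges:
        a, b = norm(rec.gene_a), norm(rec.gene_b)
        if whitelist is not None and (a not in whitelist or b not in whitelist):
            report["dropped_whitelist"] += 1
            continue
        if a == b:
            report["dropped_self_loops"] += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in best:
            report["dropped_duplicates"] += 1
            best[key] = max(best[key], rec.score)
        else:
            best[key] = rec.score

    graph = nx.Graph()
    for (a, b), score in best.items():
        graph.add_edge(a, b, score=score)
    report["n_nodes"] = graph.number_of_nodes()
    report["n_edges"] = graph.number_of_edges()
    if graph.number_of_nodes() == 0:
        logger.warning("build_network produced an empty network")
    return graph, report


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write the cleaned edge list as a 3-column TSV."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('score', 1.0):.3f}\n")
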