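"""Key-regulator identification from multi-metric top-N rankings.

A key regulator (KR) is a gene appearing in the top-N ranked list of every
centrality metric under consideration (three metrics for the human network
— degree, betweenness, closeness — and four for the worm network, adding
bottleneck).  The closed first neighborhood of the KR set (the KRs plus
every node directly interacting with one) defines the gene set carried
forward to ortholog projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RankedList", "KeyRegulatorSet", "top_n", "intersect_top", "closed_first_neighborhood"]

VALID_METRICS = ("degree", "betweenness", "closeness", "bottleneck")
TOP_N_DEFAULT = 20


@dataclass
class RankedList:
    metric: str
    n: int
    genes: list[str]


@dataclass
class KeyRegulatorSet:
    genes: set[str]
    metrics_used: list[str] = field(default_factory=list)
    n: int = TOP_N_DEFAULT


def top_n(metrics: pd.DataFrame, metric: str, n: int = TOP_N_DEFAULT) -> RankedList:
    """Top-``n`` genes by one metric, ties broken by gene symbol ascending."""
    if metric not in VALID_METRICS:
        raise ValueError(f"unknown metric {metric!r}; valid: {', '.join(VALID_METRICS)}")
    if n <= 0:
        raise ValueError("n must be positive")
    ordered = metrics.sort_values(
        [metric, "gene"], ascending=[False, True], kind="mergesort"
    )
    return RankedList(metric=metric, n=n, genes=ordered["gene"].head(n).tolist())


def intersect_top(lists: list[RankedList]) -> KeyRegulatorSet:
    """Genes common to every supplied ranked list (order-invariant)."""
    if len(lists) < 2:
        raise ValueError("intersect_top needs at least 2 ranked lists")
    common = set(lists[0].genes)
    for rl in lists[1:]:
        common &= set(rl.genes)
    return KeyRegulatorSet(
        genes=common,
        metrics_used=[rl.metric for rl in lists],
        n=max(rl.n for rl in lists),
    )


def closed_first_neighborhood(graph: nx.Graph, seeds: set[str]) -> set[str]:
    """Seeds plus every direct interactor of a seed (closed neighborhood).

    Seeds absent from the network are reported and ignored, not fatal.
    The result satisfies |result| = |seeds in network| + |non-seed neighbors|.
    """
    if not seeds:
        logger.warning("closed_first_neighborhood called with an empty seed set")
        return set()
    present = {s for s in seeds if s in graph}
    missing = seeds - present
    if missing:
        logger.warning("%d seed(s) not in network: %s", len(missing), sorted(missing)[:10])
    out = set(present)
    for s in present:
        out.update(graph[s])
    return out
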