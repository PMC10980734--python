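"""Synthetic input generators with known ground truth.

Every file format the pipeline consumes — two-group log2 expression
matrices, scored interaction edge tables, ortholog tables and GMT gene-set
collections — can be generated here with planted structure (differentially
expressed genes, dense network modules, over-represented terms) recorded in
a :class:`SyntheticTruth`, so each downstream stage is testable without any
external database download.

All generators are pure functions of their arguments including ``seed``:
the same call produces byte-identical output.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deg import ExpressionDataset

__all__ = [
    "SyntheticTruth",
    "generate_expression",
    "generate_network",
    "generate_ortholog_table",
    "generate_annotations",
    "simulate_bundle",
    "write_expression_tsv",
    "write_groups_tsv",
    "write_edges_tsv",
    "write_orthologs_tsv",
    "write_gmt",
]


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator.

    Attributes
    ----------
    de_genes:
        Identifiers of genes planted as differentially expressed.
    de_directions:
        Planted direction per DE gene (``"up"`` / ``"down"``, case vs control).
    planted_modules:
        Node sets embedded as dense clusters in a generated network.
    enriched_terms:
        Term identifiers planted as over-represented.
    seed:
        The seed the generator was called with.
    """

    de_genes: set[str] = field(default_factory=set)
    de_directions: dict[str, str] = field(default_factory=dict)
    planted_modules: list[set[str]] = field(default_factory=list)
    enriched_terms: set[str] = field(default_factory=set)
    seed: int = 0


def _planted_sign(gene: str) -> float:
    # direction tied to the gene name, not to its position in one dataset's
    # DE list, so a gene planted in several datasets always shifts the same way
    return 1.0 if zlib.crc32(gene.encode()) % 2 == 0 else -1.0


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    n_genes: int,
    n_case: int,
    n_control: int,
    n_de: int,
    effect_size: float = 1.0,
    sigma: float = 0.5,
    seed: int = 0,
    dataset_id: str = "synthetic",
    gene_names: list[str] | None = None,
    de_genes: list[str] | None = None,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate a two-group log2 expression matrix with planted DE genes.

    Per-gene baselines are drawn from N(8, 2) (log2 intensity scale) and
    sample values from N(baseline, sigma).  For the ``n_de`` planted genes
    the case-group mean is shifted by +/- ``effect_size``; the sign is a
    deterministic, approximately balanced function of the gene name, so the
    same gene planted in two datasets shifts in the same direction.

    Parameters
    ----------
    n_genes, n_case, n_control:
        Matrix dimensions; all must be positive.
    n_de:
        Number of planted differentially expressed genes (``<= n_genes``).
    effect_size:
        Planted case-minus-control mean shift in log2 units.
    sigma:
        Within-group standard deviation on the log2 scale.
    gene_names:
        Optional explicit gene identifiers (length ``n_genes``); default
        ``G0001``…
    de_genes:
        Optional explicit choice of which genes carry the planted effect;
        default: a uniform random subset of size ``n_de``.

    Returns
    -------
    (ExpressionDataset, SyntheticTruth)
    """
    if n_genes <= 0 or n_case <= 0 or n_control <= 0:
        raise ValueError("n_genes, n_case and n_control must all be positive")
    if n_de < 0 or n_de > n_genes:
        raise ValueError(f"n_de must be in [0, n_genes]; got {n_de}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive; got {sigma}")

    rng = np.random.default_rng(seed)
    if gene_names is None:
        width = max(4, len(str(n_genes)))
        gene_names = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    elif len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")

    if de_genes is None:
        de_idx = np.sort(rng.permutation(n_genes)[:n_de])
    else:
        if len(de_genes) != n_de:
            raise ValueError("de_genes length must equal n_de")
        pos = {g: i for i, g in enumerate(gene_names)}
        de_idx = np.array(sorted(pos[g] for g in de_genes), dtype=int)

    n_samples = n_case + n_control
    baseline = rng.normal(8.0, 2.0, size=n_genes)
    values = rng.normal(baseline[:, None], sigma, size=(n_genes, n_samples))

    directions: dict[str, str] = {}
    for gi in de_idx:
        name = gene_names[gi]
        sign = _planted_sign(name)
        values[gi, :n_case] += sign * effect_size
        directions[name] = "up" if sign > 0 else "down"

    samples = [f"case_{i + 1}" for i in range(n_case)] + [
        f"ctrl_{i + 1}" for i in range(n_control)
    ]
    matrix = pd.DataFrame(values, index=pd.Index(gene_names, name="gene"), columns=samples)
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples, name="group"
    )
    dataset = ExpressionDataset(dataset_id=dataset_id, matrix=matrix, groups=groups)
    truth = SyntheticTruth(de_genes=set(directions), de_directions=directions, seed=seed)
    return dataset, truth


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def generate_network(
    n_nodes: int,
    model: str = "scale_free",
    params: dict | None = None,
    seed: int = 0,
    node_names: list[str] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a scored undirected interaction edge table.

    Two models are supported:

    ``scale_free``
        Barabási–Albert preferential attachment; ``params["m"]`` (default 2)
        edges are attached per new node.  Emulates the hub-dominated degree
        structure of curated protein-interaction networks.
    ``planted_modules``
        Dense clusters (cliques, or fixed-density blocks via
        ``params["module_density"]``) embedded on disjoint node subsets,
        superimposed on Erdős–Rényi background noise with edge probability
        ``params["noise_edge_prob"]`` (default 0.02).  Cluster membership is
        either random disjoint subsets of sizes ``params["module_sizes"]``
        or the explicit name lists in ``params["module_members"]``.
        Collisions keep a single edge.

    Edge confidence scores are uniform: background edges on [0.15, 1.0),
    planted-module edges on [0.7, 1.0) — planted clusters stand in for
    well-characterised complexes, which carry strong interaction evidence.

    Returns a 3-column frame (``gene_a``, ``gene_b``, ``score``) with no
    self-pairs and no duplicate unordered pairs, plus the truth whose
    ``planted_modules`` records each embedded node set exactly.
    """
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    params = dict(params or {})
    rng = np.random.default_rng(seed)

    if node_names is None:
        width = max(4, len(str(n_nodes)))
        node_names = [f"N{i + 1:0{width}d}" for i in range(n_nodes)]
    elif len(node_names) != n_nodes:
        raise ValueError("node_names length must equal n_nodes")

    truth = SyntheticTruth(seed=seed)
    edges: dict[tuple[int, int], bool] = {}  # unordered pair -> is_planted

    def add(i: int, j: int, planted: bool) -> None:
        if i == j:
            return
        key = (i, j) if i < j else (j, i)
        edges[key] = edges.get(key, False) or planted

    if model == "scale_free":
        import networkx as nx

        m = int(params.get("m", 2))
        if m < 1:
            raise ValueError("attachment count m must be >= 1")
        g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
        for i, j in g.edges():
            add(i, j, False)
    elif model == "planted_modules":
        density = float(params.get("module_density", 1.0))
        p_noise = float(params.get("noise_edge_prob", 0.02))
        pos = {name: i for i, name in enumerate(node_names)}
        if "module_members" in params:
            member_lists = [sorted(pos[g] for g in mod) for mod in params["module_members"]]
        else:
            sizes = list(params.get("module_sizes", []))
            if sum(sizes) > n_nodes:
                raise ValueError("planted module sizes exceed n_nodes")
            perm = rng.permutation(n_nodes)
            member_lists, offset = [], 0
            for size in sizes:
                member_lists.append(sorted(int(x) for x in perm[offset : offset + size]))
                offset += size
        for members in member_lists:
            for i, j in itertools.combinations(members, 2):
                if density >= 1.0 or rng.random() < density:
                    add(i, j, True)
            truth.planted_modules.append({node_names[i] for i in members})
        if p_noise > 0:
            upper = np.triu_indices(n_nodes, k=1)
            mask = rng.random(len(upper[0])) < p_noise
            for i, j in zip(upper[0][mask], upper[1][mask]):
                add(int(i), int(j), False)
    else:
        raise ValueError(
            f"unknown network model {model!r}; expected 'scale_free' or 'planted_modules'"
        )

    pairs = sorted(edges)
    planted_mask = np.array([edges[p] for p in pairs], dtype=bool)
    noise_scores = rng.uniform(0.15, 1.0, size=len(pairs))
    planted_scores = rng.uniform(0.7, 1.0, size=len(pairs))
    scores = np.where(planted_mask, planted_scores, noise_scores)
    table = pd.DataFrame(
        {
            "gene_a": [node_names[i] for i, _ in pairs],
            "gene_b": [node_names[j] for _, j in pairs],
            "score": np.round(scores, 3),
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# orthologs
# ---------------------------------------------------------------------------

def generate_ortholog_table(
    source_genes: list[str],
    coverage: float = 0.8,
    one_to_many_rate: float = 0.3,
    seed: int = 0,
    target_prefix: str = "wrm",
    always_map: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate a two-column ortholog table with one-to-many mappings.

    Exactly ``round(coverage * len(source_genes))`` source genes receive at
    least one target; of those, ``round(one_to_many_rate * n_mapped)``
    receive two targets.  ``always_map`` names source genes guaranteed to be
    among the mapped set (they still count toward the coverage quota).
    Target names follow the worm convention (lower-case, hyphenated, e.g.
    ``wrm-17``) and are unique per (source, target) pair.
    """
    if not 0 <= coverage <= 1:
        raise ValueError("coverage must be in [0, 1]")
    if not 0 <= one_to_many_rate <= 1:
        raise ValueError("one_to_many_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)

    n = len(source_genes)
    pos = {g: i for i, g in enumerate(source_genes)}
    n_mapped = int(round(coverage * n))
    forced = sorted(pos[g] for g in (always_map or []))
    if len(forced) > n_mapped:
        raise ValueError("always_map larger than the coverage quota")
    remaining = [i for i in rng.permutation(n) if i not in set(forced)]
    mapped = sorted(forced + [int(i) for i in remaining[: n_mapped - len(forced)]])

    n_multi = int(round(one_to_many_rate * n_mapped))
    multi = set(int(x) for x in rng.permutation(n_mapped)[:n_multi])

    rows: list[tuple[str, str]] = []
    counter = 0
    for rank, gi in enumerate(mapped):
        n_targets = 2 if rank in multi else 1
        for _ in range(n_targets):
            counter += 1
            rows.append((source_genes[gi], f"{target_prefix}-{counter}"))
    return pd.DataFrame(rows, columns=["source_gene", "target_gene"])


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def generate_annotations(
    gene_universe: list[str],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 50),
    planted_terms: int = 0,
    target_set: set[str] | None = None,
    seed: int = 0,
    term_prefix: str = "T",
    planted_term_ids: list[str] | None = None,
    planted_overlap_frac: float = 0.8,
) -> tuple[list[tuple[str, str, list[str]]], SyntheticTruth]:
    """Simulate a GMT gene-set collection with planted enriched terms.

    Planted terms draw ``planted_overlap_frac`` of their members from
    ``target_set`` (far above what a uniform draw would give), the rest —
    and all non-planted terms — uniformly from the universe.  Returns GMT
    rows as ``(term_id, description, members)`` tuples plus the truth
    listing the planted term identifiers.
    """
    if n_terms <= 0:
        raise ValueError("n_terms must be positive")
    if planted_terms > n_terms:
        raise ValueError("planted_terms cannot exceed n_terms")
    lo, hi = term_size_range
    if hi > len(gene_universe):
        raise ValueError("term sizes cannot exceed the gene universe")
    if planted_terms > 0 and not target_set:
        raise ValueError("planted terms require a nonempty target_set")
    if planted_term_ids is not None and len(planted_term_ids) != planted_terms:
        raise ValueError("planted_term_ids length must equal planted_terms")

    rng = np.random.default_rng(seed)
    universe = np.array(sorted(gene_universe))
    target = np.array(sorted(target_set)) if target_set else np.array([])

    rows: list[tuple[str, str, list[str]]] = []
    truth = SyntheticTruth(seed=seed)
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        if t < planted_terms:
            term_id = (
                planted_term_ids[t] if planted_term_ids is not None
                else f"{term_prefix}{t + 1:04d}"
            )
            n_hit = min(int(round(planted_overlap_frac * size)), len(target))
            hits = rng.choice(target, size=n_hit, replace=False)
            rest_pool = np.setdiff1d(universe, hits)
            rest = rng.choice(rest_pool, size=size - n_hit, replace=False)
            members = sorted(set(hits) | set(rest))
            truth.enriched_terms.add(term_id)
            desc = "planted"
        else:
            term_id = f"{term_prefix}{t + 1:04d}"
            members = sorted(set(rng.choice(universe, size=size, replace=False)))
            desc = "background"
        rows.append((term_id, desc, members))
    return rows, truth


# ---------------------------------------------------------------------------
# writers (plain-text formats the pipeline reads back)
# ---------------------------------------------------------------------------

def write_expression_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    """Matrix TSV: first column gene id, header row = sample ids."""
    dataset.matrix.to_csv(path, sep="\t", float_format="%.4f")


def write_groups_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    """Two-column sample/group TSV."""
    dataset.groups.rename_axis("sample").to_frame().to_csv(path, sep="\t")


def write_edges_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_orthologs_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_gmt(rows: list[tuple[str, str, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, desc, members in rows:
            fh.write("\t".join([term_id, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# full bundle for the end-to-end pipeline
# ---------------------------------------------------------------------------

def simulate_bundle(outdir: str | Path, seed: int = 0) -> dict:
    """Write a complete, internally consistent synthetic input bundle.

    The bundle mirrors the shape of a two-species comparative study:

    * two case/control expression datasets over a shared 800-gene human-like
      universe; each plants 120 DE genes (effect 1.0 log2 units, sigma 0.5,
      15 vs 15 samples) drawn from a common 150-gene disease pool, always
      including the network-module members below;
    * a human interaction table over the universe with three dense clusters
      (30, 20 and 15 genes) planted inside the disease pool plus sparse
      background noise, so the DEG-restricted network has unambiguous hubs;
    * an ortholog table at 85% coverage with 30% one-to-many expansion that
      is guaranteed to map every human cluster member;
    * a worm interaction table over all worm target genes, with a 24-gene
      clique planted on orthologs of the largest human cluster (plus two
      smaller planted clusters), so MCODE applied after projection recovers
      a 24-node, 276-edge module;
    * human and worm GMT collections sharing 9 planted pathway identifiers
      with matching numeric suffixes (``hsa…``/``cel…``) enriched in the
      respective disease gene sets; background term suffixes differ between
      species, so only planted pathways can match in the cross-species
      comparison.

    Returns a manifest dict of file paths and the planted truths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_genes = 800
    universe = [f"HG{i + 1:04d}" for i in range(n_genes)]
    pool = sorted(rng.choice(universe, size=150, replace=False))
    modules = [pool[:30], pool[30:50], pool[50:65]]
    module_genes = [g for mod in modules for g in mod]

    datasets = {}
    truths: dict[str, SyntheticTruth] = {}
    other_pool = pool[65:]
    for ds_id in ("sim_ds1", "sim_ds2"):
        extra = sorted(rng.choice(other_pool, size=55, replace=False))
        de = sorted(module_genes + extra)
        ds, truth = generate_expression(
            n_genes=n_genes,
            n_case=15,
            n_control=15,
            n_de=len(de),
            effect_size=1.0,
            sigma=0.5,
            seed=int(rng.integers(2**31)),
            dataset_id=ds_id,
            gene_names=universe,
            de_genes=de,
        )
        write_expression_tsv(ds, outdir / f"{ds_id}_matrix.tsv")
        write_groups_tsv(ds, outdir / f"{ds_id}_groups.tsv")
        datasets[ds_id] = ds
        truths[ds_id] = truth

    human_edges, human_net_truth = generate_network(
        n_nodes=n_genes,
        model="planted_modules",
        params={"module_members": modules, "noise_edge_prob": 0.012},
        seed=int(rng.integers(2**31)),
        node_names=universe,
    )
    write_edges_tsv(human_edges, outdir / "human_edges.tsv")

    orth = generate_ortholog_table(
        universe,
        coverage=0.85,
        one_to_many_rate=0.3,
        seed=int(rng.integers(2**31)),
        target_prefix="cel",
        always_map=module_genes,
    )
    write_orthologs_tsv(orth, outdir / "orthologs.tsv")

    # worm clusters planted on orthologs of human cluster members
    first_target = orth.groupby("source_gene")["target_gene"].first()
    worm_modules = [
        [first_target[g] for g in modules[0][:24]],
        [first_target[g] for g in modules[1][:15]],
        [first_target[g] for g in modules[2][:10]],
    ]
    worm_universe = sorted(set(orth["target_gene"]))
    worm_edges, worm_net_truth = generate_network(
        n_nodes=len(worm_universe),
        model="planted_modules",
        params={"module_members": worm_modules, "noise_edge_prob": 0.008},
        seed=int(rng.integers(2**31)),
        node_names=worm_universe,
    )
    write_edges_tsv(worm_edges, outdir / "worm_edges.tsv")

    # KEGG-style ids: planted pathways share numeric suffixes across species;
    # background ids use species-distinct leading digits (8… vs 7…)
    suffixes = [f"{4010 + 10 * i:05d}" for i in range(9)]
    # conserved pathways concentrate on the conserved disease modules: worm
    # planted terms target the orthologs of the human cluster members
    worm_disease = sorted(
        set(orth.loc[orth["source_gene"].isin(module_genes), "target_gene"])
    )
    human_gmt, human_ann_truth = generate_annotations(
        universe, n_terms=40, term_size_range=(15, 60), planted_terms=9,
        target_set=set(pool), seed=int(rng.integers(2**31)),
        term_prefix="hsa8", planted_term_ids=[f"hsa{s}" for s in suffixes],
    )
    worm_gmt, worm_ann_truth = generate_annotations(
        worm_universe, n_terms=40, term_size_range=(15, 60), planted_terms=9,
        target_set=set(worm_disease), seed=int(rng.integers(2**31)),
        term_prefix="cel7", planted_term_ids=[f"cel{s}" for s in suffixes],
    )
    write_gmt(human_gmt, outdir / "human_sets.gmt")
    write_gmt(worm_gmt, outdir / "worm_sets.gmt")

    return {
        "outdir": str(outdir),
        "datasets": {
            ds_id: {
                "matrix": str(outdir / f"{ds_id}_matrix.tsv"),
                "groups": str(outdir / f"{ds_id}_groups.tsv"),
            }
            for ds_id in datasets
        },
        "human_edges": str(outdir / "human_edges.tsv"),
        "orthologs": str(outdir / "orthologs.tsv"),
        "worm_edges": str(outdir / "worm_edges.tsv"),
        "human_gmt": str(outdir / "human_sets.gmt"),
        "worm_gmt": str(outdir / "worm_sets.gmt"),
        "truths": {
            **truths,
            "human_network": human_net_truth,
            "worm_network": worm_net_truth,
            "human_annotations": human_ann_truth,
            "worm_annotations": worm_ann_truth,
        },
        "seed": seed,
    }
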