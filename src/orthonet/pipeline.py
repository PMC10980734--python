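"""End-to-end orchestration of the cross-species network analysis.

A single configuration (YAML-serializable) names every input file and every
stage parameter.  :func:`run_pipeline` executes the stages in method order —
DEG screening per dataset, merge, human network, human centralities, human
key regulators, closed neighborhood, ortholog projection, worm network,
worm centralities (including bottleneck), worm key regulators, MCODE
modules, module filtering, dual enrichment and cross-species comparison —
writing every intermediate table under the output directory and returning a
JSON-serializable manifest of per-stage counts and artifact paths.  The
manifest contains no timestamps, so a re-run with the same config and seed
reproduces it byte-for-byte; input-file checksums are recorded instead, so
runs against different database snapshots are distinguishable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import deg as deg_mod
from . import enrichment as enr_mod
from . import mcode as mcode_mod
from . import network as net_mod
from . import orthologs as orth_mod
from . import regulators as reg_mod
from . import topology as topo_mod

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "write_report", "default_config"]

HUMAN_METRICS_DEFAULT = ["degree", "betweenness", "closeness"]
WORM_METRICS_DEFAULT = ["degree", "betweenness", "closeness", "bottleneck"]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """All inputs and knobs of one pipeline run.

    Defaults mirror the study conditions: p <= 0.05 with a 0.25–1.5 band on
    |log2FC|; top-20 rankings; 3 human metrics and 4 worm metrics; MCODE at
    degree cutoff 2 / node score cutoff 0.2 / k-core 2 / max depth 100;
    module score >= 5; enrichment alpha 0.05 on raw p.
    """

    datasets: list[dict] = field(default_factory=list)  # {id, matrix, groups, log2}
    human_edges: str = ""
    worm_edges: str = ""
    orthologs: list[dict] = field(default_factory=list)  # {path, label}
    human_gmt: str = ""
    worm_gmt: str = ""
    outdir: str = "orthonet_out"
    seed: int = 0

    p_max: float = 0.05
    lfc_min: float = 0.25
    lfc_max: float = 1.5
    use_adjusted_p: bool = False

    score_min: float = net_mod.SCORE_MIN_DEFAULT
    top_n: int = 20
    human_metrics: list[str] = field(default_factory=lambda: list(HUMAN_METRICS_DEFAULT))
    worm_metrics: list[str] = field(default_factory=lambda: list(WORM_METRICS_DEFAULT))

    mcode: dict = field(default_factory=dict)
    min_module_score: float = mcode_mod.MIN_SCORE_DEFAULT

    alpha: float = enr_mod.ALPHA_DEFAULT
    ease: bool = False
    use_adjusted_enrichment: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def default_config() -> PipelineConfig:
    """A template config carrying the default thresholds (paths left blank)."""
    return PipelineConfig()


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return str(path)


def _modules_frame(modules: list[mcode_mod.Module]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module_id": m.module_id,
                "n_nodes": m.n_nodes,
                "n_edges": m.n_edges,
                "score": round(m.score, 3),
                "seed_gene": m.seed_gene,
                "members": ",".join(m.members),
            }
            for m in modules
        ],
        columns=["module_id", "n_nodes", "n_edges", "score", "seed_gene", "members"],
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "input_checksums": {},
        "stages": {},
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    # --- DEG screening per dataset -------------------------------------
    name = stage("deg_screen")
    screened: dict[str, pd.DataFrame] = {}
    try:
        if not config.datasets:
            raise ValueError("no expression datasets configured")
        per_dataset = {}
        for spec in config.datasets:
            ds = deg_mod.read_expression_dataset(
                spec["matrix"], spec["groups"], dataset_id=spec.get("id"),
                log2=spec.get("log2", True),
            )
            manifest["input_checksums"][spec["matrix"]] = _sha256(spec["matrix"])
            stats = deg_mod.compute_gene_stats(ds)
            kept = deg_mod.screen_degs(
                stats, p_max=config.p_max, lfc_min=config.lfc_min,
                lfc_max=config.lfc_max, use_adjusted=config.use_adjusted_p,
            )
            screened[ds.dataset_id] = kept
            _write_tsv(kept, outdir / f"degs_{ds.dataset_id}.tsv")
            per_dataset[ds.dataset_id] = {
                "n_genes": len(stats),
                "n_retained": len(kept),
                "n_up": int((kept["direction"] == "up").sum()),
                "n_down": int((kept["direction"] == "down").sum()),
            }
        manifest["stages"][name] = {"datasets": per_dataset}
    except Exception as exc:  # noqa: BLE001 - stage contract names the stage
        raise PipelineStageError(name, str(exc)) from exc

    # --- merge ----------------------------------------------------------
    name = stage("merge_degs")
    try:
        merged = deg_mod.merge_deg_tables(screened)
        merged_path = _write_tsv(merged, outdir / "degs_merged.tsv")
        n_conflict = int(merged["direction_conflict"].sum())
        manifest["stages"][name] = {
            "n_merged": len(merged),
            "n_up": int((merged["direction"] == "up").sum()),
            "n_down": int((merged["direction"] == "down").sum()),
            "n_direction_conflicts": n_conflict,
            "table": merged_path,
        }
        deg_genes = set(merged["gene"])
    except Exception as exc:
        raise PipelineStageError(name, str(exc)) from exc

    # --- human network ---------------------------------------------------
    name = stage("human_network")
    try:
        if not config.human_edges:
            raise ValueError("no human edge table configured")
        manifest["input_checksums"][config.human_edges] = _sha256(config.human_edges)
        records = net_mod.read_edge_table(config.human_edges, score_min=config.score_min)
        human_g, report = net_mod.build_network(records, node_whitelist=deg_genes, normalize="upper")
        net_mod.write_edge_list(human_g, outdir / "human_network_edges.tsv")
        manifest["stages"][name] = {**report, "edge_list": str(outdir / "human_network_edges.tsv")}
    except Exception as exc:
        raise PipelineStageError(name, str(exc)) from exc

    # --- human topology & key regulators --------------------------------
    name = stage("human_topology")
    try:
        human_metrics = topo_mod.compute_node_metrics(human_g)
        _write_tsv(human_metrics, outdir / "human_node_metrics.tsv")
        _write_tsv(topo_mod.compute_degree_profiles(human_g), outdir / "human_degree_profiles.tsv")
        manifest["stages"][name] = {
            "n_nodes": len(human_metrics),
            "metrics_table": str(outdir / "human_node_metrics.tsv"),
            "profiles_table": str(outdir / "human_degree_profiles.tsv"),
        }
    except Exception as exc:
        raise PipelineStageError(name, str(exc)) from exc

    name = stage("human_key_regulators")
    try:
        ranked = [reg_mod.top_n(human_metrics, m, config.top_n) for m in config.human_metrics]
        for rl in ranked:
            _write_tsv(
                pd.DataFrame({"rank": range(1, len(rl.genes) + 1), "gene": rl.genes}),
                outdir / f"human_top{config.top_n}_{rl.metric}.tsv",
            )
        human_krs = reg_mod.intersect_top(ranked)
        (outdir / "human_key_regulators.txt").write_text(
            "\n".join(sorted(human_krs.genes)) + "\n"
        )
        manifest["stages"][name] = {
            "metrics_used": human_krs.metrics_used,
            "top_n": config.top_n,
            "n_key_regulators": len(human_krs.genes),
            "key_regulators": sorted(human_krs.genes),
        }
    except Exception as exc:
        raise PipelineStageError(name, str(exc)) from exc

    name = stage("closed_neighborhood")
    try:
        neighborhood = reg_mod.closed_first_neighborhood(human_g, human_krs.genes)
        seeds_in_net = {s for s in human_krs.genes if s in human_g}
        (outdir / "kr_neighborhood.txt").write_text("\n".join(sorted(neighborhood)) + "\n")
        manifest["stages"][name] = {
            "n_seeds": len(human_krs.genes),
            "n_seeds_in_network": len(seeds_in_net),
            "n_non_seed_neighbors": len(neighborhood - seeds_in_net),
            "n_neighborhood": len(neighborhood),
        }
    except Exception as exc:
        raise PipelineStageError(name, str(exc)) from exc

    # --- ortholog projection ---------------------------------------------
    name = stage("ortholog_projection")
    try:
        if not config.orthologs:
            raise ValueError("no ortholog table configured")
        tables = []
        for spec in config.orthologs:
            path = spec["path"] if isinstance(spec, dict) else spec
            label = spec.get("label", Path(path).stem) if isinstance(spec, dict) else Path(path).stem
            manifest["input_checksums"][path] = _sha256(path)
            tables.append(orth_mod.read_ortholog_table(path, source_label=label))
        orth_table = orth_mod.merge_ortholog_tables(tables)
        worm_genes, report = orth_mod.project_genes(neighborhood, orth_table)
        (outdir / "worm_orthologs.txt").write_text("\n".join(sorted(worm_genes)) + "\n")
        manifest["stages"][name] = {**report, "gene_list": str(outdir / "worm_orthologs.txt")}
    except Exception as exc:
        raise PipelineStageError(name, str(exc)) from exc

    # --- worm network, topology, key regulators --------------------------
    name = stage("worm_network")
    try:
        if not config.worm_edges:
            raise ValueError("no worm edge table configured")
        manifest["input_checksums"][config.worm_edges] = _sha256(config.worm_edges)
        records = net_mod.read_edge_table(config.worm_edges, score_min=config.score_min)
        worm_g, report = net_mod.build_network(records, node_whitelist=worm_genes, normalize=None)
        net_mod.write_edge_list(worm_g, outdir / "worm_network_edges.tsv")
        manifest["stages"][name] = {**report, "edge_list": str(outdir / "worm_network_edges.tsv")}
    except Exception as exc:
        raise PipelineStageError(name, str(exc)) from exc

    name = stage("worm_topology")
    try:
        worm_metrics = topo_mod.compute_node_metrics(worm_g)
        _write_tsv(worm_metrics, outdir / "worm_node_metrics.tsv")
        _write_tsv(topo_mod.compute_degree_profiles(worm_g), outdir / "worm_degree_profiles.tsv")
        manifest["stages"][name] = {
            "n_nodes": len(worm_metrics),
            "metrics_table": str(outdir / "worm_node_metrics.tsv"),
            "profiles_table": str(outdir / "worm_degree_profiles.tsv"),
        }
    except Exception as exc:
        raise PipelineStageError(name, str(exc)) from exc

    name = stage("worm_key_regulators")
    try:
        ranked = [reg_mod.top_n(worm_metrics, m, config.top_n) for m in config.worm_metrics]
        for rl in ranked:
            _write_tsv(
                pd.DataFrame({"rank": range(1, len(rl.genes) + 1), "gene": rl.genes}),
                outdir / f"worm_top{config.top_n}_{rl.metric}.tsv",
            )
        worm_krs = reg_mod.intersect_top(ranked)
        (outdir / "worm_key_regulators.txt").write_text("\n".join(sorted(worm_krs.genes)) + "\n")
        manifest["stages"][name] = {
            "metrics_used": worm_krs.metrics_used,
            "top_n": config.top_n,
            "n_key_regulators": len(worm_krs.genes),
            "key_regulators": sorted(worm_krs.genes),
        }
    except Exception as exc:
        raise PipelineStageError(name, str(exc)) from exc

    # --- MCODE modules ----------------------------------------------------
    name = stage("mcode_modules")
    try:
        params = mcode_mod.MCODEParams(**config.mcode)
        modules = mcode_mod.find_clusters(worm_g, params)
        kept = mcode_mod.filter_modules(modules, config.min_module_score)
        _write_tsv(_modules_frame(modules), outdir / "modules_all.tsv")
        _write_tsv(_modules_frame(kept), outdir / "modules_significant.tsv")
        kr_membership = {
            kr: [m.module_id for m in kept if kr in m.nodes]
            for kr in sorted(worm_krs.genes)
        }
        manifest["stages"][name] = {
            "params": dataclasses.asdict(params),
            "n_modules": len(modules),
            "n_significant": len(kept),
            "min_score": config.min_module_score,
            "top_modules": [
                {"module_id": m.module_id, "n_nodes": m.n_nodes,
                 "n_edges": m.n_edges, "score": round(m.score, 3)}
                for m in kept[:4]
            ],
            "kr_module_membership": kr_membership,
        }
    except Exception as exc:
        raise PipelineStageError(name, str(exc)) from exc

    # --- enrichment & cross-species comparison ---------------------------
    name = stage("enrichment")
    try:
        if not config.human_gmt or not config.worm_gmt:
            raise ValueError("human and worm GMT collections must both be configured")
        manifest["input_checksums"][config.human_gmt] = _sha256(config.human_gmt)
        manifest["input_checksums"][config.worm_gmt] = _sha256(config.worm_gmt)
        human_terms = enr_mod.read_gmt(config.human_gmt)
        worm_terms = enr_mod.read_gmt(config.worm_gmt)
        human_enr = enr_mod.enrich(deg_genes, human_terms, ease=config.ease)
        worm_enr = enr_mod.enrich(worm_genes, worm_terms, ease=config.ease)
        _write_tsv(human_enr, outdir / "enrichment_human.tsv")
        _write_tsv(worm_enr, outdir / "enrichment_worm.tsv")
        p_col = "adj_p" if config.use_adjusted_enrichment else "p_value"
        manifest["stages"][name] = {
            "n_human_terms": len(human_enr),
            "n_worm_terms": len(worm_enr),
            "n_human_significant": int((human_enr[p_col] <= config.alpha).sum()),
            "n_worm_significant": int((worm_enr[p_col] <= config.alpha).sum()),
        }
    except Exception as exc:
        raise PipelineStageError(name, str(exc)) from exc

    name = stage("compare_species")
    try:
        common = enr_mod.compare_species(
            human_enr, worm_enr, alpha=config.alpha,
            use_adjusted=config.use_adjusted_enrichment,
        )
        common_path = _write_tsv(common, outdir / "common_terms.tsv")
        manifest["stages"][name] = {
            "n_common_terms": len(common),
            "common_terms": common["term_a"].tolist(),
            "table": common_path,
        }
    except Exception as exc:
        raise PipelineStageError(name, str(exc)) from exc

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("manifest written to %s", manifest_path)
    return manifest


REPORT_STAGES = [
    "human_topology", "human_key_regulators", "worm_topology",
    "worm_key_regulators", "mcode_modules", "compare_species",
]


def write_report(manifest: dict, outdir: str | Path | None = None) -> dict[str, str]:
    """Render human-readable report tables from a completed manifest.

    Emits top-10 metric tables per species, the key-regulator module
    membership table, the significant-module summary (3-decimal scores) and
    the common-pathway table with both species' p-values.
    """
    missing = [s for s in REPORT_STAGES if s not in manifest.get("stages", {})]
    if missing:
        raise ValueError(f"manifest incomplete; missing stages: {missing}")
    stages = manifest["stages"]
    outdir = Path(outdir or manifest["parameters"]["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    for species in ("human", "worm"):
        metrics = pd.read_csv(stages[f"{species}_topology"]["metrics_table"], sep="\t")
        metric_names = manifest["parameters"][f"{species}_metrics"]
        blocks = []
        for metric in metric_names:
            top = metrics.sort_values([metric, "gene"], ascending=[False, True]).head(10)
            block = top[["gene", metric]].reset_index(drop=True)
            block.columns = [f"{metric}_gene", metric]
            blocks.append(block)
        table = pd.concat(blocks, axis=1)
        table.insert(0, "rank", range(1, len(table) + 1))
        path = outdir / f"report_top10_{species}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written[f"top10_{species}"] = str(path)

    membership = stages["mcode_modules"]["kr_module_membership"]
    rows = [
        {"gene": kr, "modules": ",".join(str(m) for m in mods) if mods else "-",
         "in_module": bool(mods)}
        for kr, mods in membership.items()
    ]
    path = outdir / "report_kr_modules.tsv"
    pd.DataFrame(rows, columns=["gene", "modules", "in_module"]).to_csv(path, sep="\t", index=False)
    written["kr_modules"] = str(path)

    modules = pd.read_csv(Path(manifest["parameters"]["outdir"]) / "modules_significant.tsv", sep="\t")
    path = outdir / "report_modules.tsv"
    modules.assign(score=modules["score"].map(lambda s: f"{s:.3f}")).to_csv(
        path, sep="\t", index=False
    )
    written["modules"] = str(path)

    common_path = stages["compare_species"]["table"]
    common = pd.read_csv(common_path, sep="\t")
    path = outdir / "report_common_terms.tsv"
    if common.empty:
        path.write_text("term_a\tterm_b\tname\tp_a\tp_b\n# 0 common terms\n")
    else:
        common.to_csv(path, sep="\t", index=False, float_format="%.3g")
    written["common_terms"] = str(path)
    return written
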