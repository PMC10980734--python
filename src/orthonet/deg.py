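"""Differential-expression screening and multi-dataset merging.

A dataset is a log2-scale gene x sample matrix with a case/control label
per sample.  Screening follows a two-stage filter: a per-gene two-sample
test (Welch by default) with p <= 0.05, and a two-sided band on the
absolute log2 fold change, 0.25 <= |log2FC| <= 1.5 by default.  Gene lists
retained from several datasets are merged into one de-duplicated list with
per-gene provenance; genes whose direction disagrees across datasets are
flagged rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionDataset",
    "read_expression_dataset",
    "compute_gene_stats",
    "screen_degs",
    "merge_deg_tables",
]

#: default screening thresholds
P_MAX_DEFAULT = 0.05
LFC_MIN_DEFAULT = 0.25
LFC_MAX_DEFAULT = 1.5


@dataclass
class ExpressionDataset:
    """A two-group log2 expression matrix.

    ``matrix`` is genes x samples (log2 intensities); ``groups`` labels each
    sample column ``"case"`` or ``"control"``.
    """

    dataset_id: str
    matrix: pd.DataFrame
    groups: pd.Series
    log2: bool = True

    def __post_init__(self) -> None:
        missing = [s for s in self.matrix.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"group labels must be 'case'/'control'; got {sorted(bad)}")
        if self.matrix.index.has_duplicates:
            dupes = self.matrix.index[self.matrix.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes}")
        if not self.log2:
            # linear-scale input: move onto log2 with a +1 offset guard
            self.matrix = np.log2(self.matrix + 1.0)
            self.log2 = True

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.matrix.columns if self.groups[s] == group]


def read_expression_dataset(
    matrix_path: str | Path,
    groups_path: str | Path,
    dataset_id: str | None = None,
    log2: bool = True,
) -> ExpressionDataset:
    """Load a matrix TSV (first column gene id) and a sample/group TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    grp = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    grp.index = grp.index.astype(str)
    if dataset_id is None:
        dataset_id = Path(matrix_path).stem
    return ExpressionDataset(dataset_id=dataset_id, matrix=matrix, groups=grp, log2=log2)


def compute_gene_stats(dataset: ExpressionDataset, pooled: bool = False) -> pd.DataFrame:
    """Per-gene log2FC, two-sample t-test p, and BH-adjusted p.

    log2FC is mean(case) - mean(control).  The test is Welch's
    unequal-variance t-test (``pooled=True`` switches to the pooled-variance
    Student test).  No filtering happens here; ``direction`` is ``"none"``
    for every gene until :func:`screen_degs` assigns it.

    Degenerate genes: a gene constant across *all* samples gets p = 1 by
    convention; a gene constant within both groups but at different levels
    has zero sampling variance, and its p is set to the smallest positive
    float.
    """
    case = dataset.samples_in("case")
    ctrl = dataset.samples_in("control")
    for name, cols in (("case", case), ("control", ctrl)):
        if len(cols) < 2:
            raise ValueError(
                f"dataset {dataset.dataset_id!r}: group {name!r} has "
                f"{len(cols)} sample(s); need at least 2"
            )

    a = dataset.matrix[case].to_numpy(dtype=float)
    b = dataset.matrix[ctrl].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=pooled)

    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p = np.asarray(p, dtype=float)
    p[zero_var & (log2fc == 0)] = 1.0
    p[zero_var & (log2fc != 0)] = np.finfo(float).tiny
    p[np.isnan(p)] = 1.0

    adj_p = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": dataset.matrix.index,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": adj_p,
            "direction": "none",
        }
    ).reset_index(drop=True)


def screen_degs(
    stats_table: pd.DataFrame,
    p_max: float = P_MAX_DEFAULT,
    lfc_min: float = LFC_MIN_DEFAULT,
    lfc_max: float = LFC_MAX_DEFAULT,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Retain genes with p <= p_max and lfc_min <= |log2FC| <= lfc_max.

    ``use_adjusted`` gates on the BH-adjusted p instead of the raw p.
    ``lfc_max=math.inf`` recovers the conventional one-sided threshold.
    Direction is assigned by the sign of log2FC on the retained rows.
    """
    if not 0 < p_max <= 1:
        raise ValueError(f"p_max must be in (0, 1]; got {p_max}")
    if lfc_min < 0 or lfc_min > lfc_max:
        raise ValueError(f"need 0 <= lfc_min <= lfc_max; got {lfc_min}, {lfc_max}")

    p_col = "adj_p" if use_adjusted else "p_value"
    abs_fc = stats_table["log2fc"].abs()
    keep = (stats_table[p_col] <= p_max) & (abs_fc >= lfc_min) & (abs_fc <= lfc_max)
    out = stats_table.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


def merge_deg_tables(tables: dict[str, pd.DataFrame] | list[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-dataset retained gene tables into one de-duplicated list.

    Gene symbols are upper-cased for cross-dataset comparability.  Each gene
    appears once; ``datasets`` lists the contributing dataset ids
    (comma-joined); a gene retained with opposite directions in different
    datasets keeps direction ``"conflict"`` and ``direction_conflict=True``.
    Merging is idempotent: merging a merged table with itself is a no-op.
    """
    if isinstance(tables, dict):
        items = list(tables.items())
    else:
        items = [(str(t.attrs.get("dataset_id", i)), t) for i, t in enumerate(tables)]
    if not items:
        raise ValueError("merge_deg_tables requires at least one table")

    records: dict[str, dict] = {}
    for ds_id, table in items:
        for row in table.itertuples(index=False):
            gene = str(row.gene).upper()
            prov = getattr(row, "datasets", None)
            sources = prov.split(",") if isinstance(prov, str) and prov else [ds_id]
            direction = row.direction
            rec = records.setdefault(
                gene, {"directions": set(), "datasets": set()}
            )
            rec["directions"].add(direction)
            rec["datasets"].update(sources)

    rows = []
    for gene in sorted(records):
        rec = records[gene]
        dirs = rec["directions"] - {"conflict"}
        conflict = len(dirs) > 1 or "conflict" in rec["directions"]
        rows.append(
            {
                "gene": gene,
                "direction": "conflict" if conflict else next(iter(dirs)),
                "direction_conflict": conflict,
                "datasets": ",".join(sorted(rec["datasets"])),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "direction", "direction_conflict", "datasets"])
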