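# Methods

This note documents the models and procedures implemented in `orthonet`,
the defaults they carry, and the design decisions taken where the
underlying methods are conventionally under-specified.

## DEG screening

Each expression dataset is a log2-intensity gene × sample matrix with a
case/control label per sample (a linear-scale flag applies `log2(x+1)` on
load). Per gene, the effect is `log2FC = mean(case) − mean(control)` and
the p-value comes from Welch's unequal-variance two-sample t-test; a
pooled-variance mode exists but Welch is the default because group
variances in case/control designs are rarely equal. Benjamini–Hochberg
adjusted p-values are always computed and reported, but the screen gates on
the raw p by default (`use_adjusted_p` switches). The retention rule is
`p ≤ 0.05` and `0.25 ≤ |log2FC| ≤ 1.5`; both band edges are configurable
and `lfc_max = inf` recovers the conventional one-sided threshold. The
band's upper bound deliberately *excludes* very large effects, which in
meta-analyses of heterogeneous array datasets often flag platform artifacts
rather than biology; users who disagree set it to infinity.

Degenerate genes: constant across all samples → p = 1 by convention;
constant within both groups at different levels → zero sampling variance,
p set to the smallest positive float (the limit of the test as variance →
0 with a nonzero effect).

Merging across datasets upper-cases symbols, de-duplicates, records
per-gene provenance, and *flags* direction conflicts (`direction =
"conflict"`) rather than resolving them — a conflict is information, not
noise. Merge is idempotent.

## Network construction

Edge tables are STRING-export-like 3-column TSVs. The default confidence
cutoff is 0.4 ("medium confidence" in STRING's convention); the appropriate
cutoff and score channel depend on the snapshot used, so both are plain
configuration and logged. Cleanup order: whitelist restriction →
self-loop removal → duplicate-pair collapse keeping the **maximum** score
(conservative retention of the strongest evidence) → isolated-node
removal. Human symbols are upper-cased; worm names are left verbatim
(`pmk-1` style). An empty result is a legitimate empty network.

## Centralities

* **Betweenness** is computed by Brandes' dependency accumulation over
  single-source BFS shortest-path DAGs, endpoints excluded, normalized by
  the undirected pair count (n−1)(n−2)/2 so values live in [0, 1] and a
  star center scores exactly 1.
* **Closeness** is (reachable nodes)/(sum of distances to them) — on a
  connected graph the familiar (n−1)/Σd, on a disconnected one the
  reciprocal mean distance within the component, which avoids infinities
  and matches common network-analyzer behavior.
* **Bottleneck** grows one BFS shortest-path tree per root; a non-root node
  whose subtree exceeds a quarter of the tree's nodes is a bottleneck for
  that root, and BN(v) counts such roots. The tree is not unique, so
  determinism is enforced: parents are chosen lexicographically. Subtree
  counting is v-inclusive and the root is excluded as a candidate — the
  published description of this centrality is ambiguous on endpoint
  handling, and this choice makes the leaf/single-edge cases well-defined
  (a single edge gives BN = 1 to each endpoint).
* **Degree profiles**: P(k) is the degree distribution; C(k) averages the
  local clustering coefficient `2·links/(k(k−1))` (0 when k < 2) over
  degree-k nodes — the clustering coefficient is used, not Cytoscape's
  "topological coefficient", which measures shared-neighbor overlap and is
  a different quantity; C_N(k) averages mean neighbor degree.

Both betweenness and closeness are verified against an exhaustive
all-shortest-paths enumeration oracle on seeded random graphs (n ≤ 50,
tolerance 1e-9).

## Key regulators and neighborhoods

Per metric, genes are ranked by value descending with lexicographic
tie-break, the top N = 20 taken, and the KR set is the intersection of the
lists — three metrics (degree, betweenness, closeness) for the human
network, four (adding bottleneck) for the projected network; the metric
lists and N are configuration. The closed first neighborhood returns the
seeds *plus* their direct interactors, so |result| = |seeds in network| +
|non-seed neighbors|; seeds absent from the network are reported, not
fatal. Manual hub tracing through hierarchical network levels has no
published algorithm; the pipeline instead reports each KR's membership in
the detected modules, which captures the same question — do the regulators
sit inside the dense cores? — reproducibly.

## Ortholog projection

Tables from several sources are unioned (pairs deduplicated, evidence
labels unioned); an intersection mode was considered and rejected as the
default because source compendia have complementary coverage, but a
minimum-evidence filter can be applied by the caller. Projection expands
one-to-many mappings fully — a human gene may legitimately have several
worm co-orthologs and collapsing to best hits would bias the projected
network against duplicated families.

## MCODE

Re-implemented in full: vertex weight = (highest k-core of the node's
closed neighborhood) × (that core's density), zero below the degree
cutoff; complexes grow breadth-first from the highest-weight unassigned
seed, including neighbors with weight ≥ seed weight × (1 − node score
cutoff), never revisiting assigned nodes, to a depth cap; post-processing
discards clusters without a 2-core, shaves singly-connected nodes
(haircut, single pass), and optionally fluffs boundary nodes. Expansion
order among equal-weight candidates is lexicographic — the original
description leaves it unspecified and determinism is required for testing.
Defaults are the conventional ones: degree cutoff 2, node score cutoff
0.2, k-core 2, max depth 100, haircut on, fluff off.

A cluster's score is density × node count computed on the subgraph its
nodes induce **in the parent network** (that is what published module
tables describe): `2E/(N(N−1)) × N = 2E/(N−1)`, so an N-clique scores
exactly N. Modules with score ≥ 5 are reported as significant by default.
The weighting routine is tested against an independent core-decomposition
oracle, and recovery of a planted 24-clique in background noise is part of
the acceptance surface.

## Enrichment and cross-species comparison

Over-representation uses the upper-tail hypergeometric
`P(X ≥ k | M, K, n)`; the EASE variant (overlap decremented by one before
the tail, floor 0) is available because DAVID-style tools report it, but
the standard tail is the default. Fold enrichment is `(k/n)/(K/M)`. The
background defaults to the union of loaded term members — species-wide
annotation backgrounds are snapshot-dependent — and can be set explicitly.
BH correction runs within each GO category (BP/CC/MF) and pathways
separately, matching how per-category tables are conventionally reported.
A pathway is called enriched at raw p ≤ 0.05 before intersection (adjusted
gating is a flag); the cross-species table keeps terms significant in
*both* species, mapped through an identifier crosswalk — for KEGG-style
ids, identity on the numeric suffix after stripping the 3–4 letter species
prefix (`hsa04010` ↔ `cel04010`); other vocabularies need an explicit map.

The hypergeometric tail is verified against exhaustive enumeration over
all C(M, n) draws for M ≤ 15.

## Synthetic data: what it emulates and what it does not

The generators emulate the *shapes* the pipeline consumes, with planted
truth for every downstream contract:

* **Expression**: Gaussian log2 noise around gene baselines (N(8, 2)),
  within-group σ = 0.5, planted case-mean shifts of ±1.0 log2 units —
  chosen so that the t-test's assumptions hold exactly and type-I error
  calibration is meaningful. The planted sign is a deterministic function
  of the gene name so multi-dataset fixtures stay directionally coherent.
  Probe-level artifacts, normalization drift and batch effects are *not*
  emulated, so passing tests demonstrate correctness of the screen's
  logic, not robustness to raw microarray pathology.
* **Networks**: preferential attachment for hub-dominated backgrounds, or
  planted cliques/dense blocks over Erdős–Rényi noise. Planted-module
  edges carry scores in [0.7, 1) versus [0.15, 1) for noise — planted
  clusters stand in for well-characterised complexes, whose interactions
  carry strong evidence — so default-confidence filtering does not shred
  the planted structure. Degree-correlated score biases of real curated
  networks are not modeled.
* **Orthologs**: exact coverage and one-to-many quotas with unique
  synthetic worm-style names; no paralog families or shared targets.
* **Annotations**: planted terms draw 80% of members from a target set,
  the rest uniformly; term overlap structure (GO's hierarchy) is absent.

The end-to-end bundle (`simulate_bundle`) wires these together so that the
planted 24-clique provably flows DEG screen → network → KRs →
neighborhood → projection → module detection: the clique sits on orthologs
of the largest human cluster, whose members are planted DE in both
datasets and guaranteed ortholog coverage. Bundle sizes (800 genes, two
15 vs 15 datasets, 150-gene disease pool, ~3400 human edges) are chosen so
a full run takes about a second while leaving every stage's statistics
comfortably away from small-sample degeneracy.

## Numerical and testing choices

* Acceptance-grade checks run at fixed seeds; stochastic recovery claims
  (planted-clique recovery, screen recall) are evaluated over 20 seeded
  replicates with the success criterion at ≥ 95%.
* Type-I calibration uses 10,000 null genes, 20 vs 20 samples, tolerance
  three binomial standard errors.
* The run manifest contains parameters, stage counts and input checksums
  but no timestamps, so identical configs reproduce byte-identical
  manifests.
* Ranking ties anywhere in the pipeline break lexicographically; all
  generators are pure functions of their seed.

## Known limitations

* Welch's t-test stands in for moderated (empirical-Bayes) statistics;
  with very few samples per group its p-values are less stable than
  limma-style shrinkage. The screen's thresholds, not the variance
  estimator, are the point of the procedure.
* MCODE's interactive "re-run on subgraph" mode and overlapping-cluster
  variants are out of scope.
* The enrichment background is collection-derived unless supplied;
  comparisons against web-service results will differ with their
  species-wide backgrounds and annotation snapshots.
* Published gene lists from any specific study depend on database
  snapshots (expression repositories, interaction databases, ortholog
  compendia) and are not expected to reproduce exactly from other
  snapshots; the package reproduces the *method*, with synthetic fixtures
  covering the result shapes.
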