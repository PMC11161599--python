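# Methods

## Pipeline model

`markerbench` treats marker-gene benchmarking as a three-stage procedure on
a cells × genes UMI count matrix `X` with a reference partition C^E of the
cells (the "expected" clusters, usually the user's annotation).

**Preparation.** Cells are kept when their detected-gene count lies in
[`min_genes`, `max_genes`] (defaults 200 and 6000) and their mitochondrial
count fraction (genes prefixed `MT-`/`mt-`) is at most `max_mito_fraction`
(default 0.2). These defaults are deliberately permissive conventions, all
exposed as flags; the filter is idempotent by construction because the gene
axis is untouched. Normalization is library-size normalization,
`log(1 + x_cg / Σ_g x_cg · s)` with natural log and scale factor
`s = 10⁴`, which is exactly invariant to rescaling any cell's counts.
Scaling z-scores each gene with the population SD and clips at ±10
(constant genes map to 0); scaled values feed only the re-clustering —
every selection method consumes the log-normalized matrix, because rank-
based and cosine statistics are what the respective originals compute on
expression, not on z-scores. HVG ranking uses dispersion = variance/mean of
log-normalized expression, z-standardized within up to 20 equal-frequency
mean bins so that genes compete against genes of similar expression; the
bin count is capped at one bin per ten genes (tiny panels fall back to
plain dispersion) because singleton bins have no within-bin SD and would
degenerate to gene-order ranking. All ties, here and everywhere, break by
gene list order under stable sorts, making every ranking reproducible.

## Selection methods

All methods emit at most `n_per_cluster` genes per cluster (default 10, the
convention for reporting marker panels) with a score that is non-increasing
in rank.

* **wilcoxon** — per cluster, two-sided Wilcoxon rank-sum of in-cluster vs
  all other cells per gene, normal approximation with tie and continuity
  corrections. Genes with positive in-minus-rest mean log difference are
  ranked by ascending p, then descending mean difference; score −log₁₀ p.
  The approximation tracks exact enumeration well for moderate groups but
  is intrinsically coarse for very small ones (max |Δp| ≈ 0.09 over all
  splits of n ≤ 8 with both groups ≥ 2; ≤ 0.02 only from n = 7 up) — a
  property of the statistic, documented rather than patched, since clusters
  of two or three cells are below any reasonable DE sample size.
* **kruskal** — per gene, tie-corrected Kruskal–Wallis H across all
  clusters against χ²(k−1); each gene is assigned to its highest-mean
  cluster (requiring a positive mean contrast over the rest) and clusters
  rank their genes by ascending p.
* **cosg** — cosine similarity cos θ_gk between the gene's expression
  vector and the one-hot indicator of cluster k, penalized by similarity to
  other clusters: score = cos θ · cos²θ / (cos²θ + μ Σ_{k'≠k} cos²θ_{gk'}),
  μ = 1 by default. The cosine magnitude is kept in the numerator: a pure
  ratio score saturates at 1 for any gene expressed in a handful of
  cluster-exclusive cells (zero penalty term), which would rank two-cell
  noise genes above genuine markers; with the magnitude kept, μ = 0
  degenerates exactly to ranking by raw cosine. This penalized form is this
  package's definition of the cosine method.
* **scmarker** — stage 1 keeps genes whose 2-component Gaussian mixture
  beats the 1-component fit by ≥ 10 BIC (bimodal on/off expression); stage
  2 binarizes each candidate at its mixture decision boundary and keeps
  those with ≥ 5 other candidates in significant 2×2 χ² association
  (p < 0.01, co-occurrence or mutual exclusion — discriminative genes
  travel in packs); stage 3 gives each cluster its top genes by in-cluster
  mean. A simplified, fully specified variant of the ab-initio original;
  k-NN consistency heuristics are not reproduced. May legitimately return
  an empty table (warning, not an error).
* **hgt** — for each gene and cluster, sweep cuts over the gene's distinct
  expression values; at each cut compute the hypergeometric upper-tail p
  that cells above the cut are enriched in the cluster; take the minimum
  over cuts (the all-cells cut keeps constant genes at exactly p = 1).
  Benjamini–Hochberg within cluster, keep adjusted p ≤ 0.05, rank
  ascending. Single genes only; no multi-gene panel search.
* **hvg** — the top `n_per_cluster × k` HVGs globally, each assigned to its
  highest-mean cluster and re-ranked by dispersion. A deliberately
  cluster-blind baseline: it shows how much re-clustering agreement is
  attainable from global variability alone, so specificity claims by other
  methods have a floor to beat. Clusters may receive fewer than
  `n_per_cluster` genes because the global pool is split by assignment.
* **plugin** — any shell command template `{norm} {clusters} {out}` whose
  output is a standard `markers.csv`; parsed and validated exactly like the
  built-ins (non-zero exit or unparseable output is a plugin error carrying
  stderr; structural violations are validation errors).

## Evaluation

Re-clustering restricts the scaled matrix to the pooled unique marker
genes, reduces with PCA to at most 30 components when more genes remain
(full SVD solver — deterministic), builds a k = min(20, n−1) Euclidean kNN
graph, and runs Leiden modularity optimization (RBConfiguration, resolution
0.8, fixed seed). These defaults stand in for the common "default
clustering" conventions of the field and are all exposed as flags.
Identical inputs and seed give identical partitions.

From the contingency table n_ij between C^o and C^E:

* **ARI** — (Σ C(n_ij,2) − E) / (½[Σ C(n_i·,2) + Σ C(n_·j,2)] − E) with
  E the chance expectation. The standard form can be negative for
  worse-than-chance agreement and is *not* clamped to [0, 1]; when the
  index and its expectation coincide (e.g. a trivial partition) the value
  is defined as 0 (1 for two identical trivial partitions).
* **Jaccard (overall)** — pairwise JI(i,j) = n_ij/(n_i· + n_·j − n_ij); the
  overall score averages, over expected clusters, the best-matching
  observed cluster's JI. A plain mean over all i×j pairs shrinks toward 0
  as cluster count grows, so best-match is the default and the all-pairs
  mean is available as an option. Directional (expected side anchors the
  average), as is purity.
* **NMI** — I(C^o, C^E)/√(H(C^o)·H(C^E)) in natural log (the base cancels),
  with 0·log 0 ≡ 0; defined as 0 with a warning when either partition is
  trivial.
* **FMI** — √(TP/(TP+FP) · TP/(TP+FN)) over unordered cell pairs,
  TP = Σ C(n_ij,2); 0 when TP = 0.
* **purity** — Σ_i max_j n_ij / n, observed clusters against expected
  labels.

Known-marker precision/recall compare gene symbols case-sensitively
(exact match — silent aliasing would be worse than a missed synonym), per
cluster and pooled over the unions of predicted and known genes; clusters
with empty known sets are skipped, and an empty prediction yields missing
values with a warning rather than a fake zero. The standard-scale matrix
(per-gene min–max of cluster means, constant rows → 0) is the numerical
object behind the usual marker heatmaps; no image rendering is done.

## Synthetic data

The simulator generates what the pipeline actually eats: a 10x triple, a
cluster CSV, a known-marker CSV. Gene base means are lognormal (ln-mean 0,
ln-SD 1 — at the 2000-gene default this gives ≈ 3000 UMI per median cell,
the typical 10x regime); cells get lognormal library factors (ln-SD 0.3);
counts are negative binomial with variance μ + μ²/φ, φ = 2 (moderate
overdispersion), giving realistic sparsity without an extra zero-inflation
knob, so `dropout_rate` defaults to 0 and adds independent Bernoulli zeros
only when asked. Cells are allocated to clusters by largest remainder, so
sizes are exact and reproducible. Each cluster plants `markers_per_cluster`
(default 10) disjoint marker genes whose mean is multiplied by
2^`marker_logfc` (default 2, i.e. 4-fold) in the target cluster only.
Planted markers draw their base means from the *same* lognormal as
background genes — at `marker_logfc = 0` the two groups are statistically
exchangeable, so any recovery above chance is attributable to the planted
fold-change alone. All randomness flows from one seed through a single
generator.

What the simulator does *not* emulate: batch effects, continuous
trajectories, gene–gene correlation beyond the planted structure, and
cell-type-specific library sizes. Passing recovery tests therefore show
that a method detects clean mean-shift markers at realistic noise — not
that it is robust to confounded real data.

Default study conditions used by the tests and the acceptance script:
5 clusters × 100 cells, 2000 genes, 10 planted markers per cluster at
4-fold up-regulation; the imbalance series uses 2 clusters × 500 cells at
mixing 1:1 vs 9:1 over 10 seeds. These sizes resolve every effect of
interest while keeping a full run in the minutes range on one CPU.

## Numerical conventions and degenerate inputs

* p-values are floored at 1e-300 before −log₁₀ scores.
* Zero-variance ("constant") genes: never HVGs, z-score 0, cosine 0,
  minimal-hypergeometric p = 1, Kruskal/Wilcoxon excluded by the positive
  contrast requirement.
* A gene vector of all zeros has cosine 0 to every cluster by convention.
* Cells with zero total counts are dropped at normalization with a warning.
* Cluster labels are opaque strings ordered by first appearance; numeric
  labels are kept in string form. Cluster CSV headers are auto-detected
  (first row with second field "cluster" or first field "barcode",
  case-insensitive).
* The on-disk matrix is genes × cells, 1-based MatrixMarket, as 10x writes
  it; in memory everything is cells × genes.

## Known limitations

* The Wilcoxon/Kruskal p-values are asymptotic; exact enumeration is used
  only as a test oracle. For clusters under ~7 cells the reported p can
  deviate from exact by up to ~0.09 (see above); rankings are far more
  stable than the p-values themselves.
* The minimal hypergeometric sweep is O(cells) per gene and cluster;
  it is the slowest selector (~seconds at 500 × 2000).
* scmarker fits two mixture models per gene and is intended for
  moderate gene counts (use HVG reduction first on large panels).
* Leiden resolution 0.8 recovers the planted k at the default conditions
  but is a convention, not an estimate of k; severely imbalanced data
  over-split at this resolution, which is precisely the sensitivity the
  imbalance study measures.
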