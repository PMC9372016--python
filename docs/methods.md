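# Methods

This note documents the models and procedures `scshift` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where more than
one reasonable convention exists.

## Input model and normalization

The package operates on genes × cells UMI count matrices (MatrixMarket
triplet or dense TSV) with a per-cell annotation table (sample,
condition ∈ {control, perturbed, treated}, batch, cell type, optional
tissue/timepoint). Cell-type labels are inputs: clustering, embedding
and label transfer are deliberately out of scope.

Quality filtering keeps a cell when it has at least `min_genes`
detected genes (count > 0; default 200) **and** a mitochondrial UMI
fraction strictly below `max_mito_fraction` (default 0.15). The strict
inequality is a fixed convention: a cell at exactly the maximum is
removed. Mitochondrial genes are identified by the configurable id
prefix `mt-` (mouse convention) or an explicit list.

Log-normalization is `value(g,c) = ln(1 + s · count(g,c) / total(c))`
with scale factor `s = 10,000`. Natural log is used (configurable only
by post-transforming; the sparsity pattern of the counts is preserved,
and per cell Σ<sub>g</sub> (e<sup>value</sup> − 1) = s exactly). Cells
with zero total UMIs are rejected with a pointer to run QC first.

## Sensitivity metrics

All three metrics operate on the top `top_n_genes` (default 1000) most
highly expressed genes of the cell type, computed on the pooled cells
of both conditions, with lexicographic tie-breaks for determinism.

**Euclidean shift.** Genes are z-scored with the sample (n−1) standard
deviation over the pooled cells; zero-variance genes map to all-zero
rows rather than NaNs. The observed statistic is the distance between
the two per-condition mean z-vectors. The null permutes condition
labels with group sizes preserved; gene selection and z-scores are
computed once on the pooled cells and *not* re-derived per permutation,
which keeps the null exchangeable with the observed statistic. The
empirical p uses the add-one estimator (never 0, floor 1/(B+1));
Bonferroni is applied across the cell types tested within the same
tissue × timepoint stratum. The ranking statistic is
log2(observed / null mean) rather than the raw distance, because the
ratio normalizes away cell-count and gene-count effects; the raw
distance is reported alongside. Degenerate inputs: constant expression
gives distance 0 and p = 1; if exactly one of observed/null mean is 0
the log-ratio is ±∞, which still ranks correctly.

**SVM shift.** A linear-kernel soft-margin SVC with C = 1 (no kernel or
hyperparameters are tuned; the cost value is a fixed convention). Per
bootstrap: stratified 70/30 split, optional repeated stratified k-fold
CV on the training portion (`cv_folds`=10 × `cv_repeats`=3 by default,
run for protocol fidelity only — nothing is selected from it; CV is
skipped when a training class has fewer members than folds), fit on the
training cells, accuracy recorded on the untouched 30 %. Features are
the pooled z-scored top genes; pooled scaling uses no label
information, so chance-level calibration on label-randomized data is
unaffected. Cell types with fewer than `min_cells_per_group` (default
10) cells in either condition are skipped with a reason and excluded
from ranking.

**Subsample-DEG count.** Conditions above `subsample_n` (default 100)
cells are subsampled to that size; smaller groups are used whole, and
when *neither* group needs subsampling the replicates are identical, so
a single run is performed (the Tippett family size `k` stays the
nominal `n_permutations` — the combiner of k identical values equals
1 − (1 − p)^k either way). Genes failing the DE pre-filters in a
replicate contribute an adjusted p of 1. Per gene the minimum adjusted
p across replicates enters 1 − (1 − min p)^k, evaluated as
−expm1(k·log1p(−p)) for accuracy at small p; the statistic is the count
of genes with meta p < `alpha`.

**Consensus.** Each metric ranks descending by its statistic
(log2-ratio, median accuracy, DEG count), rank 1 = most perturbed,
average ranks on ties; the consensus is the unweighted mean of the
three ranks, reported at full precision and rounded to 2 d.p. in the
table view.

## Differential expression

Wilcoxon rank-sum, two-sided. Pre-filters: the gene must be expressed
(value > 0) in ≥ 10 % of the cells of at least one group, and
|log FC| ≥ 0.25. Fold change is
ln[(mean(e<sup>x₁</sup>−1)+ε)/(mean(e<sup>x₂</sup>−1)+ε)], ε = 10⁻⁹ —
the ratio of de-logged group means, the convention of the scRNA-seq
software family this procedure mirrors (the alternative, difference of
mean log values, is more conservative for sparse genes). Exact
enumeration is used when both groups have ≤ 25 cells and the gene has
no cross-group ties; otherwise the normal approximation with tie and
continuity correction (vectorized across genes).

**Multiplicity family.** Bonferroni uses *all genes in the matrix* as
the family, not only the genes passing the pre-filters. This was a
genuinely open choice: correcting only over tested genes looks natural,
but the fold-change pre-filter selects genes with randomly extreme
observed effects, so conditioning the family on the filter is
anti-conservative — in null simulations (500 genes, 50 vs 50 cells) the
tested-genes family produced at least one false Bonferroni-significant
gene in ~9 % of replicates versus ~2.5 % with the all-genes family. The
all-genes denominator is also the documented convention of the software
family the procedure mirrors.

Conserved markers run the same test cluster-vs-rest within each
timepoint × condition stratum; genes surviving the pre-filters in every
usable stratum (≥ 2 strata required; under-sized strata are dropped
with a warning) get a Tippett meta p across strata, the all-genes
Bonferroni, and must have a consistent fold-change direction.

Treatment reversal: a gene is reversed when adjusted p < α in both the
perturbed-vs-control and treated-vs-perturbed tables and the
fold-change signs are opposite. The rule is symmetric as a gene set.

Enrichment: one-sided (greater) Fisher's exact test on the 2×2 overlap
table after intersecting query and sets with the declared universe;
Benjamini–Hochberg across the sets tested.

## Ligand–receptor coordination

For every ordered cluster pair (A, B) and ligand–receptor pair, the
score is ½·(mean ligand expression in A + mean receptor expression in
B) on log-normalized values — the mean-of-means combiner. A pair is
tested only when the ligand is expressed in strictly more than 10 % of
A's cells and the receptor in more than 10 % of B's (the gate uses the
observed labels). The null shuffles all cluster labels jointly,
preserving cluster sizes, and recomputes the score (default 1000
shuffles, minimum 100); p is the add-one estimator. Tiles count pairs
with p < α per ordered (A, B); a symmetrized matrix (tile + transpose)
is emitted as well, since either counting convention may be wanted. No
FDR is applied across pairs — the tile counts are descriptive counts of
marginally significant interactions, which is the described usage; this
is flagged here deliberately. Note a limitation inherent to the
mean-of-means score: a strongly boosted ligand (or receptor) raises the
score of *every* direction using that sender (or recipient), not only
the co-expressed pair — directionality is informative mainly relative
to the strict reverse direction.

## Batch mixing

Per cell type, a self-inclusive kNN graph (Euclidean, on log-normalized
expression) with k = max(10, ⌈0.25·n⌉) by default (k is exposed — the
original method's heuristic is not published in a single convention).
Each of `n_runs` = 100 runs samples 10 % of the cells and compares each
sampled cell's neighborhood batch composition to the global proportions
with a chi-squared goodness-of-fit test, (B−1) df, α = 0.05; expected
categories below 1 are merged smallest-first, and a single remaining
category never rejects (hence acceptance exactly 1.0 for one batch).
Acceptance = mean over runs of (1 − rejection rate); > 0.75 is reported
as well mixed. Cell types with fewer than 15 cells are skipped.

## Synthetic-data generator

Counts are negative binomial, NB(μ, r) with shared inverse-dispersion
r (`nb_dispersion`, default 2 — moderate overdispersion typical of
droplet UMI data), where
μ = μ<sub>g</sub> · exp(Δ) · lib<sub>c</sub>: μ<sub>g</sub> is a
log-normal per-gene baseline (default meanlog −1, sdlog 1, i.e. most
genes weakly expressed with a heavy right tail), lib<sub>c</sub> a
log-normal per-cell library factor (sdlog 0.3), and Δ sums the
applicable natural-log offsets:

- condition effect: a random `fraction_de` of non-mitochondrial genes
  shifts by ±`log_fc` in perturbed cells (50/50 up/down by default);
  the scalar effect size is fraction_de × |log_fc|;
- batch effect: each non-reference batch shifts a random 10 % gene
  subset by `batch_effect_log_fc` (additive in log-mean space);
- planted ligand–receptor pairs: ligand up in all cells of the sender
  type, receptor up in the recipient type, by `boost_log_fc`; planted
  genes optionally get a fixed baseline mean (`lr_base_mean`, default
  1.0) so the 10 % expression gate is controllably open or closed.

Mitochondrial gene means are tuned so the expected mito fraction hits
`mito_fraction_target` (default 0.05). Identical config + seed is
bit-identical. Ground truth (per-type effect sizes, DE gene lists and
signs, planted pairs, batch gene subsets) is returned alongside.

What the generator does **not** emulate: gene–gene correlation beyond
the planted structure, zero inflation beyond NB sampling, doublets,
ambient RNA, cell-type-specific library sizes, or any attempt to match
a real dataset's per-gene distributions. Passing tests therefore
demonstrate calibration and recovery under a well-specified NB world;
on real data the metrics remain valid permutation tests, but power
statements do not transfer.

## Determinism and seeds

Every stochastic step takes an explicit seed; orchestration derives
sub-seeds by SHA-256 hashing of (master seed, stage, stratum, cell
type), so per-component results are independent of execution order and
always below 2³¹. Pipeline runs write a manifest with the package
version, seed, a parameter hash, and per-stage status/outputs;
identical config + seed reproduces outputs byte for byte.

## Problem sizes used in the test and acceptance suites

Simulations run at desk scale, chosen as the smallest sizes at which
the statistical properties under test are comfortably identifiable:
null-calibration replicates use one cell type with 30 cells per
condition and 80 genes (Euclidean shift, 400 replicates × 100
permutations), 50 cells × 500 genes (DE null, 50 replicates), and three
clusters × 40 cells with 18 decoy pairs × 10 datasets (≥ 1000
ligand–receptor pair tests); parameter recovery uses three cell types ×
120 cells per condition × 300 genes with effect sizes 0/0.3/0.8 over 20
replicates; classifier calibration uses 100 cells per group × 100 genes
at 200 bootstraps; batch audits use 200 cells × 200 genes at 100 runs.
`scripts/acceptance.py` recomputes the same quantities at the same
sizes (200 Euclidean replicates, 10 recovery replicates) from the
`--seed` argument alone.

## Known limitations

- The three sensitivity metrics detect *transcriptomic* shifts only;
  cell types whose response is morphological or post-transcriptional
  are invisible to all three.
- The Euclidean null permutes condition labels within the cell type;
  sample-level (animal-level) correlation is not modelled, so p-values
  are calibrated at the cell level, as in the procedure implemented.
- The subsample-DEG Tippett combiner treats subsample replicates as the
  meta-analysis family; replicates overlap in cells and are not
  independent, so the meta p is a stability score rather than a
  calibrated p — it is used only to *count* stable DEGs, never reported
  as significance on its own.
- The ligand–receptor module ships a ~30-pair toy table; real analyses
  should supply a curated resource via `--pairs`/`lr_pairs_path`.
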