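# scshift

Which cell types does a perturbation hit hardest? `scshift` answers that
question for droplet single-cell RNA-seq studies with a two-condition
design (control vs perturbed, optionally plus a treated arm): it ranks
cell types by how far their transcriptomes moved, calls the genes that
moved, tests whether cell–cell ligand–receptor coordination changed, and
audits whether batch structure could explain any of it. It is written
for computational biologists analysing case/control scRNA-seq at the
cell-type level — given a UMI count matrix and per-cell labels (sample,
condition, batch, cell type), everything downstream of clustering is
covered.

## The statistics at the core

For each cell type *c* within a tissue × timepoint stratum, three
complementary resampling metrics quantify the transcriptome shift
between conditions, each on the top *N* = 1000 most highly expressed
genes:

- **Euclidean shift.** Expression is z-scored per gene over the pooled
  cells; the statistic is the Euclidean distance
  ‖z̄<sub>perturbed</sub> − z̄<sub>control</sub>‖ between the two
  per-condition mean vectors ("representative cells"). A null is built
  by permuting condition labels (group sizes preserved, 1000
  permutations); reported are the add-one empirical p-value
  p = (1 + #{d<sub>null</sub> ≥ d<sub>obs</sub>})/(1 + B), a Bonferroni
  correction across the cell types in the stratum, and
  log<sub>2</sub>(d<sub>obs</sub>/mean d<sub>null</sub>), the ranking
  statistic.
- **SVM shift.** A linear soft-margin SVM (C = 1) predicts the condition
  label from the z-scored top genes over 1000 stratified 70/30
  bootstrap splits; the ranking statistic is the median held-out
  accuracy. Requires ≥ 10 cells per group.
- **Subsample-DEG count.** Each condition is subsampled to 100 cells
  (groups already at or below 100 are used whole) and a Wilcoxon
  rank-sum DE test with 10 %-expressed and 0.25 log-FC pre-filters and
  Bonferroni correction is run, 1000 times; per gene the replicate
  p-values are combined with Tippett's minimum-p rule,
  p<sub>meta</sub> = 1 − (1 − min p)<sup>k</sup>, and the statistic is
  the number of genes with p<sub>meta</sub> < 0.05. Equal subsample
  sizes give every cell type the same statistical power.

Each metric ranks the cell types (rank 1 = most shifted, average ranks
on ties) and the **consensus rank** is the equal-weight arithmetic mean
of the three ranks.

Around that core: Wilcoxon DEG calling with the same pre-filters,
conserved cluster markers via Tippett meta-analysis across
timepoint × condition strata, *treatment-reversal* detection (genes
significant in both perturbed-vs-control and treated-vs-perturbed with
opposite fold-change signs), Fisher's-exact pathway enrichment with
Benjamini–Hochberg FDR, a CellPhoneDB-style ligand–receptor permutation
test (score = mean of the ligand's and receptor's cluster means, null
from joint cluster-label shuffles, 10 % expression gate), and a
kBET-style kNN batch-mixing acceptance test (acceptance > 0.75 ⇒ well
mixed). A negative-binomial synthetic-data generator with planted ground
truth (per-type effect sizes, DE genes, ligand–receptor pairs, batch
effects) makes every stage testable end to end.

## Worked example

`examples/02_sensitivity_ranking.py` simulates three cell types with
true effect sizes 0, 0.3 and 0.8 and runs the full ranking:

```
true effect sizes: {'type0': 0.0, 'type1': 0.3, 'type2': 0.8}
cell_type  ed_statistic  svm_statistic  deg_statistic  ed_rank  svm_rank  deg_rank  avg_rank  ed_p_adjusted
    type2         2.474          1.000          100.0      1.0       1.0       1.0       1.0          0.015
    type1         1.429          0.944           31.0      2.0       2.0       2.0       2.0          0.015
    type0         0.009          0.472            0.0      3.0       3.0       3.0       3.0          1.000
```

The untouched type sits at a log2 distance ratio of ~0 versus its
permutation null, classifies at chance (0.47) and yields no stable DEGs;
the strongly perturbed type separates perfectly and lands at consensus
rank 1, matching the planted order. The other scripts in `examples/`
walk through QC + normalization, DE + enrichment + reversal, the
ligand–receptor test, batch-mixing auditing, and the one-config pipeline
(also available as a CLI: `scshift synth|qc|sensitivity|de|reverse|enrich|lr|batchqc|run`).

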