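# otokit

Single-cell RNA-seq analysis for inner-ear sensory epithelia — a tested,
reusable reimplementation of the classic pipeline used to resolve the cell
types of the neonatal mouse utricle and cochlea (hair cells, supporting
cells, transitional epithelial cells and their sub-populations), and to
order cells along a hair-cell differentiation trajectory.

The package covers the full analysis chain:

- **Normalization** — cross-sample median-of-ratios scaling (the DESeq
  size-factor scheme): for gene *g* with values *x<sub>gc</sub>*, size
  factor *s<sub>c</sub>* = median<sub>g</sub>
  ( *x<sub>gc</sub>* / (∏<sub>c</sub> *x<sub>gc</sub>*)<sup>1/n</sup> ),
  genes with a zero geometric mean excluded; normalized values are "nTPM".
- **Limit of detection** — nTPM < 1 set to zero, the rest log2-transformed;
  the LOD is recoverable from a 92-species RNA spike-in dilution series.
- **QC** — analytic gene-saturation depth cutoff (hypergeometric
  expectation of down-sampling), and low-expressing-cell identification by
  trimmed-gene median expression against the pooled cohort distribution.
- **Batch correction** — deterministic per-gene location/scale equalization
  of isolation batches.
- **Clustering** — CV-based gene filtering, PCA, PC-correlated gene
  selection, and k-means with the number of clusters *k* chosen by the gap
  statistic: Gap(*k*) = E*[log W<sub>k</sub>] − log W<sub>k</sub> against
  uniform reference draws, selecting the smallest *k* within one reference
  s.e. of the first local maximum.
- **Differential expression** — Gaussian likelihood-ratio test on log2
  expression, Λ = *n*·ln(RSS₀/RSS₁) ~ χ²<sub>G−1</sub>, with seeded noise
  injection, Benjamini–Hochberg FDR, and Jensen–Shannon marker specificity:
  S<sub>k</sub> = 1 − JSdist(p, e<sub>k</sub>) where p is the normalized
  vector of per-group log2 geometric means and e<sub>k</sub> the one-group
  indicator.
- **Pseudotime** — ICA embedding, Euclidean minimum spanning tree, backbone
  = tree diameter path, natural-spline (df = 3) likelihood-ratio test for
  pseudotime dependence, and k = 4 clustering of fitted kinetic trends
  (Off / Early / Transient / Late).
- **qPCR** — standard-curve primer efficiency E = 10^(−1/slope) with a
  ±0.2 validation window around the ideal of 2, and Ct → log2 expression
  = LOD − Ct (LOD Ct 24).
- **Synthetic data** — truth-known generators for cell populations with
  planted markers and logistic dropout, differentiation trajectories with
  four kinetic gene classes, spike-in dilution series, batch effects and
  qPCR plates, so every stage is testable without any data download.

## Worked example

```python
from otokit.simulate import simulate_cell_types, default_cell_type_specs
from otokit.preprocess import median_ratio_normalize, apply_lod_log2
from otokit.cluster import (filter_variable_genes, run_pca,
                            select_pc_correlated_genes, gap_statistic,
                            kmeans_cluster)
from otokit.diffexpr import (filter_testable_genes, build_de_table,
                             refine_marker_list)
from sklearn.metrics import adjusted_rand_score

# 150 cells: three 50-cell populations, 50 planted markers each, 2,000 genes
matrix, ann = simulate_cell_types(default_cell_type_specs(), seed=0)
norm = median_ratio_normalize(matrix)          # size factors 0.90-1.12
variable = filter_variable_genes(norm.matrix)
log2 = apply_lod_log2(norm.matrix)
pca = run_pca(log2, genes=variable)
selected = select_pc_correlated_genes(log2.subset(genes=variable), pca,
                                      n_components=2, n_genes=50)
X = log2.subset(genes=selected).to_numpy().T
gap = gap_statistic(X, k_range=range(1, 9), B=50, seed=0)
print(gap.selected_k)                          # 3
km = kmeans_cluster(X, gap.selected_k, seed=1)
print(adjusted_rand_score(ann["truth_label"], km.assignment))  # 1.0

testable = filter_testable_genes(norm.matrix, ann["truth_label"])
ntpm = norm.matrix.subset(genes=testable)
de = build_de_table(ntpm, apply_lod_log2(ntpm), ann["truth_label"], seed=2)
markers = refine_marker_list(de, specificity_threshold=0.5)
print({k: len(v) for k, v in markers.items()})
# {'HC': 50, 'SC': 50, 'TEC': 50}   <- exactly the planted markers
```

The gap statistic selects the true three populations, clustering recovers
them perfectly (adjusted Rand index 1.0), and the refined marker lists
(q < 0.05, top specificity, detected in ≥ 50 % of the group) contain
exactly the 50 planted markers per population with no false positives.

A command-line interface mirrors the stages
(`otokit simulate|normalize|qc|select-genes|cluster|de|specificity|pseudotime|compare-organs|qpcr`),
each writing TSV tables plus a JSON run report; see `otokit --help`.

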