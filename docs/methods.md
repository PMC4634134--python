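# Methods

This note documents the models and procedures otokit implements, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions that matter
for reproducing results.

## Units and the limit of detection

Matrices carry a units tag. Raw relative abundances (TPM) become **nTPM**
after cross-sample median-of-ratios normalization, and **log2nTPM** after
LOD thresholding: values below 1 nTPM are set to 0 (undetected) and the
rest log2-transformed. "Detected" downstream always means nTPM > 1,
equivalently log2nTPM > 0. The 1 nTPM default reflects the abundance at
which spike-in species become detectable in typical full-length single-cell
libraries; `estimate_lod_from_spikeins` recovers it empirically from a
dilution series by walking up the concentration ladder to the point past
the last fully undetected species.

## Median-of-ratios normalization

Per gene, values are divided by the gene's geometric mean across cells;
a cell's size factor is the median of its ratios over genes whose geometric
mean is nonzero (any zero in a gene makes its geometric mean zero and
excludes it). Size factors are then rescaled to unit geometric mean. The
rescaling is a package convention: it fixes the arbitrary overall scale and
makes the operation exactly idempotent — renormalizing normalized data
returns unit factors to machine precision — without changing any relative
comparison. A single cell, or identical cells, get factor 1.

## Outlier cells

Following the single-cell toolkit convention this routine emulates,
low-mean genes are trimmed (ascending mean, one gene at a time — the order
and step are a deterministic convention, chosen for order-invariance) until
≥ 95 % of the remaining genes are above 1 nTPM in ≥ 50 % of cells. A pooled
distribution of log2 expression over the retained genes and all cells is
formed; a cell is an outlier when its median over those genes lies strictly
below the 15th percentile (linear interpolation) of that pooled
distribution. Because a healthy cell's median sits near the pooled 50th
percentile, homogeneous cohorts produce no outliers and only globally
depressed cells are flagged; a percentile taken over per-cell medians
instead would unconditionally flag ~15 % of any cohort. Whether medians are
computed on log2 or linear nTPM is exposed (`median_scale`); log2 is the
default.

## Saturation depth cutoff

Instead of down-sampling reads, the expected number of distinct genes at
depth *d* is computed exactly from a cell's per-gene counts via the
hypergeometric miss probability C(N−c, d)/C(N, d) (log-gamma arithmetic).
The cutoff is the smallest grid depth whose expectation reaches 90 % of the
genes present. This is the same quantity a read-level down-sampling
estimates, without its Monte-Carlo noise.

## Batch correction

A deterministic location/scale adjustment: per gene, each batch's values
are centered, rescaled to the pooled within-batch standard deviation, and
re-anchored at the gene's grand mean; single-cell batches get location-only
adjustment. This removes the additive/multiplicative batch structure that
empirical-Bayes methods (e.g. ComBat) target, without shrinkage — chosen
because it is exactly testable (batch means equalized to 1e-9, grand means
preserved) and sufficient for a preprocessing role. On log2 matrices,
corrected values are clamped at 0; for genes whose values sit near the LOD
this clamp can perturb the mean-preservation guarantees.

## Gene selection and PCA

Clustering genes must be above 1 nTPM in more than 2 cells and have a
cell-to-cell coefficient of variation (population sd / mean, linear nTPM)
of at least 0.5. PCA treats cells as observations with centered,
unit-variance (population) gene variables — eigenvalues then sum to the
number of variables — with a deterministic sign convention (largest
loading positive). Genes are then ranked per leading component by |Pearson
r| against the component scores, significance assessed by the exact t
transform t = r·√((n−2)/(1−r²)); the top genes per component (both tails)
are kept. The number of genes per component has no principled default and
is a required choice (50 in the examples).

## Gap statistic

Gap(k) = mean_b log W\*_kb − log W_k, where W is the k-means within-cluster
dispersion (inertia) and the B = 100 (default) reference datasets are drawn
uniformly over each feature's observed range (the simple box reference, not
the PCA-rotated variant). s_k = sd_b(log W\*_kb)·√(1+1/B). Selection: the
first local maximum k\* (ties toward smaller k; boundary k judged
one-sided), then the smallest k ≤ k\* with Gap(k) ≥ Gap(k\*) − s_{k\*}.
Reference datasets are clustered with the same number of k-means restarts
as the data: an asymmetric optimization effort biases Gap upward at larger
k. k-means itself is k-means++ with 25 restarts (default), seeded;
empty-cluster repair is scikit-learn's.

On null data the method's true behavior should be understood before
reading its output: on 2-D uniform samples both this implementation and
R's `cluster::clusGap` (`firstSEmax`) select k = 1 in only ~85 % of
realizations, because small-sample clumpiness in two dimensions is real;
in five or more dimensions (uniform ball, 150 points) selection is k = 1
in ≥ 98 % of seeds. The validation suite therefore uses a 5-D spherical
uniform null, consistent with the higher-dimensional null experiments of
the method's original validation.

## Differential expression and specificity

The group test is a Gaussian likelihood-ratio test on log2 expression:
full model one mean per group, reduced model a grand mean,
Λ = n·ln(RSS₀/RSS₁) referred to χ² with (groups − 1) df. Because
zero-inflated genes can have zero within-group variance, N(0, 0.01²)
jitter (seeded; the magnitude is a conventional "small noise") is injected
once before testing. Λ is a monotone transform of the one-way ANOVA F
statistic, so p-value *orderings* coincide exactly; the χ² calibration is
asymptotic and mildly anti-conservative at small n (empirical type-I error
~0.055 at 50 cells per group). P-values are Benjamini–Hochberg adjusted
(step-up with monotonicity enforcement, implemented directly and verified
against a brute-force oracle).

Specificity: per gene, the geometric mean over detected (nonzero) cells in
each group, converted to log2 and clamped below at 0 (the clamp keeps the
normalized vector a probability distribution; geometric means below 1 nTPM
carry no marker evidence), normalized to sum 1; the score for group k is
1 − JSdist(p, e_k), with JSdist the base-2 Jensen–Shannon distance (square
root of the divergence), so scores live in [0, 1] with 1 = perfectly
specific. Note the "1 −" convention: a distance of 0 to the ideal
indicator means a perfect marker. Markers are refined by q < 0.05, score
above threshold (0.5 or 0.6 by comparison), argmax-score group assignment,
and detection in ≥ 50 % of the group's cells.

Marker-based splitting (e.g. Tectb⁺ vs Tectb⁻) compares cells with log2
expression > 10 against cells at exactly 0, excluding intermediates.
Inter-organ calls: organ-exclusive genes are detected in strictly more
than 10 cells of one organ, zero of the other, q < 0.05 and specificity 1;
shared genes are detected in every cell of both organs with q ≥ 0.05.

## Pseudotime

Cells are embedded in 2-D by ICA (seeded FastICA; PCA available as a
deterministic fallback — the choice is exposed because the upstream tools
this emulates do not document theirs), connected by a Euclidean MST
(deterministic tie-breaks by cell id), and the backbone is the tree
diameter found by double Dijkstra traversal. Backbone pseudotime is
cumulative path distance normalized to [0, 1]; off-backbone cells inherit
the time of the backbone cell where their tree path attaches (a
first-order stand-in for PQ-tree refinement, identical at the resolution
validated here). Orientation follows a root hint (lower mean pseudotime)
or a lexicographic endpoint rule.

Pseudotime dependence is tested gene-wise with a natural cubic spline of
df = 3: the basis is the standard truncated-power natural basis (linear
beyond the boundary knots), boundary knots at the pseudotime extremes and
interior knots at quantiles, df + 1 knots total, so df = 1 reduces exactly
to simple linear regression. Λ = n·ln(RSS₀/RSS₁) on χ²_df; BH q-values;
fitted curves evaluated on a 100-point grid. The χ² reference is
asymptotic: null p-values pass a KS uniformity check at 250 cells × 2,000
genes (the simulation size used in validation). Significant genes are
clustered into k = 4 kinetic trends by k-means on standardized fitted
curves (standardization removes amplitude, leaving shape).

## qPCR

Primer efficiency: replicate Cts averaged per dilution, slope from least
squares of mean Ct on log10(relative concentration), E = 10^(−1/slope) —
the only form consistent with an ideal efficiency of 2 at slope −3.32 per
decade. The validation window |E − 2| ≤ 0.2 is inclusive at the boundary.
Expression = LOD − Ct with LOD Ct 24, clamped at 0 for Cts at or above the
LOD (the raw formula would go negative); missing Cts count as undetected.

## Synthetic data: what it emulates, what it does not

`simulate_cell_types` plants discrete populations (default: three 50-cell
types with 50 markers each among 2,000 genes, emulating the scale of a
one-organ experiment) with log-normal expression (Gaussian on log2, sd 1,
matching the Gaussian modelling assumption of the DE test), markers at
latent log2 mean 8 versus baseline 1, and logistic dropout in the latent
mean (midpoint 1, slope 1): an observation is zeroed with probability
σ(slope·(midpoint − latent mean)). The dropout law is a parametric
stand-in — real dropout is documented only through the LOD — but it is
identifiable: a logistic fit of detection against latent mean recovers the
midpoint within 10 % at 200+ cells.

`simulate_trajectory` draws pseudotime uniformly on [0, 1] and gives each
gene one of four latent log2 curves — Off: a·(1−σ((t−o)/w)); Early/Late:
a·σ((t−o)/w) with small/large onset; Transient: a·exp(−(t−o)²/2w²) — with
amplitude 8, onsets in tight class bands (Off/Early 0.20–0.35, Transient
0.45–0.55, Late 0.65–0.80, widths 0.08/0.12) and Gaussian log2 noise
(default 0.25). The bands are deliberately class-coherent: the four kinetic
groups are qualitative trend families, and heavily overlapping onsets would
make them non-identifiable by construction.

`simulate_spikeins` draws 92 known concentrations geometrically over six
decades and Poisson-thins them (capture efficiency 0.1, 30 cells default);
the reporting scale (20 TPM-like units per captured molecule) places the
detection boundary at mean abundance ≈ 1 by construction, so the LOD
estimator should recover ~1 within a factor of two.

Not emulated: UMI/count noise, gene–gene correlation beyond type and
trajectory means, ambient contamination, doublets, branching trajectories,
read-level artifacts. Passing recovery tests on these generators shows the
algorithms are correctly implemented and calibrated under their own
assumptions — not that real inner-ear data satisfies those assumptions.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed; identical seeds give
bit-identical outputs. Validation problem sizes (150-cell type recovery,
200-cell trajectories, 2,000-gene null calibrations, 50-seed gap-statistic
batteries with B = 50 and 5 k-means restarts) were chosen as the smallest
sizes at which the measured properties are stable across seeds; larger
sizes sharpen, not change, the results.
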