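# Methods

This note documents the statistical model behind each stage of hccpipe, the
parameters that matter, the design choices that were genuinely open, and
what the synthetic-data generators do and do not emulate.

## Count preprocessing

Raw gene-level read counts (genes × samples) are filtered to genes with at
least 10 reads summed over all samples ("less than 10" discards the gene, so
a row sum of exactly 10 survives). Counts then get a pseudo-count of 1 and a
log2 transform. Each sample column is shifted so its own median is 0.

Two interpretations of "library-size normalized to a global median of 0"
exist: a single global shift, or per-sample centering. Per-sample centering
is the only reading that makes samples with different library sizes
comparable, and it forces the pooled median toward 0 as well; it is the
implemented default and is idempotent. The log base is 2 throughout, chosen
for consistency with the fold-change selection rule, which is stated in
log2 units. Medians of even-length columns are midpoints of the two central
values (numpy's convention).

## Stage association

For each gene, a one-way fixed-effects ANOVA compares expression across the
tumor-stage groups T1/T2/T3. Cirrhosis samples and samples with
unassessable stage (TX/NA) are excluded from the test (cirrhosis can be
passed explicitly as a group for display purposes). F = MSB/MSW with
df (k−1, n−k); p is the upper tail. A group with fewer than two samples is
an error naming the group.

The effect size is the log2 "between-mean variance". That phrase has no
standard definition; it is implemented as the sample variance (ddof 1) of
the k group means, with the classical between-group mean square available
via `between_mean_square=True`. When the group means are identical the
effect is −∞, which can never pass the `> −3` filter.

Selection keeps genes with FDR < 0.25 and log2 between-mean variance > −3;
both inequalities strict, so boundary values are excluded. P-values are
adjusted with Benjamini–Hochberg (wrapping statsmodels; the step-up
definition is kept as an independent oracle in the test suite).

Selected genes are clustered by Ward's agglomerative method on the distance
1 − Pearson correlation, cut to exactly k clusters (default k = 3, matching
the three trend programs the analysis is designed to expose). Ward linkage
formally assumes Euclidean distances; it is applied to the correlation
distance deliberately, matching the clustering conventions of the analysis
this package reproduces, and behaves well in practice on these matrices.
Cluster labels are assigned by decreasing size with ties broken by the
smallest member id — labels are bookkeeping only, since each cluster's
biological identity is its trend verdict, not its number. Samples are
clustered with the same linkage on Euclidean distance.

A signature score is the per-sample mean of per-gene z-scores (gene
standardized across all scored samples, sd with ddof 1); scores therefore
average to 0 across the scored samples. Whether z-scores should be computed
over all samples or tumors only is an open choice; the default standardizes
over all samples in the scored matrix. The T-effector signature is the
score over GZMA, GZMB, PRF1, EOMES and CD8A (configurable). Trend verdicts
come from strict comparisons of consecutive group means along the given
order: `decreasing`, `increasing`, `up_then_down` (strictly up then
strictly down, with the peak interior), else `none`.

## Differential expression (exclusion signature)

Per gene, a two-sided two-sample t-test compares peri-tumoral against
intra-tumoral samples (phenotype-unknown samples excluded). The default is
the pooled-variance Student t — the plain reading of "t-test", and
consistent with the unpaired two-tailed t-tests used elsewhere in the
source analyses — with Welch available via `welch=True`. The effect is
mean(peri) − mean(intra) in log2 units, i.e. the log2 fold-change, since
the data are already log2. Identical constant groups yield t = 0, p = 1.

The exclusion gene set keeps genes with FDR < 0.125 and |log2FC| > 1
(strict), with an additional up-in-peri direction restriction on by
default: the published signature consists of genes up-regulated in the
T-cell-excluded (peri-tumoral) phenotype, while the stated filter is
two-sided. `direction=None` gives the plain two-sided selection.

## Enrichment

Over-representation of a query list in each gene set is tested one-sided by
the hypergeometric upper tail P(X ≥ overlap) over the expression universe
(equivalent to one-sided Fisher's exact); a classical two-sided Fisher test
is available behind a flag. The universe defaults to all genes surviving
the low-count filter. Query genes outside the universe are dropped with a
warning; sets with fewer than 2 genes in the universe are skipped with a
warning. BH adjustment runs across the tested sets; `significant` flags
adjusted p < 0.10.

## Cross-indication module refinement

Given a candidate gene set and several expression datasets ("indications"),
the Pearson correlation matrix of the candidates is computed within each
dataset, and the reference matrix is the cell-wise minimum across datasets:
a pair of genes scores high only if it is correlated in *every* indication.
Genes absent from any dataset are dropped with a warning before the
minimum; negative correlations are allowed to dominate it, as the formula
dictates.

The reference matrix is clustered with the same Ward / 1 − r conventions as
the trend clustering (the refinement itself does not prescribe a method;
reusing the pipeline's clustering conventions is the natural choice) and
cut at k = 2. The cluster with the largest internal median off-diagonal
reference correlation becomes module1 (the conserved module); everything
else is module2. A singleton's internal median is defined as −∞ so it is
never preferred unless all clusters are singletons; ties are broken by the
smallest member id with a warning. Per-dataset median pairwise correlations
of each module are reported, and a Wilcoxon rank-sum utility tests whether
a flagged sample subtype carries higher module scores (exact null
distribution when both groups have ≤10 samples).

## Phenotype classification

Samples are called peri-tumoral (positive class — the conserved module is
up-regulated in T-cell-excluded tumors) when their module signature score
exceeds a threshold, strictly; a score equal to the threshold is intra. The
threshold rule is this package's own: maximize Youden's J (sensitivity +
specificity − 1) over midpoints of consecutive sorted scores on a fitting
cohort, taking the lowest maximizing threshold, then freeze it for any
validation cohort. An alternative `cluster` mode splits the scores by 1-D
2-means and thresholds at the midpoint of the cluster centers. Sensitivity
and specificity follow the standard confusion-matrix definitions with peri
as positive.

## Histology quantification

Images are 8-bit RGB with a required microns-per-pixel scale. Fibrotic
clusters (aniline-blue collagen in a trichrome stain) are segmented by the
pixel score S = B − (R+G)/2 thresholded at 50, followed by morphological
closing then opening with a disk of radius 2 px and removal of 8-connected
components under 100 px. Tissue is the complement of near-white background
(all channels ≥ 240), closed with radius 2, so slide background and cavity
space are excluded from the denominator. Fibrosis is 100 · |fibrosis ∧
tissue| / |tissue|. A Sirius-Red preset reuses the same machinery with
score R − (G+B)/2.

CD8 cells are detected by the score R − B > 50 and an 8-connected component
size window of [5, 500] px, one centroid per component; the score function
matches the red-dominant rendering of the synthetic images and is the
configurable entry point for real micrographs. Each centroid's distance to
fibrosis is read from the Euclidean distance transform of the fibrosis-mask
complement at the rounded centroid pixel, scaled to µm; centroids inside
fibrosis get 0, and with no fibrosis at all every cell is infiltrated
(infinite-distance convention). Cells at distance ≤ 5 µm are trapped,
otherwise infiltrated — the boundary value itself, which the <5/>5 µm
phrasing leaves undefined, is assigned to trapped. The measured quantity is
the centroid distance, not the nearest cell-boundary pixel: simpler and
unambiguous. Per nodule, the report carries raw trapped/infiltrated counts,
counts per mm² of fibrosis area (the normalized rate; the exact published
normalization formula is ambiguous, so both raw fractions and
area-normalized rates are emitted), and the trapped fraction of all cells.

All thresholds, radii and size windows above are module defaults exposed as
parameters; none are prescribed by the source analyses.

## Synthetic data

`simulate_cohort` draws per-gene baseline log2 means uniformly from [3, 8],
adds trend-shaped group offsets for planted genes, adds per-sample
library-size offsets N(0, 0.2) in log2 units, and draws counts from a
negative binomial with mean 2^(log2 mean) and variance µ + 0.1·µ²
(dispersion parameterization; Poisson at dispersion 0). Default group
sizes are cirrhosis 30 and tumors 30/16/40 across T1/T2/T3, mirroring the
stage distribution of the motivating cohort at a desk-friendly scale; the
default plant is three 100-gene clusters with per-step effect 1 log2 unit
and shapes down / up-then-down / up across cirrhosis→T1→T2→T3.

`simulate_phenotypes` labels tumor samples peri/intra at a given fraction
(default 0.5) and adds a per-gene log2 shift drawn from [1, 2] to the peri
samples of n_deg planted genes (drawn from background genes where possible
so trend and phenotype plants stay disjoint), re-drawing the affected
counts from the shifted means.

`simulate_indications` uses a one-factor model: shared-module genes are
λ·f + √(1−λ²)·ε with a per-sample standard-normal factor f and unit-normal
noise, making the population within-module pairwise correlation exactly λ²
(0.7225 at the default λ = 0.85). A dataset-specific module uses a local
factor in the first dataset only and pure noise elsewhere — its reference
(minimum) correlation collapses to background, which is what the
refinement must reject. Background genes are independent noise.

`render_ihc` draws a light-pink tissue field inset in a white frame, blue
deposit disks and red cell disks, and computes ground-truth cell distances
analytically from the disk geometry (center-to-edge) before rasterization.
Pixel noise is N(0, 2) truncated at ±2 sd, which by construction cannot
move any pixel across the segmentation thresholds, keeping pixel-level
truth exact. Cells drawn over a deposit overwrite its pixels, so
mask-exactness checks use cell-free scenes.

What the generators do **not** emulate: viral-etiology and batch structure,
FFPE degradation, gene-length and GC biases, realistic gene-gene
correlation beyond the planted modules, stain variability, uneven
illumination, touching/overlapping nuclei. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not robustness to every artifact of real cohorts or slides.

## Numerical choices and scales

- Strict inequalities at every published cut-off (FDR, fold-change,
  between-mean variance, enrichment significance).
- Correlations are clipped to [−1, 1] against floating-point drift; the
  reference matrix is re-symmetrized and its diagonal pinned to 1.
- Zero-variance genes are errors (named) wherever a correlation or z-score
  is required.
- Cluster-label determinism: size-descending, then smallest member id.
- Problem sizes in the test suite and acceptance script (e.g. 2,000-gene
  cohorts, 100 simulation replicates, 200-sample indication panels,
  256-px images) are chosen so each check completes in seconds while
  keeping Monte-Carlo error far from the asserted margins.
- The pipeline's single seed fans out to stages by fixed offsets; reruns
  with the same config and inputs are byte-identical.
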