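# Methods

This note documents the models and numerical choices behind `tmekit`, in
the spirit of the methods appendices of statistical genetics packages: what
each procedure assumes, which knobs matter, and what the synthetic-data
tests do and do not demonstrate.

## Data model and normalization

Counts are sparse integer matrices, genes × cells (scRNA) or genes × beads
(spatial), with per-column metadata. Tissue fractions are `healthy`,
`adj_normal` (benign tissue adjacent to tumor) and `tumor`. Spatial beads
carry a dominant cell-type call and a decomposition confidence class;
only `singlet` and `doublet_certain` beads enter any analysis, `reject`
beads are excluded everywhere.

Depth normalization is linear: each column is scaled so its total equals
`scale_constant` (default 10,000). No log transform is applied by default
— signature scores are defined as plain means of expression magnitudes and
the ligand-receptor scores are products of magnitudes, both of which change
meaning under a log. A `log1p` option exists for users who want
variance-stabilized values for other purposes.

QC boundaries, all verified by test fixtures:

| rule | boundary |
|---|---|
| scRNA cell UMI filter | total ≥ 600 kept (“less than 600” removed) |
| spatial bead UMI filter | total ≥ 100 kept |
| doublet filter | score > 0.4 removed (strictly above) |
| pseudo-bulk inclusion | ≥ 10 cells of the type per sample |
| LR expression filter | detected in ≥ 10% of the type's cells (inclusive) |

## Signature scores and rank-sum comparisons

The score of a cell for a gene set is the arithmetic mean of its
depth-normalized expression over the set's genes present in the matrix
(absent genes dropped with a warning; zero overlap is an error). Sample
scores are exact means over member cells. Group comparisons use the
two-sided Wilcoxon rank-sum test: when both groups have ≤ 8 samples the
p-value is computed by full enumeration of all C(n₁+n₂, n₁) label
assignments on midranks (valid under ties); larger groups use the normal
approximation with tie and continuity corrections. The cutoff of 8 keeps
the largest enumeration at 12,870 assignments.

Inter-individual expression distance: per cell type, 1 − Pearson
correlation between two samples' mean normalized profiles (computed only
from sample × type combinations with ≥ 10 cells; flat profiles are
skipped because the correlation is undefined). Per sample pair the type
distances are averaged with weights equal to the pair's minimum cell count
per type — the weighting is our choice; no canonical definition exists for
“weighted expression distance”, so it is an exposed, documented default.

## Tumor-signature derivation

Marker ranking computes, per gene, the two-sided rank-sum p between
malignant and non-malignant luminal cells and converts it to a signed Z
(standard-normal quantile of p/2, sign of the mean difference; all-zero
genes get Z = 0). The signature keeps genes that are (i) upregulated with
Z **strictly** above 3 and (ii) detected (raw count > 0 — “expressed” has
no other defensible reading without a stated detection threshold) in
**strictly** fewer than 5% of all healthy epithelial cells, ordered by
descending Z. Cells are called malignant when their signature score
strictly exceeds the threshold (default 0.1). All three strict boundaries
are asserted by tests. On the constructed fixture (ten genes clearing
Z > 3, two of them too common in healthy epithelium) the derivation
returns exactly eight genes.

Bulk evaluation scores each sample as the unstandardized mean expression
of the signature genes (a per-gene z-score option exists) and computes AUC
as the Mann-Whitney concordance probability with ties counted ½, which a
test cross-checks against exhaustive pairwise enumeration and against
scikit-learn's ROC implementation.

## Spatial graph and Moran's I

The bead graph is the Euclidean kNN graph (default k = 10) with binary
weights, symmetrized by union; equidistant ties resolve toward the lower
bead index so construction is deterministic and order-independent.
Moran's I is the textbook statistic; with row-standardized weights (the
default) the n/ΣW prefactor is 1 and a perfect checkerboard on a rook grid
scores exactly −1. Absolute values depend on the weighting scheme, so
analyses should compare orderings (clustered vs dispersed, condition vs
condition) rather than absolute magnitudes. Cell-type autocorrelation uses
the binary membership indicator over confident beads — not decomposition
weights, which are not always available.

Context segmentation automates what is usually drawn by hand: per bead,
the share of tumor-annotated beads within `smoothing_hops` graph hops
(self-inclusive) is compared to `density_threshold` (default 0.3,
inclusive); beads at or above it form the tumor context, the remainder the
adjacent context. On half-plane simulations the recovered boundary matches
the true domain boundary for ≥ 95% of beads outside a one-spacing band.

## Admixture correction

The central interpretive choice of the pipeline. A target type's
pseudo-bulk y (summed counts over its beads in one unit, scaled to sum 1)
is modeled as a non-negative mixture of pure-type reference profiles P
(columns scaled to sum 1, the target's own profile included):

    min_{w ≥ 0} ‖ y − P w ‖₂ ,   solved by NNLS, no intercept,
    weight estimation in proportion space, subtraction in count space.

Robustness: genes whose relative residual (residual / fitted, with a small
floor) exceeds 4 MADs are trimmed and the weights refit (≤ 3 rounds).
This matters because genuinely regulated genes are exactly the ones the
mixture cannot explain; leaving them in drags the weights and turns real
regulation into apparent contamination. Corrected counts subtract the
contaminant component using the **raw** NNLS coefficients — the
sum-to-one-normalized weights would over-subtract whenever trimmed genes
inflate the observed total — and are floored at 0 and rounded so count
models apply downstream. Reported weights are normalized to sum 1 for
interpretation. An ill-conditioned design (condition number > 1e8, e.g.
duplicate reference columns) triggers a warning and a ridge-regularized
fallback, flagged on the fit.

Reference profiles come from the caller (in practice: annotated scRNA
pseudo-bulk means; in tests: the generator's true profiles).

## Pseudo-bulk differential expression

A self-contained negative-binomial test, judged by calibration and power
rather than by matching any external implementation:

* effective library sizes by the median-of-ratios method (robust to a
  minority of genuinely changing genes; raw totals would convert a
  one-sided planted shift into spurious global down-regulation),
* per-group abundance as the pooled proportion with a half-count
  continuity term,
* per-gene dispersion by moment matching of within-group residual
  variance (Var = m + φm²), shrunk toward the count-weighted common
  dispersion with 20 prior degrees of freedom,
* a Wald statistic on the log fold change referred to a t distribution
  with (replicate df + prior df) degrees of freedom — near-normal at the
  5% level, with the heavier far tail the estimated variance actually
  has, which is what BH thresholds probe,
* Benjamini-Hochberg adjustment.

Measured on null simulations: type-I error 0.039–0.051 at α = 0.05 across
homogeneous and heterogeneous dispersion regimes; p-values pass a KS
uniformity check. Replicates are pucks where available; a single puck is
split into four spatial quadrant tiles per context (`tile_units`), a
documented fallback that treats tiles as exchangeable replicates and
therefore understates between-puck variability.

The scRNA fraction comparison (`fraction_de`) uses the same engine on
per-sample pseudo-bulks, excluding samples with fewer than 10 cells of the
type.

## Ligand-receptor screening

Non-spatial: S = mean ligand expression over sender-type cells × mean
receptor expression over receiver-type cells, both genes required to pass
the 10% detection filter in their respective types. Spatial: the
antisymmetric score on the kNN graph given in the README; the subtracted
reverse term cancels signal that is symmetric in the two genes — exactly
the signature of bead admixture. Both nulls shuffle type labels (cluster
labels over cells; bead labels over positions, expression staying with
beads), with defaults of 1,000 and 2,000 rounds and a one-sided
upper-tail p with the +1 pseudo-count, so p ≥ 1/(n_perm+1). The screen
shares one label permutation per round across all (pair, type-pair) rows,
making the cost independent of the number of pairs, and BH-adjusts across
all tested rows. Sidedness is our choice (positive S = directional
co-expression in neighbors); the 10% filter is applied in spatial mode
too, on bead-level detection per annotated type. Self-pairs (A → A) are
skipped in spatial mode because S is identically zero by antisymmetry.

## Synthetic-data generator

Counts are NB with mean m and dispersion φ (variance m + φm²; φ = 0 is
Poisson; default φ = 0.3 per gene). Cell-type profiles share a lognormal
per-gene baseline; each type's markers are multiplied by `marker_fold` in
the owning type only, and `marker_background` optionally scales them down
in non-owning types (near-silent markers are the regime the
healthy-expression exclusion filter expects). Cohort composition may be
given per fraction, e.g. no malignant cells in healthy tissue. Planted effects multiply the affected genes but the
expected library is scaled by the *unmodified* profile total, so
up-regulation adds transcripts (inflating that cell's library) instead of
compressing every other gene — under the compressive alternative every
unplanted gene becomes genuinely differentially expressed and the planted
truth would be wrong.

Pucks place beads on a jittered hexagonal grid (default 20 µm pitch over
600 × 600 µm, ~1,050 beads; a Poisson layout is available). Each bead's
expectation is `self_weight` (default 0.7) times its own cell's profile
plus the remaining mass spread over neighbors with a Gaussian distance
kernel (bandwidth 30 µm, truncated at 3 bandwidths); the realized per-bead
mixing weights, aggregated by contributing type, are recorded as truth.
No published admixture rate exists for the platform, so 0.7 is a knob,
not a claim. Planted LR pairs boost the ligand in sender-type beads with
a receiver-type bead within one bandwidth and the receptor in those
receivers (strength 4 by default) — precisely the adjacency-coupled
signal the spatial score is built to detect. Bulk cohorts are
composition-weighted sums of normalized profiles times per-(gene, sample)
lognormal noise.

What the generator does **not** emulate: transcriptome-wide gene-gene
correlation, cell-cycle structure, segmentation errors, platform-specific
capture biases, or spatial noise beyond NB + admixture. Passing tests
demonstrate internal correctness and statistical calibration under the
stated model, not performance on real tissue.

## Validation battery and problem sizes

`tmekit.validation` (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs: oracle equivalence of the sparse spatial
score on 200 random pucks of ≤ 300 beads; exact sign-flip identities on
1,000 instances; type-I error of both LR permutation tests over 2,000
null rounds (199 permutations each) and of the NB test over 200 null
rounds; planted-LR detection over 50 pucks (10 planted + 90 decoy pairs,
999 permutations); the admixture confound and planted-effect studies over
8 pucks each (400-gene panels, 50 planted genes at 4-fold); deconvolution
recovery over 100 NB pseudo-bulk fits at 10⁵ total counts (modeled as
sums over 100 beads, so per-bead overdispersion averages out);
Moran's I closed forms and 100 clustered-vs-dispersed pairs; the
8-gene signature fixture; exhaustive AUC and rank-sum enumerations. These
sizes keep the full battery under a few minutes on one CPU while leaving
the Monte-Carlo standard errors well inside the asserted bands.

## Known limitations

* The admixture correction assumes the reference profiles span the true
  contaminant space; unmodeled cell states load onto the nearest column.
* Quadrant tiles are pseudo-replicates; real multi-puck designs should
  pass pucks as replicates.
* Moran's I magnitudes are weighting-dependent; only orderings are
  asserted.
* The LR screen treats pairs as single ligand gene × single receptor gene;
  multi-subunit complexes are out of scope.
* Exact rank-sum enumeration is limited to groups of ≤ 8; beyond that the
  corrected normal approximation is used.
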