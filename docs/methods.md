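# Methods

This note documents the models, defaults, and design choices behind
`mifpipe`, and what the synthetic cohorts do and do not emulate.

## Synthetic cohorts

`generate_cohort` emulates a 12-patient anti-PD1 melanoma cohort
profiled by cyclic multiplex immunofluorescence: 6 responder (R) and 6
non-responder (NR) samples, 2,000 cells each by default, in a
1,000 × 1,000 μm field (image convention: origin top-left, y downward,
all distances Euclidean in μm).

**Phenotypes.** Cell counts per sample are a multinomial draw over
{Melanoma 0.50, BloodVessel 0.20, Thelper 0.15, CytotoxicT 0.15} —
melanoma-dominant with a substantial vascular and T-cell compartment, a
realistic mix for melanoma metastases.  A configuration whose smallest
expected class is below one cell is rejected ("empty phenotype").

**Marker model.** Each marker is "on" for the phenotypes it defines
(Melanoma: SOX10, MelanA; BloodVessel: AQP1, CD31; Thelper: CD4;
CytotoxicT: CD8) and "off" otherwise.  MFI = `loc · exp(N(0, scale)) +
N(0, noise_sd)`, floored at 0; `loc` is the natural-unit median (on 10,
off 1 by default, scale 0.25, noise_sd 0.5).  The multiplicative
log-normal term reproduces the right-skew of immunofluorescence
intensities; the additive term models detector noise.  Two helper
configs pin the regimes used in validation: `zero_noise_config()`
(scale = noise_sd = 0, MFIs exactly equal their locations) and
`separation_config(n_sd)` (scale = 0, noise_sd = (on−off)/n_sd, so the
on/off separation is exactly `n_sd` noise-sds; 4 sd is the "moderate
noise" validation condition).

**Functional markers.** VCAM1/STING (vessels) and PD1/GrzB (T cells)
use the same on/off machinery, driven by per-cell ground-truth flags:
30% of ECs are inflamed (VCAM1⁺), half of those STING⁺; 30% of CD8
cells each PD1⁺ and GrzB⁺.  These fractions are conventions — no public
distributional description of the real data exists — chosen so that
positive populations are minorities but large enough to analyze.

**Planted proximity.** With probability π(group) a CD8 cell is placed
at a uniformly chosen inflamed EC plus isotropic Gaussian noise of sd
15 μm (clipped to the field), else uniformly.  Defaults π_R = 0.4,
π_NR = 0 plant the responder-only vessel–T-cell association; setting
π_R = π_NR gives the null used for calibration.

**Compartments.** Each sample's region set is three vertical bands
(bulk | interface | non-tumoral) — the simplest partition exercising
point-in-polygon logic; arbitrary polygons are accepted.

**Randomness.** All draws flow from one integer seed through a
name-keyed stream splitter (CRC32 of "sample/<id>" etc. into a
`SeedSequence`), so adding samples never perturbs earlier ones and
every output is bit-reproducible.

**What is not emulated:** pixel-level image formation, segmentation
errors, marker spillover/autofluorescence, spatial dependence of
intensity, within-sample batch structure, cell shapes.  Passing tests
demonstrate that the algorithms recover signals of the planted form;
they do not certify performance on real staining artifacts.

`generate_expression` draws gamma-Poisson (negative binomial) counts
with log-normal per-gene base means (dispersion 0.3); designated "EC"
cells have signature-gene means multiplied by the enrichment factor.
`generate_count_experiment` builds two-group panels with a planted
log2FC on a random gene subset and ±20% library-size jitter; at
dispersion 0 it emits exact float means so closed-form checks apply.

## Normalization

Z-scores per marker within each sample, sample sd (ddof = 1), trimmed
to [−5, 5].  A constant channel yields all-zero scores with a warning
rather than an error: flat background channels occur in practice and
must not kill a run.  Fewer than 2 cells is an error.  Normalization is
within-sample only — no cross-sample batch correction.  Trimming makes
the transform non-idempotent, which the tests assert explicitly to
guard against accidental double normalization.

## Consensus phenotyping

Clustering uses only the six lineage markers; functional markers are
reserved for positivity calls.  The stratified sample (default 2,500
cells, proportional per sample, largest-remainder rounding, no
replacement) feeds three methods:

- **Graph**: Euclidean kNN graph (k = 20), edges weighted by the
  Jaccard overlap of neighbor sets, Louvain modularity maximization
  (seeded).  All-identical input returns a single cluster.
- **SOM**: a batch-trained 8 × 8 rectangular self-organizing map
  (Gaussian neighborhood shrinking geometrically over 20 epochs, nodes
  initialized from data points), whose node weights are Ward-linked
  into the requested number of meta-clusters; cells inherit their
  best-matching node's meta-cluster.
- **k-means**: k-means++ with 10 restarts, seeded.

The SOM and k-means receive exactly the community count found by the
graph method.  Each method's clusters are annotated automatically: a
phenotype's score for a cluster is the maximum cluster-mean z over its
defining markers (OR logic); the cluster takes the argmax phenotype if
that score ≥ τ (default 0.5 z), with ties and sub-threshold scores
giving NOS.  The automated rule replaces expert manual annotation, which
is not reproducible in software.  The consensus is the modal label when
its multiplicity is ≥ 2, else NOS; NOS counts as a vote value.

## Label propagation

Up to 500 labeled cells per phenotype (NOS excluded by default,
configurable) form the reference.  The default 2D map is a supervised
deterministic linear projection: linear-discriminant axes (≤ 3 for four
classes) followed, when three axes exist, by the 2D plane that retains
the largest minimum pairwise class-mean separation, found by scanning a
fixed 4,000-point Fibonacci sphere of candidate plane normals.  The
reason is geometric: four phenotype means span three dimensions, so any
unsupervised 2D linear projection (e.g. PCA) collapses one contrast —
in this panel the CD4/CD8 distinction — while stochastic neighbor
embeddings break down on the duplicate-heavy zero-noise regime.  The
discriminant map is deterministic, has an exact out-of-sample
transform, and keeps all four classes separated.  PCA and UMAP remain
available behind the same transform contract.

Every cell is projected and receives the modal label of its k = 100
nearest reference cells (Euclidean in embedding space); only reference
cells vote, because only they carry labels.  Label ties are broken by
the nearest tied label — deterministic and distance-respecting.  If the
reference is smaller than k, k is lowered with a warning.

## Spatial analysis

Point-in-polygon uses the boundary-inclusive covering test; a cell in
polygons of several compartments takes interface > tumoral bulk >
non-tumoral precedence; self-intersecting polygons are rejected.
Functional positivity is `z ≥ cutoff` (default 1.0 z, boundary
inclusive) restricted to the marker's applicable base phenotype; the
cutoff value is a convention and should be set explicitly in any
headline configuration.  Per-compartment R-vs-NR abundance uses
two-sided Wilcoxon rank-sum tests (exact when sample sizes permit),
deliberately unadjusted for multiple comparisons, matching the
exploratory design.

Neighborhood curves use the cumulative convention: value at radius r =
mean over reference cells of the number of target cells at distance
≤ r (KD-tree pair counting).  Cumulative counts are monotone, stable,
and Ripley-K-like; a per-bin mode exists behind a flag.  The default
radius grid is 0–300 μm in 10 μm steps.  Curves are compared across
groups per radius with two-sided equal-variance t-tests on per-sample
values (one value per sample = core; per-patient aggregation is the
caller's choice of grouping).  Degenerate radii with zero variance in
both groups give p = 1 on equal means and p = 0 on unequal means.  Edge
effects are not corrected (no Ripley correction) — curves near the
field border underestimate true neighbor counts equally in both groups.

## Signature scoring

The DE surrogate is intentionally simple: total-count normalization to
the mean library size, log2(x+1) (pseudocount 1), per-gene two-sided
Welch t-test; log2FC is the difference of group means on the log scale.
Genes all-zero in both groups report (0, 1); zero-variance genes follow
the same degenerate rule as the curves.  The signature rule —
log2FC ≥ 0.7 (inclusive) AND p < 0.05 (strict), ordered by descending
fold change — is applied verbatim; an empty selection returns an empty
gene set with a warning.

The per-cell score ranks genes by descending expression (ties broken by
gene order in the matrix — documented because the area is
tie-sensitive), counts gene-set members along the top
L = ceil(0.05 · n_genes) ranks, and divides the recovery-curve area by
the maximal rectangle L · m (m = set size in the universe, capped at
L).  A set occupying the top ranks scores 1 − (m−1)/(2L); a set
entirely below rank L scores 0.  Being rank-based, scores are invariant
to monotone transforms of a cell's expression.  ECs are selected at
score > 0.1 (strict).  Signature correlations are Spearman
(tie-corrected) on per-sample values, default the mean score over each
sample's selected ECs; constant vectors report NaN with a warning.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 12 × 2,000-cell cohorts
for end-to-end recovery (≥ 99% zero noise, ≥ 95% at 4-sd separation
observed ≈ 99.5%); 20 cohorts of 12 × 1,000 cells for proximity
detection; 500 null cohorts of 12 × 200 cells for type-I calibration of
the per-radius t-test (observed ≈ 0.04–0.05); 1,000-gene 6-vs-6 panels
for DE recovery; 1,000 × 1,000 and 2,400 × 400 expression matrices for
EC-selection and signature-correlation recovery.  Exhaustive or
brute-force oracles cover the vote rule (125 triples), kNN majority
(200 instances), neighborhood curves (100 instances), and the recovery
AUC (500 instances).

## Known limitations

- No image-level preprocessing: the cell table is the trusted input.
- No edge correction in neighborhood curves; no permutation nulls.
- The DE surrogate is not a negative-binomial GLM; with 6 vs 6 samples
  it is adequate for threshold-rule recovery but underpowered for
  subtle fold changes.
- The SOM is a minimal batch implementation (fixed grid, Ward
  meta-clustering); it satisfies the consensus contract but is not a
  feature-complete FlowSOM replacement.
- Synthetic marker parameters are conventions, not estimates from real
  staining data.
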