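# Methods

This note documents the statistical model behind `orgspatial`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical edge cases.

## Data model and quality control

A `SpatialDataset` is a cells × genes integer count matrix (sparse CSR)
aligned with per-cell centroids in micrometres, a section (sample) ID and
a condition label. Coordinates are taken as already in μm with arbitrary
origin; no pixel conversion or segmentation handling is attempted.
Operations never mutate datasets; every transform returns a new object.

Spatial QC keeps cells with **more than** 15 genes detected and **more
than** 20 total transcripts — both strict inequalities, both
configurable. Imaging panels are shallow (tens of counts per cell over
~10³ probes), so the filter is deliberately relaxed compared to
whole-transcriptome scRNA QC, which here uses 500–10,000 genes detected
(inclusive), 1,000–15,000 total counts (inclusive) and mitochondrial
fraction strictly below 10% (genes matched by the `MT-` prefix; if no
gene matches, the mitochondrial filter passes through with a warning).
"Genes detected" counts distinct genes with ≥ 1 transcript; if the
instrument reports several probes per gene these are assumed already
collapsed to gene level.

Normalization is library-size scaling to 10,000 followed by natural
log1p, with the per-cell total taken over **all** panel genes. The scale
factor is the de facto single-cell standard; it is recorded in the run
manifest. Cells with zero total are an error (run QC first).

## Exclusive marker typing

Cell type *T* is assigned iff the cell has at least one marker of *T* at
raw count ≥ `expressed_min_count` (default 1) and zero expressed markers
of every other type; otherwise the cell is `undefined`. The rule uses raw
counts, not normalized values: at imaging-panel depth a single transcript
is already informative, and a normalized threshold would couple the call
to library size. Marker sets must be pairwise disjoint; markers absent
from the dataset are dropped with a warning.

Note a non-obvious property of the exclusion rule: raising
`expressed_min_count` is **not** monotone on labels. A cell with VIM = 2
and EOMES = 1 is `undefined` at threshold 1 (two types expressed) but
becomes NPC at threshold 2 (the competing type's veto falls away). What
is monotone is each type's "expresses a marker" set, and that is what the
tests assert.

Undefined cells are retained: they count as neighbors in the density
metric and form their own group in expression tests.

## Spatial statistics

**Distances.** For a pair of types, all |A|×|B| Euclidean distances are
computed within each section, then concatenated across the sections of a
condition. Same-type distances are available behind an explicit flag and
exclude self-pairs and duplicates. Conditions are compared with the
two-sample KS test; the exact small-sample null is used when
n₁·n₂ ≤ 10,000, the asymptotic Kolmogorov distribution otherwise.

**Neighborhood metric.** `n(c)` counts cells of any type within radius
`r` (default 100 μm, boundary inclusive — conventional, and documented
here since either choice is defensible) in the same section, excluding
the cell itself. A KD-tree does the counting; an O(N²) all-pairs path is
kept as an oracle and the two are asserted identical. Density classes:
`n = 1` sparse, `n ≥ 5` dense, otherwise intermediate (including
`n = 0`: an isolated cell is not "in a sparse cluster" — it has no
cluster at all). Both bounds are configurable.

**Density–expression association.** Within each cell-type group (≥ 3
cells), each gene's normalized expression is regressed on `n` by OLS
(hand-vectorized across genes; verified against `statsmodels.OLS`), with
a two-sided t-test on the slope, df = m − 2. Zero variance in `n` yields
all p = 1 with a warning; a perfect noise-free fit yields p = 0; constant
genes yield slope 0, p = 1. The logistic variant drops intermediate
cells, codes dense = 1 / sparse = 0, and fits class ~ expression per gene
(statsmodels `Logit`, Wald test), requiring ≥ 2 cells per class. Complete
separation — detectable a priori when the two classes occupy disjoint
expression ranges, or via non-convergence — is flagged per gene and
reported as NaN, which the BH step skips. BH adjustment is applied across
genes *within* each (group × test family).

## Differential expression and composition

Wilcoxon rank-sum (two-sided) per gene between conditions within each
group, on normalized expression. The tie-corrected normal approximation
is the default; for small comparisons (n_A·n_B ≤ 200) with no ties the
exact null distribution is used instead. All-tied genes get p = 1. The
effect size is the Seurat-style average log2 fold change with a
pseudocount of 1 on de-logged means. Selection presets:

| preset | padj | |log2FC| floor | intended data |
|---|---|---|---|
| `spatial_nofc` | < 0.05 | 0 | imaging panel (default) |
| `findmarkers_026` | < 0.05 | 0.26 | split-pool scRNA |
| `seurat_fc15` | < 0.01 | log₂1.5 | legacy fold-change convention |

Two conventions ship because both are in circulation for the same kind of
comparison; the pipeline default is the imaging-panel one.

Composition: Pearson χ² without continuity correction on the raw
cell-type × condition count table (raw counts, not rescaled proportions),
df = (r−1)(c−1), zero-margin rows/columns dropped with a warning;
per-type 2×2 tests (type vs all others) are BH-adjusted across types.

## Assay quantitation

2^−ΔΔCt: ΔCt = Ct_target − Ct_reference per condition, ΔΔCt =
ΔCt_treated − ΔCt_control, fold change 2^−ΔΔCt. Replicates are averaged
on the ΔCt (log) scale, and spread reported as the SD of per-replicate
ΔCt. Deiodinase activity: net converted fraction =
product/total − background (floored at 0, background measured from a
no-cells assay), activity = net fraction × substrate / (protein ×
duration), i.e. fmol·mg⁻¹·h⁻¹ for fmol substrate and hours. Units are
carried explicitly and never auto-converted between fmol and pmol.

## Synthetic data generator

Each section is a homogeneous Poisson background (intensity 2.5×10⁻⁵
cells/μm² over 1.5 × 1.5 mm) plus 3 Thomas-process clusters (uniform
parents, Poisson(13) offspring, isotropic Gaussian scatter σ = 40 μm).
These intensities were calibrated, once, so that the two density classes
the analysis dichotomizes are both well populated — sparse ≈ 15–25% and
dense ≈ 30–50% of cells over replicate seeds — since a generator that
produced only one regime could not exercise the sparse/dense tests. Two
conditions × two sections give ~400 cells at default settings.

Cell types are drawn per condition from configurable proportions; the
default plants a composition shift (fewer neurons in the MCT8-deficient
condition). Counts are negative binomial (variance μ + μ²/k, dispersion
k = 2) with a three-tier mean structure: markers of the cell's own type
at mean 4, markers of *other* types at 0.01, all remaining genes at 0.6.
The low off-type tier reflects what marker panels are for — probes chosen
precisely because they are type-exclusive; with a single shared
background mean the exclusion rule would spuriously un-label ~25% of
cells, which is a property of a badly chosen panel, not of the assignment
rule under study.

Planted condition effects multiply the mean by 2^(log2FC) in one
condition. Planted density effects multiply by 2^(δ·n(c)); the affected
genes default to mid-abundance mean 5.0. That default matters: under
log1p library-size normalization, a count-scale density effect appears in
expression space amplified for low-abundance genes (the zero fraction
responds steeply to the mean) and attenuated for high-abundance ones (the
gene's own growth inflates the cell total it is divided by). At
mid-abundance the two distortions approximately cancel and the
expression-scale slope is close to δ·ln 2, which makes the planted δ a
meaningful recovery target. Recovery is assessed as: mean estimated slope
over replicate seeds within twice the average per-seed regression
standard error of δ·ln 2 — i.e. the truth sits inside the estimator's own
confidence band; an exactly unbiased estimate is not attainable on
log-normalized counts, for the compositional reasons above.

Replicated experiments derive their seeds by `SeedSequence` hashing
(`spawn_seeds`), not consecutive integers: consecutive-integer seeding
leaves small cross-seed correlations, measurable as a spurious ~−2.8 z
on an exactly unbiased slope over 4,000 replicates.

What the generator does **not** emulate: segmentation errors,
probe-specific sensitivity, spatial expression gradients other than the
planted density effect, spatially correlated cell-type placement (types
are drawn independently of position), doublets, and ambient counts.
Passing tests therefore demonstrate correctness of the statistics under
the assumed NB/point-process model, not robustness to those artifacts.

## Problem sizes and determinism

The reference fixture is ~400 cells × 60 genes; calibration and recovery
studies use 50–100 replicate seeds at that scale, and the null
calibration uses ~500 cells × 200 genes per seed — sizes at which every
quantity of interest (type-I fraction, recovery bias) is measured with
standard errors far below the decision thresholds, while the full suite
runs in seconds. Null-calibration fractions are computed over
non-degenerate tests only: a gene constant within a comparison group has
p = 1 identically and no sampling distribution, so it carries no
information about calibration.

The pipeline writes plain CSV tables plus a manifest with per-table
SHA-256 digests; identical config + seed reproduces tables byte-for-byte
(floats are written with round-trippable repr and read back with
`float_precision="round_trip"`).

## Known limitations

- The exclusion rule ignores expression magnitude beyond the threshold;
  a cell with 50 VIM counts and 1 EOMES count is `undefined`.
- Logistic association at realistic sparse/dense group sizes (~30 cells)
  is conservative (small-sample Wald); its p-values are reported but the
  linear test is the better-calibrated instrument at this scale.
- Distance aggregation concatenates sections within a condition without
  weighting, so a section with more cells dominates the pooled ECDF.
- χ² composition tests treat cells as independent, ignoring
  within-section correlation; with two sections per condition this
  overstates confidence when sections differ systematically.
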