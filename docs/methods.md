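# Methods

`rockisc` implements the computational analysis behind a reversibility
question: does a short (six-day) treatment of cultured primary human
keratinocytes with the Rho-associated kinase inhibitor Y-27632 permanently
change the population's composition and differentiation behaviour, or do all
changes revert once the inhibitor is withdrawn?  The study design has four
arms — an untreated control (Control-6D⁻), a treated culture (ROCKi-6D⁺),
and both cultures after six further days without treatment
(Control-6D⁻6D⁻, ROCKi-6D⁺6D⁻) — each profiled by droplet single-cell
RNA-seq across three donors, plus colony-formation assays quantified from
stained plate scans.

## The synthetic study

Because the deposited data require per-sample QC thresholds that are not
published, every stage of the package is exercised on a synthetic study with
known ground truth (`rockisc.syndata`).  The generator's defaults *are* the
study conditions; they are not tuned per test.

**Model.**  Each keratinocyte carries a latent differentiation coordinate
("true pseudotime") in [0, 1]; two fixed cut points (0.33, 0.66) map it to
the holoclone-forming / clonogenic (transient-amplifying) / terminally
differentiated stages, so type proportions and pseudotime are mutually
consistent by construction.  Counts are negative binomial with dispersion
θ = 10 and a log2-scale mean built from:

* a gene baseline drawn log-normally (centred at 1 count/cell, SD 1 log2
  unit; signature genes fixed at 1 count/cell);
* +`marker_logfc` (default 2, log2) for the published signature genes of the
  cell's own stage — holoclone (ANLN, AURKB, CCNA2, CKAP2L, FOXM1, HMGB2,
  LMNB1), clonogenic (KRT14, TP63, ITGA6, ITGB1, BIRC5) and differentiated
  (SERPINB3, SFN, KRT10, TGM1, IVL, SPINK5);
* 40 gradient genes whose log-mean varies smoothly (±1.5 log2 units) with
  pseudotime, making the differentiation axis continuous — without them a
  three-level type indicator alone cannot support within-stage pseudotime
  ordering;
* a cell-cycle program: 30% of cells activate either the S or the G2M gene
  list (+1 log2) — the standard human lists ship as editable text fixtures,
  with signature genes excluded from the boosted sets so marker and cycle
  structure stay separable;
* an additive per-donor gene shift (SD 0.2 log2, three donors, shared across
  arms) and a log-normal per-cell depth factor (σ = 0.3).

**Treatment and reversibility.**  The treated arm draws pseudotime from the
control distribution shifted by +0.2 and clamped to 1; both withdrawal arms
use shift 0.  Reversibility is therefore built in, and every downstream
"treatment > withdrawal" result is a recovery test, not an assumption.
5% of cells are contaminants (melanocytes expressing MLANA/PMEL/MITF;
fibroblast-like cells expressing the eight mesenchymal markers plus VIM, at
~6 counts expected each) with undefined pseudotime.

**What the generator does not emulate:** ambient RNA, doublets, read-level
noise, gene–gene correlation beyond the programmed structure, or donor
effects that interact with treatment.  Passing tests show the pipeline
recovers effects of this form and size; they do not certify performance on
tissues or chemistries the model omits.

## Single-cell pipeline

**QC** (fixed order): genes in <3 cells and cells with <200 detected genes
are dropped; per-sample bounds on detected genes, total counts and percent
mitochondrial counts (genes with the `MT-` prefix) are user configuration,
since "anomalous" cannot be derived from published information — a MAD-based
suggestion helper exists but is never applied silently.  Cells with ≥2
counts ("more than one") of any melanocyte or mesenchymal marker are then
excluded; the boundary is exposed as `min_count`.

**Normalization.**  Analytic Pearson residuals of an offset
negative-binomial model: μ_gc = depth_c · gene_total_g / grand_total,
r_gc = (x − μ)/√(μ + μ²/θ) with fixed θ = 100, clipped to ±√n_cells.  This
keeps the variance-stabilising core of regularized NB-regression
normalization while remaining analytically testable (a model-exact gene has
residual 0; null simulations centre at 0).

**Cell cycle.**  S and G2M module scores (mean expression over the set
minus bin-matched control genes, 25 bins, 50 controls per gene) are computed
on log-normalized counts; the S−G2M difference is regressed out of the
residuals per gene by OLS — a projection, hence idempotent and
variance-non-increasing.  Scoring on log counts and regressing residuals is
a deliberate resolution of an ambiguity in the original description.

**Dimensionality reduction and donors.**  Top-HVGs by residual variance
(ties broken lexicographically for determinism), centered PCA, then donor
integration in PC space: iterated soft k-means with per-cluster, per-donor
centroid offsets subtracted under soft weights (the mixture-correction core
of Harmony-style integration, without its diversity penalty), or a plain
per-donor recentering (`global_center`).  The tested contract is donor
mixing restored and cell-type geometry preserved.  With zero donor effect
the correction is bounded by donor-centroid sampling noise (O(σ/√n)), so
"no change" is asserted relative to the embedding scale, not absolutely.

**Cell typing.**  A semi-supervised EM over signature genes: each marker is
a two-component Gaussian (elevated in the owning type, background
elsewhere) with the elevated mean constrained ≥ background; cell posteriors
are the E-step.  After convergence, genes whose elevated/background
separation is below 0.8 pooled SDs are deemed uninformative and dropped
from the final posterior — without this, EM fitted to pure noise yields
confidently wrong labels; with it, signal-free data produce near-uniform
posteriors and cells fall below the 0.5 posterior cutoff into "unknown".
The printed marker symbol ITB1 is mapped to ITGB1 at panel-matching time.
Proportions are computed over assigned cells only.

**Differential abundance.**  For each cell of a pair, at each neighborhood
size k (default 50…500, capped at n−1), the imbalance
(f_B − f_A)/(f_B + f_A) of its k nearest neighbors with counts weighted
inversely to label totals; the per-cell score is the mean over k (the per-k
vector is retained).  A pooled permutation null gives (α/2, 1−α/2) score
thresholds; the overlap is the fraction of the focal (treated) sample's
cells inside the band.  The mean over k replaces a logistic-regression
summary: it preserves exact label-swap antisymmetry and calibrates cleanly.

**Trajectory.**  k-means (k = 3) on the integrated embedding of a combined
pair; the cluster richest in holoclone-assigned cells starts the lineage; an
MST over centroids fixes the cluster order (from an internal start both
branches are reported, longest last).  A principal curve initialized on the
centroid path is refined by projecting cells to the curve and smoothing the
cell cloud ordered by arc length (uniform window, default 10% of cells,
forced odd for direction symmetry); the curve is linearly extrapolated past
both ends so boundary cells spread along a tangent instead of piling onto
the endpoints.  Pseudotime is arc length anchored at the holoclone end,
reported raw and normalized by total curve length.  Fitting both samples on
one curve makes the two pseudotime distributions directly comparable.
Numerical notes: the curve length stabilizes rather than decreasing
monotonically, and lineage reversal mirrors pseudotime to ~1% (the
projection/sort/smooth loop amplifies floating-point-level ordering ties).

**Comparison statistics.**  T = Σ_t |π_A(t) − π_B(t)| over the three types;
D = mean over the percentile grid 0.1, 0.2, …, 100.0 of |q_A(p) − q_B(p)|
with linear-interpolation quantiles.  Percentile bootstrap CIs (default
1000 draws) resample cells with replacement within each sample; degenerate
draws are redrawn and counted.  The treatment/withdrawal ratio
R = D_treat/D_withdraw takes its CI from index-paired ratios of the two
bootstrap vectors; zero-denominator draws flag the result and push the CI
upper bound to infinity.  The CI lower bound supports "at least k-fold"
statements; both the point ratio and the bound are reported.
Differential expression is a two-sided Wilcoxon rank-sum (normal
approximation, tie and continuity corrected) on log-normalized expression,
BH-adjusted, with genes called up/down at adjusted p < 0.05 and
|log2 FC| > 1, where the fold change compares group means of de-logged
expression (ε = 10⁻⁹); no minimum-expression prefilter is applied.

## Colony assay

Plate scans (8-bit grayscale, known DPI; px/mm = DPI/25.4) are segmented by
median filter (radius 2 px) → global IsoData (intermeans) threshold keeping
the dark class (Otsu available by flag) → binary hole filling →
distance-transform watershed (Gaussian-smoothed distance, peak separation
0.5 mm) → connected components.  A guard rejects thresholds whose
foreground/background contrast is under 25 gray levels, so pure background
noise yields zero colonies.  The "adaptive median filter (r = 2)" of the
original description is implemented as a plain radius-2 median filter (the
referenced software's median filter is non-adaptive).  Per-colony area is
pixel count/px_per_mm²; perimeter uses the Crofton estimator (pixel-edge
counting biases circularity low); circularity 4πA/P² is clamped to 1 for
filtering, and colonies pass at area ≥ 1 mm² and circularity ≥ 0.5
(boundaries inclusive).  Colony-forming efficiency is
100 · colonies/cells seeded (default 800/dish), and the culture growth rate
is ln(harvested/seeded)/days.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the workflow at 400–3000 cells
per sample and 300–1000 genes, with 150–1000 bootstrap draws and 25–50
permutations — sizes chosen so the full property suite replicates across
many seeds while preserving the study's effect sizes; the replicated
reversibility check uses 20 seeds at 2000 cells/sample, and the colony
check 50 plates.  All randomness flows from explicit integer seeds;
identical seeds reproduce byte-identical reports.

## Known limitations

* Per-sample QC thresholds of the original study are unpublished; they are
  configuration, not defaults.
* One lineage only: the trajectory module deliberately supports no
  branching and no multi-lineage shrinkage.
* The EM classifier assumes Gaussian residual components and disjoint
  signatures; heavily overlapping marker programs would need a different
  model.
* The DA overlap is an operationalization: "fraction of cells whose
  neighborhood score is consistent with the permutation null"; other
  definitions of "clustering similarly" would shift absolute overlap values
  (direction and ordering are what the tests pin down).
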