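# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage, what the synthetic data does and does not emulate, and
the known limitations.

## Synthetic data

The generators are first-class, tested code: every downstream stage is
validated against their known ground truth.

**Histology.** Sections are nested elliptical shells whose geometry drifts
slowly along the cutting axis (`anatomy_drift`, default 3% — enough to make
neighbouring sections distinct, little enough that rigid registration of
neighbours is well posed). A fixed angular modulation of the shell radius
breaks rotational symmetry, without which rotation recovery would be
ill-conditioned. Labels render to a stain-like palette (hues 0.55–0.85,
deliberately away from the hue wraparound so hue distances to white
artifacts are informative) plus per-pixel Gaussian texture. Three artifact
classes are injected — tears (pixels erased to background white, placed
wholly inside tissue so every injected pixel genuinely differs), folds
(darkened duplicated patches) and stain shifts (hue rotated in a disc) —
along with per-section rigid misalignments recorded as ground truth. The
generator does not attempt realistic Nissl texture, scanner physics, or
deformable tissue distortion.

**Expression.** Each gene follows an additive model over the
specimen × region × zone grid: baseline + per-factor level shifts +
Gaussian noise. A gene carries an effect per factor with independent
probability (default 10%); active shifts are an evenly spaced ramp of
half-width `effect_size` (default 0.5, noise SD 0.25) permuted over levels,
so the planted signal strength is the declared one rather than a random
draw. Default design: 5 zones, 10 regions, 2 timepoints × 2 specimens
(ages 15/21 weeks postconception). Optional "monotone" genes keep the
region ramp ordered to seed association tests. Missingness is injected
completely at random; no batch structure, probe saturation or
normalization artifacts are simulated, so passing tests show correctness of
the statistics, not robustness to microarray pathologies.

**Surfaces.** All subjects share one icosphere topology. Total area grows
log-linearly with age at 0.054 log10 mm²/week over 21–38 gestational weeks
(sampled uniformly), matching the exponential expansion regime of the third
trimester. Vertex areas follow the generative log-log model with a smooth
beta field spanning [0.7, 1.3]; intercepts are chosen so expected vertex
areas tile the target total at the cohort's mid age. Because the *measured*
total is the sum of vertex areas, it deviates from the generative total by
a small even distortion when the beta field is spread; with a *uniform*
beta field the measured total scales with the same exponent and the fitted
slope against it is identically 1 — recovery tests for uniform fields must
therefore supply the generative total as predictor (`total_areas=` in
`fit_vertex_scaling`). Curvature is a per-vertex Gaussian field; when a
curvature leak is configured it acquires subject-level variation and leaks
linearly into log-area, otherwise it is identical across subjects (making
the correction step a provable no-op). A polar cap (5% of vertices) stands
in for the medial wall; parcels are nearest-seed Voronoi patches.

**Annotations.** Gene sets are drawn with a planted enrichment ratio
(expected overlap rounded to an integer), probe tables carry 1–3 probes per
gene with present/absent flags, and score tables plant a median shift in a
subset (exact when the noise SD is zero).

## Histology repair

The artifact detector formalizes the outlier rule as a robust z-score:
both images go to HSV (all channels in [0, 1]), are box-blurred (5 px), and
per-pixel hue (circular distance, min(|Δ|, 1−|Δ|)) and saturation
differences are scored as |d − median(d)| / MAD(d); a pixel is flagged when
both channels exceed θ = 2.5, and the joint mask is opened with an
elliptical 3-px element, 3 iterations. The MAD is floored at 1e−6 so flat
difference maps produce an empty mask rather than a division error. A
config switch (`outlier_rule: raw_gt_theta_mad`) exposes the alternative
literal reading (raw difference > θ·MAD). Lowering θ provably never
shrinks the pre-opening outlier set.

The appearance model is a per-label Gaussian colour model (mean, covariance
per label, global fallback for labels with < 100 fitted pixels) behind a
pluggable synthesizer interface; any callable from label patch to RGB patch
can be substituted. Synthesis draws one standard-normal vector per pixel
and transforms it per label through the covariance Cholesky factor, making
the output deterministic per seed and equivariant under relabeling.

Whole sections are processed in 256 × 256 patches with an 8-px overlap;
overlapping outputs blend by linear feathering, which is exact for any
operator that acts identically on shared content.

Poisson repair solves the discrete 5-point Laplace system per channel and
per mask connected component (better conditioning, smaller solves), with a
1-px image border always cleared so Dirichlet data exists; a singular
system falls back to direct pixel replacement with a warning. Output is
clipped to [0, 255].

## Reconstruction

Rigid registration searches rotations coarse-to-fine (grid halving from
max/4 down to 0.25°), proposing the translation at each rotation by phase
correlation (integer pixels, capped at 10% of width) and scoring candidates
by NCC computed **over the fixed image's tissue mask** — scoring over the
warp-dependent overlap would reward transforms that shrink the overlap.
Edge cost is 1 − NCC. The alignment graph connects each section to up to
k = 2 neighbours toward the reference (middle section by default);
Dijkstra picks the cheapest chain and the chain transforms compose in path
order.

The shape-prior refinement runs 5 iterations of per-slice 6-parameter
affine registration (seeded by an isotropic-scale grid × rigid search,
polished by Powell on scale-normalized parameters, with images pre-blurred
σ = 2 px to widen the NCC basin) followed by a moving median (window 5) of
the six parameters along the stack axis. A slice keeps the identity unless
the optimizer improves the cost by more than 1e−4, which stops parameter
drift on the interpolation-noise plateau once slices are aligned.

ISH sections register their red channel against the stained section's red
channel (matching contrast family; red-to-grayscale registration is ill
posed when per-label contrasts differ), then ride the section's composed
transform. Missing planes are NaN plus a presence vector — zeros are valid
intensities. Regional means are computed only over present planes, with
per-structure section counts reported.

Volumes export to NIfTI at a configurable isotropic voxel size (default
150 μm) with the voxel size in the affine.

## Expression processing

Absent/multi-gene/unassigned probes are dropped before DS is computed.
DS uses Pearson correlation over (region, zone) cells shared by a specimen
pair, requiring ≥ 4 common cells for a pair to count; a probe with no valid
pair has undefined DS and is treated as below threshold. Ties in DS break
toward the lexicographically smaller probe id, making the pipeline
deterministic and order-stable. The missingness ceiling (10%) is applied to
cells of the aggregated tensor — the level at which analysis happens —
rather than raw samples.

## Zone–region–time model

The design matrix (intercept + treatment-coded zone, region, timepoint) is
shared by all genes; complete genes are solved in one vectorised
least-squares pass and genes with missing cells are refit individually with
listwise deletion. Degenerate cases are resolved against the data scale
(thresholds at 1e−10 of the total sum of squares): a perfect full fit with
remaining factor signal yields F = ∞, p = 0; both residuals at numerical
zero yield F = 0, p = 1. Timepoint is two levels (early = 15/16 weeks
pooled, mid = 21). Specimen is not a covariate and no interactions are fit.
FDR is Benjamini–Hochberg per factor across genes. Fold changes use means
over specimens × regions per timepoint within a zone; non-positive means
leave log2FC undefined.

## Allometric scaling

Curvature correction regresses vertex area on curvature across subjects,
with the curvature first partialled for log total area: in a growing cohort
the raw across-subject regression would attribute growth variance to
curvature by chance, and the partialled slope isolates the folding effect.
The full curvature deviation (not the partialled residual) is then
subtracted, so an exactly curvature-determined area becomes constant across
subjects. Vertices with zero curvature variance are skipped.

Mesh smoothing iterates x ← 0.5·x + 0.5·(neighbour mean); because the
iterated kernel is peakier than a Gaussian, the iteration count is
calibrated on the mesh itself by smoothing a delta function until its
half-maximum width reaches the target FWHM (10 mm default), rather than by
matching kernel variance.

The outlier screen sorts scans by age and takes each scan's up-to-25
nearest neighbours in sorted order (centred, truncated at the ends);
the tested scan is excluded from its own window mean/SD so an extreme scan
cannot mask itself. Scans flagged at > 5% of non-medial vertices are
dropped entirely; remaining flags exclude (scan, vertex) pairs.

The vertex fit is a masked, vectorised OLS of log10(a_v) on log10(A), with
A the sum of (corrected) non-medial vertex areas per scan, overridable via
`total_areas=`. beta is reported only where ≥ 10 scans contribute. Parcel
summaries are unweighted means over defined, non-medial member vertices.
beta is invariant to global rescaling of all areas (intercept shifts only).

## Association and enrichment

Kendall tau-b (tie-corrected) relates each gene's regional expression
vector to parcel-mean beta; genes with constant expression are excluded
from the FDR batch. FDR pools one batch per screen across genes × zones ×
timepoints; a per-zone batching alternative is a caller-side choice of how
records are pooled. The neocortex-only rerun is the same call with a region
subset.

The hypergeometric test reports P(X ≥ x) via `hypergeom.sf` (log-gamma
arithmetic); a strict variant computing the exclusive tail P(X > x) sits
behind `strict_printed_formula` because the two readings of the cumulative
bound differ by one term. Enrichment ratio is (x/N)/(K/M) after
deduplicating and intersecting all sets with the background; K = 0 or
N = 0 yields an undefined ratio and p = 1. Odds ratios come from
proportions or 2×2 counts (Fisher two-sided p in the latter case);
proportions of exactly 0 or 1 are reported symbolically. The permutation
median test draws same-size gene sets uniformly without replacement;
p = (1 + #extreme)/(n_perm + 1), so its floor is 1/(n_perm + 1)
(n_perm ≥ 999).

## Problem sizes

Default verification sizes were chosen to exercise every code path while
keeping a full run on one CPU to a few minutes: sections of 96–256 px and
5–10 per stack, 2,000-gene expression designs, 60-subject cohorts at 642 or
2,562 vertices, 1e5 Monte-Carlo draws for the hypergeometric cross-check
and 500 replicates for the permutation-uniformity check.

## Limitations

- The appearance model is colour-statistics only; it cannot flag artifacts
  that preserve hue and saturation (pure geometric distortions).
- Registration is rigid + affine; deformable residuals between adjacent
  sections are out of scope, as is surface extraction.
- The expression model is main-effects only; specimen random effects and
  factor interactions are not modelled.
- The mesh smoother approximates a geodesic Gaussian by calibrated
  neighbour averaging; on strongly anisotropic meshes the kernel is only
  approximately isotropic.
- Synthetic data is idealized (see above); green tests demonstrate
  correctness of the implemented statistics under the stated generative
  models, not robustness to real-data pathologies.
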