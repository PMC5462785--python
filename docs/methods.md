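# Methods

This note documents the models, numerical choices and known limitations of
`vitreoseg`. It states how quantities are defined and computed; every
empirical number it refers to is produced by the test suite or by
`scripts/acceptance.py`, not asserted here.

## Problem and model

A macular OCT volume is a grid of A-scans organized into B-scans with
highly anisotropic voxel spacing (clinically ~3.8 µm axial × ~11 µm lateral
× ~118 µm between B-scans). Five regions are modelled along each A-scan,
exterior to interior: vitreous gel, posterior vitreous cortex, the
retrohyaloid gap between cortex and ILM, the retina (ILM–RPE), and the
space below the RPE. The four boundary surfaces between them are the
segmentation target. Each surface is stored as the axial index of the
*first voxel of its interior region*; the cortex band is
`[vit_top, vit_bottom)` with thickness ≥ 3 voxels, and the ILM–vitreous
distance is `(ilm − vit_bottom) × axial_spacing`, exactly 0 for an attached
vitreous. Where the detached cortex lies above the scanned axial range
(complete PVD) the vitreous surfaces carry an explicit NaN sentinel —
"unknown" is distinct from "zero".

## Eigenfeatures

Local orientation comes from masked image moments of 21×21 patches under a
circular disc mask (radius 10.5 px). The half-angle formula is evaluated
with the two-argument arctangent, `φ = ½·atan2(2µ′₁₁, µ′₂₀ − µ′₀₂)`, which
resolves the π/2 ambiguity of the printed arctan form so φ is the
major-axis angle modulo π; isotropic patches return 0 and are flagged
degenerate (tolerance 1e-12 relative to µ′₂₀+µ′₀₂).

The kernel bank is learned by sampling patches (75% from above-Otsu
foreground, 25% background; default 50 000 patches), rotating each by −φ
into a canonical frame, and taking the top 20 PCA eigenvectors of the
masked pixels (sklearn full SVD; component signs fixed so the
largest-magnitude coefficient is positive, making training deterministic).
PCA centring doubles as the mean-subtraction of responses: a response is
the centred projection `(patch_canonical − mean)·kernel`.

Numerical choices that matter:

* **Patch rotation** uses bilinear interpolation with *edge extension*
  (not zero fill): the disc mask reaches radius 10.5 while the square's
  inscribed radius is 10, so rotation samples slightly outside the square
  at the rim. With zero fill the rim content is lost and responses to a
  ridge and its 40°-rotated copy differ by ~12%; with edge extension the
  difference drops to ~3%, within the 10% invariance budget.
* **Feature extraction** rotates the *kernel* by the local orientation
  (the adjoint of rotating the patch) and quantizes orientations to 24
  bins over the half-circle (7.5° bins), so each B-scan needs one batched
  FFT correlation per occupied bin rather than a per-pixel rotation.
  Convolution borders are reflective.

## Region classifier

A random forest (default 100 trees, unlimited depth, single-thread,
seeded) is trained on a class-balanced voxel sample (default cap 20 000
per class). Training excludes (a) the 20 voxels immediately exterior to
the annotated vitreous boundary — only the exterior cortex surface is
annotated, so labels just above it are unreliable — and (b) all supra-ILM
voxels of A-scans whose vitreous is out of range, because whether those
voxels are gel or retrohyaloid space is exactly what the missing
annotation cannot say. Probabilities of classes absent from training are
0 and vectors are renormalized to sum to 1.

## Surface extraction

For surface *s* with "above-cost" `a(v)` (the summed probability of the
classes exterior to *s*), the objective is the misassigned probability
mass `F(z) = Σ_c [ Σ_{k<z(c)} (1 − a) + Σ_{k≥z(c)} a ]`. Hard constraints:
|Δz| ≤ 3 voxels between neighbouring A-scans and ≤ 9 between B-scans
(equal physical slope ≈ 0.09 µm/µm on the default 6 mm phantom grid),
ILM–RPE separation ≥ 10, cortex thickness ≥ 3. The problem maps to a
minimum-weight closed set: node (s, c, k) ⇔ "z_s(c) ≤ k", with node weight
2a−1, intra-column monotonicity arcs, inter-column shift arcs for the
smoothness bounds and inter-surface shift arcs for separations. The
min-cut is computed by an int64 Dinic max-flow implemented in numba
(scipy's `maximum_flow` truncates capacities to int32, which is too coarse
for the float→int scaling used here). Weights are scaled by 2³⁸, so
rounding perturbs objectives by < 1e-9 even on large instances; ties are
broken toward smaller axial index by taking the maximal min-cut source
side. Exactness is verified against an exhaustive dynamic-programming
search on 4×3×10 instances.

The ILM/RPE pair is solved jointly, then the vitreous pair constrained to
lie at or above the extracted ILM. Columns failing the vitreous presence
test (peak cortex-class probability < τ = 0.3) receive neutral costs
(0.5) during the vitreous solve — otherwise out-of-range columns drag
neighbouring in-range columns through the hard smoothness arcs — and are
reported NaN. Finally `vit_top` is projected into
`[vit_bottom − 6, vit_bottom − 3]`: the training-exclusion band leaves the
classifier blind right above the cortex, so the exterior surface otherwise
drifts into the vitreous; the cortex is a thin membrane, and anchoring it
to the well-localized interior surface bounds the error by the band width.
(A joint in-graph maximum-thickness constraint was tried and rejected: it
drags the accurate interior surface along with the drifting exterior one.)

## Auto-context

Iteration k trains a new forest on the image features merged with context
features from iteration k−1: signed axial distances to the four extracted
surfaces (sentinel 10×n_axial for missing surfaces) and probability
samples of the cortex and retina classes at axial offsets ±2, ±5, ±10
(clamped at the border). The same balanced voxel sample (same seed) is
drawn each iteration so improvements are attributable to the context
features. The default is two iterations; the trace keeps every iteration's
surfaces and probability maps.

## Phantom generator

The phantom emulates a 6×6 mm macular cube (defaults: 16 B-scans × 48
A-scans × 96 axial voxels at 3.87 µm axial spacing; lateral spacings scale
so the field of view stays 6 mm). Geometry: an ILM with a Gaussian foveal
depression, a flat-ish RPE ≥ 10 voxels deeper, and a 3-voxel vitreous
cortex whose separation from the ILM is 0 inside the adhesion radius
(default 750 µm) and ramps linearly outside it. Class defaults: attached —
separation 0; shallow VMA — peak 80 µm at the volume edge; steep VMA —
peak 200 µm reached at 80% of the adhesion-to-edge span (≈3× the shallow
gradient); complete PVD — boundary above the axial range everywhere.
The peaks were chosen so the boundary stays mostly inside the ~372 µm
axial field of view (steep eyes lose a peripheral sliver, realistically).

Rendering: retina 0.45 with bright ILM (0.85) and RPE (0.95) lines,
cortex at 30% of the retinal band contrast, vitreous gel 0.12 vs
retrohyaloid gap 0.05 — the gel scatters weakly while the subhyaloid
space is optically empty; with identical intensities the two classes
would be mathematically indistinguishable to any local feature, which is
harsher than OCT physics. A mild in-plane Gaussian blur (σ = 0.5 px)
softens band shoulders. Speckle is multiplicative gamma noise with shape
1/c² (contrast c, default 0.3). With zero noise the intensity has local
maxima at the true ILM and RPE along every A-scan.

Cohorts allocate eyes to classes by largest remainder (exact stratified
counts), jitter geometry ±20% per eye, and draw clinical covariates
(baseline/change in visual acuity in ETDRS letters, central retinal
thickness, injection counts) from per-class normal distributions whose
defaults echo the gradients reported across vitreomacular phenotypes in
treated retinal vein occlusion (non-VMA: smaller baseline CRT and smaller
acuity gains than VMA).

What the phantom does *not* emulate: vascular shadowing, motion artefacts,
tilt, real speckle correlation, epiretinal pathology, scanner-specific
intensity response. Passing phantom validation therefore demonstrates the
pipeline's mechanics (feature invariance, globally optimal surfaces,
context refinement, phenotype recovery), not clinical-grade accuracy.

## Distance maps, histograms and clustering

The per-eye feature vector is the histogram of defined A-scan distances
over 30 equal bins on 0–300 µm plus one overflow bin, normalized to
frequencies. Missing (out-of-range) A-scans are folded into the first bin
by default: "no measurable separation within the scan" reads the same
whether the vitreous is attached or detached beyond the range, which is
what lets fully attached and complete-PVD eyes share the non-VMA cluster.
The alternative encoding — excluding missing mass and appending the
missing fraction as a feature — is implemented and selectable, but under
Euclidean k-means it places fully-missing eyes (zero histogram) closer to
the small-norm spread histograms of VMA eyes than to attached eyes, and
planted-cohort recovery collapses (ARI 0.24 vs 1.00 on a 60-eye cohort);
the missing fraction is always recorded on the histogram object either
way. k-means uses k-means++ seeding, 10 restarts, fixed seed; clusters are
relabelled so cluster 0 has the smallest mean defined distance (the
non-VMA convention).

## Statistics

One-way ANOVA is pooled-variance by default with a Welch switch; the
regression of acuity change is OLS on baseline acuity plus cluster
indicators (cluster 0 reference), reporting the multiple correlation R
(not R²), the overall F-test p, per-term p-values and a joint F-test over
the cluster terms. p-values are two-sided with no multiplicity adjustment
(the analyses are exploratory). The attenuation experiment plants a
cluster↔baseline confound (point-biserial r, default −0.4, via a baseline
shift δ = 2rσ/√(1−r²)) and regression to the mean (baseline slope −0.4,
residual SD 11 letters); the attenuation frequency is the fraction of
replicates where the unadjusted ANOVA is significant at α = 0.05 while the
adjusted cluster term is not.

## Validation problem sizes

The held-out validation harness trains on 8 phantom volumes and tests on 3
at 16×48×96 voxels (3 000 PCA patches, 30 trees, 4 000 voxels per class),
across five seeds; the graph-exactness check uses 50 random 4×3×10
instances against the DP oracle; clustering recovery uses 60 eyes; the
attenuation simulation uses 500 replicates of n = 200. These sizes keep
the full validation in a few minutes on one core while leaving every
stage's behaviour measurable; accuracy at larger grids is limited by the
same voxel-level mechanisms, not by grid size.

## Known limitations

* `vit_top` is only localized to the cortex-thickness band (≤ 3 voxels of
  systematic error): the training-exclusion rule removes exactly the
  voxels that would teach the classifier the gel/cortex transition. The
  interior surface, which defines the clinical distance, does not share
  this limitation.
* Features are 2D (per B-scan); inter-B-scan coherence comes only from the
  graph's smoothness constraints, so segmentation across B-scans is less
  smooth than within them.
* The steep-VMA geometry approaches the hard smoothness bounds on coarse
  grids; grids coarser than ~125 µm lateral / ~375 µm inter-B-scan need
  proportionally larger Δ or the true surface becomes infeasible.
* Histogram clustering with plain Euclidean distance ignores bin adjacency;
  χ² or earth-mover metrics might separate phenotypes at finer k but are
  out of scope.
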