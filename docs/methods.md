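# Methods

This note records the models, estimators and numerical choices behind
`fetalmorpho`, what the synthetic cohort does and does not emulate, and the
known limitations.

## Coordinate conventions and inputs

Label volumes are NIfTI-1 integer grids with isotropic spacing (default
0.8 mm, the resolution of super-resolution-reconstructed fetal MRI); codes
are 1 = unmyelinated white matter (UWM), 2 = ventricles, 3 = cerebellum.
The centre of voxel (i, j, k) maps to world millimetres as
`origin + index·spacing` (voxel-centre convention); stating this once makes
volumes and meshes commensurable.  Anisotropic files are rejected rather
than resampled.  Gestational age is carried in decimal weeks
(23 + 3 days → 23.4286).

## Surface extraction

Marching cubes at iso-level 0.5 on the structure's binary mask gives
sub-voxel boundary placement.  Two refinements matter numerically:

* **Mask anti-aliasing.**  The binary mask is pre-filtered with a Gaussian
  of σ = 0.5 voxel before contouring.  Without it the voxel staircase
  inflates surface area by ~3% at 0.8 mm on decimetre-scale structures and
  dominates curvature estimates.  σ is kept well below one voxel because
  level-set smoothing moves the contour inward in proportion to σ²·H (H the
  local mean curvature) and would bias small structures.
* **Taubin smoothing** (λ = 0.5, μ = −0.53, 10 iterations by default)
  rather than plain Laplacian smoothing, which shrinks surfaces and biases
  both volume and curvature.

A mask touching the volume border signals a clipped structure and is a hard
error, not a silent crop.  Connected components are resolved at two levels:
voxel islands below the largest component are dropped (the structures are
single bodies after manual correction; islands are segmentation noise),
except the ventricular compartment, which legitimately contains two lateral
bodies and keeps every component of at least 50 voxels.  After meshing, a
structure whose mask encloses a cavity (UWM around the carved-out
ventricles) yields an inner surface as well; only the outer boundary is
kept.  Every extracted mesh must pass a closed-2-manifold check with
outward normals (positive divergence-theorem volume).

Accuracy on digitized balls: volume within ~1% and area within ~2% of the
closed form at 0.8 mm spacing, with mean error decreasing monotonically
across spacings 1.2 → 0.8 → 0.5 mm (averaged over sub-voxel grid
alignments; at a single alignment the trend can be masked by ±0.5%
placement luck).

## Morphometry

Volume is defined by voxel counting (label count × spacing³), not by the
mesh: the two definitions are both computed and a warning is logged when
they disagree by more than 5%, which deliberately surfaces the mixed
voxel/mesh definition inherent in pairing a voxel volume with a mesh area
in one ratio (for UWM the mesh-enclosed volume includes the ventricular
cavity, so the warning is expected).  Surface area is the exact sum of
triangle areas.  The shape parameter is V/A in mm; for a sphere it equals
r/3 and it decreases as a surface folds at fixed volume.

## Curvature estimation

Per vertex, the 2-ring neighbourhood is expressed in the tangent frame of
the area-weighted vertex normal and a quadric patch
h(x, y) = ax² + bxy + cy² + dx + ey is fitted by least squares; the linear
terms absorb normal-estimation error.  Principal curvatures are the
eigenvalues of the Weingarten map of the fitted patch (first-fundamental-
form-corrected, so the estimate is exact for quadratic surfaces even with a
tilted frame).  Sign convention: convex-with-respect-to-the-outward-normal
is positive, anchored by the requirement that gyral domes score SI → +1 and
sulcal pits SI → −1.  At umbilic points (κ₁ = κ₂ within 1e−9 relative) the
shape index is sign(κ₁)·1, and 0 on planes, so summaries over
near-spherical surfaces stay defined instead of going NaN.  A vertex with
fewer than 5 ring neighbours is an error (mesh too small to fit).

An angle-deficit Gaussian-curvature estimator is kept as an independent
cross-check; the test suite verifies it agrees with κ₁·κ₂.  Measured
accuracy: < 2% on icospheres (subdivision 4), and 3%-level agreement with
the closed-form torus curvatures at ≥ 95% of vertices, with relative error
floored at the torus's smallest curvature scale 1/R (a pure relative
tolerance is ill-posed where the analytic curvature crosses zero).
Per-vertex values are summarised raw — no winsorising or smoothing — which
is a sensitivity axis worth remembering when comparing absolute values.

## Spectral longitudinal correspondence

The Laplacian is cotangent-weighted with lumped (one-third triangle area)
vertex masses; an unweighted-graph fallback exists for degenerate
triangulations.  Eigenmodes are solved with a shift-inverted Lanczos
iteration seeded with a fixed start vector; each retained mode is
normalised to unit magnitude and given a deterministic sign
(largest-magnitude entry positive).  A disconnected mesh makes eigenvalue 0
degenerate and is rejected.

Matching two timepoints uses k = 5 non-trivial modes:

1. **Coarse geometric pairing** — similarity-transform (Procrustes)
   alignment of B onto A (index-seeded when vertex counts match), then
   nearest neighbours.
2. **Spectrum alignment** — Laplacian eigenmodes are only defined up to
   sign, up to ordering of close eigenvalues, and up to rotation inside
   degenerate multiplets.  All three ambiguities are resolved by an
   orthogonal Procrustes fit of B's modes onto A's within each
   near-degenerate eigenvalue group (relative gap < 5%); singleton groups
   reduce to a sign flip.  Each mode receives an alignment confidence
   (post-alignment correlation); a multiplet truncated by the choice of k —
   e.g. only 2 of the 5 ℓ = 2 sphere modes — cannot be aligned and scores
   low.
3. **Initial inter-layer links** — nearest neighbours in eigenvalue-scaled
   spectral coordinates (mode / √λ), using only modes with confidence
   ≥ 0.8.
4. **Joint solve** — the dual-layered graph keeps each mesh's cotangent
   weights and connects the layers by the initial links, with total
   inter-layer weight a configurable fraction (default 0.1) of the mean
   intra-layer weight; the combined graph's first k non-trivial eigenmodes
   embed both layers in one basis, and each A-vertex takes its nearest
   B-vertex there (ties resolved by the deterministic tree query).

Self-matching returns the identity at 100% of vertices, a rigidly moved
copy is recovered exactly, and on same-parameterisation growth pairs the
median distance to the ground-truth twin is below one mean edge length.
Per-vertex weekly rates are then (field_B[match(v)] − field_A[v])/Δweeks,
summarised signed by the median (mean/absolute variants behind a switch).

## Lobe parcellation

The reference surface carries exact sector labels (hemisphere by the sign
of x with the mid-sagittal plane at x = 0; frontal/parietal/occipital/
temporal by quadrants of the sagittal-plane angle).  Subject surfaces are
labelled by Procrustes alignment of the atlas followed by nearest-neighbour
transfer — a deliberate simplification of non-rigid atlas registration,
adequate for the synthetic geometry (≥ 90% agreement with ground-truth
labels on generated subjects) but not a substitute for real atlas
registration on clinical data.

## Statistics

Each parameter is reduced to paired weekly rates over three windows:
immediate (x₂−x₁)/(ga₂−ga₁), long-term (x₃−x₂)/(ga₃−ga₂), and global.
The global window is defined as the overall T1→T3 rate
(x₃−x₁)/(ga₃−ga₁): the alternative reading "long-term minus immediate"
is implemented behind `global_definition="difference"`, but the reported
global medians of the motivating cohort lie between the two period rates,
which is consistent only with the overall-rate definition.

Group comparison: Anderson–Darling (case-adjusted A², 5% critical value,
n ≥ 8) gates normality; the analysis route is Kruskal–Wallis with tie
correction regardless (every reported result of this kind is
nonparametric; no parametric branch exists).  All-identical data make H
0/0 and are returned as H = 0, p = 1.  With more than two groups a
significant omnibus is followed by Dunn's pairwise rank z-tests with Holm
adjustment (Bonferroni and Benjamini–Hochberg selectable).  Significance
is α = 0.05.  Groups with a single subject report medians/IQRs but skip
the test with a warning.  Measured type-I error of the Kruskal–Wallis
route is ~4–5% over 1000 null simulations.

Ventriculomegaly severity from the atrial diameter uses the integer bands
none < 10, mild 10–12, moderate 13–15, severe > 15 mm; fractional
measurements are rounded half-up to integer millimetres first, matching
the integer banding of the clinical classes.

## Synthetic cohort

The generator defines the study conditions; its defaults are not tuned to
test outcomes.

* **Cohort structure**: 29 OSB vs 12 control subjects; GA schedules (mean,
  SD in decimal weeks) OSB 23.43/25.86/31.86 (±1.14/0.71/1.0), controls
  23.14/28.86/32.86 (±1.29/1.43/1.71); strictly increasing per subject.
* **UWM surface**: r(θ,φ) = R(ga)·E(θ,φ)·(1 + a(ga)·f(θ,φ)) on a fixed
  40 × 80 (θ,φ) grid, so vertices correspond by index across timepoints
  and lobe labels are exact sectors.  E is an ellipsoidal base (axis
  ratios 1.0/1.15/0.9), R(ga) = 21 + 1.5·(ga − 20) mm, and f is a fixed
  band-limited sum of eight sin(ℓθ)·cos(mφ) terms (ℓ ≤ 8) with
  per-subject random phases, tapered by sin θ for pole continuity and
  normalised to max |f| = 1.  Amplitudes a·max|f| ≥ 1 (self-intersection)
  are rejected.
* **Gyrification trajectory**: a(ga) rises piecewise-linearly; the OSB
  profile rises faster before 26 weeks (0.022/week vs 0.013) and slower
  after (0.008/week), mirroring the direction of the reported immediate
  increase and long-term decrease of folding change after surgery.  Note
  that in this geometry median curvedness can still *fall* with GA because
  R grows faster than the folding term: the generator reproduces group
  differences in folding change, not the absolute sign of normal
  curvedness development, whose increase in real cohorts is driven by
  fine secondary/tertiary folds this band-limited model does not contain.
* **Ventricles**: two mirrored ellipsoids (axis ratios 1/1.8/0.75 of the
  atrial semi-diameter, 0.5 mm midline gap).  The atrial-diameter
  surrogate is the minor-axis diameter, drawn per severity class with OSB
  class frequencies 4/8/17 of 29 (mild/moderate/severe) and controls at
  5–9 mm.  Total ventricular volume grows linearly at a per-subject rate
  drawn log-normally with medians 2500.94 (OSB) and 708.21 mm³/week
  (control) and σ matched to the reported IQRs (1689.70–3580.80 and
  474.50–925.00).  Subpopulation multipliers (partial corpus-callosum
  agenesis ×1.27, persistent hindbrain herniation ×2.0, the ratios of the
  reported subgroup medians to the overall median) are divided by their
  cohort-expected mean log so the realised group median stays at the
  anchor.  Draws are clipped at ±2.5 SD in log space — medians and IQRs
  untouched — to avoid tail geometries larger than any plausible cranium.
* **Nesting**: if the ventricles would not fit inside the folded UWM
  surface, R is enlarged to contain them with a 2 mm margin — a
  hydrocephalus-like stretching of the mantle that keeps severe cases
  geometrically consistent (and implies UWM volumes above the base growth
  curve in those subjects).  Any residual overlap after placement triggers
  phase re-jitter (5 attempts) and then a hard error.
* **Rasterisation** is analytic: a voxel centre is labelled by the exact
  radial/ellipsoid inequalities, not by voxelising the triangulated mesh;
  this is exact with respect to the generative model and an order of
  magnitude faster.  The generic mesh voxelizer (scanline parity test on
  voxel centres) exists independently in `surface_io` and is verified by
  round-trip tests against brute-force point classification.
* **Ground truth**: volumes by fine midpoint quadrature of ρ³/3·sinθ
  (256 × 512 grid), areas by quadrature of ρ·√(ρ²sin²θ + ρ_θ²sin²θ + ρ_φ²);
  cerebellum and ventricles in closed form.  Everything is regenerable
  bit-for-bit from (config, seed) via spawned SeedSequence streams, and
  `sample_cohort_rates` draws from exactly the same per-subject streams,
  so statistical replicates are consistent with rendered cohorts.

What passing tests on this cohort show: that the pipeline recovers
programmed growth rates through the voxel path within measurement error
(≤ a few ‰ at 0.8 mm), that the group statistics detect the reported
effect size at the reported sample sizes with high power and calibrated
size, and that correspondence/parcellation recover a known ground truth.
What they do not show: robustness to segmentation error, partial voluming,
motion artifacts, anatomically realistic folding, or non-linear growth —
none of which the generator emulates.

## Problem sizes and runtime choices

Default cohort rendering uses the 40 × 80 surface grid and 0.8 mm voxels
(~1–6 M voxels per subject-timepoint); a full 41-subject render takes
about two minutes on one CPU.  Statistical power/size checks use 50
replicates at the rate level (`sample_cohort_rates`), with one fully
rendered cohort verifying measurement recovery.  The pipeline extracts the
large UWM surface with marching-cubes step 2 (step 1 for the small
structures); the curvature and spectral stages run on those meshes
directly.

## Known limitations

* The atlas and parcellation are synthetic-sector constructs; no claim is
  made about real lobar boundaries.
* Joint spectral matching assumes comparable topology and moderate shape
  change; it has no geometric regularisation and will not handle large
  topology changes or missing data.
* The generator's folding field is band-limited and low-frequency;
  absolute curvature magnitudes are an order of magnitude below real
  cortical values at term.
* Statistics treat subjects as independent and implement only the
  nonparametric route; GA differences between groups beyond the use of
  weekly rates are not adjusted for.
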