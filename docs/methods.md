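# Methods

## Scope and data model

All stages operate on a `VoxelGrid`: a 3D 16-bit intensity volume with an
isotropic voxel edge `s` in µm, axes ordered (z, y, x), z along the flower
axis with z = 0 at the base (peduncle end). Indexing is 0-based with
half-open intervals. Stacks scanned tip-first are brought into convention
with an axis flip; only axis-aligned flips/permutations are offered,
because interpolating rotation resamples intensities and would bias
volumes, the primary measurand. Connectivity is 6-neighborhood in 3D and
4-neighborhood in 2D throughout (surface faces, components, pooling).

The pipeline starts from reconstructed slices; tomographic reconstruction,
beam-hardening and ring-artifact correction belong to scanner vendor
software and are out of scope.

## Gland segmentation

1. **VOI.** Analysis is restricted to the slice range [z_first, z_last)
   containing the gland; the offset is carried so heights stay in stack
   coordinates.
2. **Threshold.** Tissue is `intensity ≥ t`. Default `t` is Otsu's value
   on the VOI histogram, shifted half an intensity step above the returned
   background bin so the ≥ convention holds exactly; a fixed threshold can
   be supplied (and is required for degenerate constant-intensity input).
   The threshold used is always recorded.
3. **Height projection.** Each (y, x) column maps to the z of its topmost
   tissue voxel; empty columns carry the sentinel −1.
4. **Watershed.** The height map is treated as topography: seeds are its
   regional maxima after h-maxima suppression of depth `h_min`
   (default 2 voxels — bumps shallower than 2 slices do not open their own
   compartment), and the negated map is flooded from the seeds. Sentinel
   columns are masked out, so footprints separated by air are always
   distinct compartments. Flooding is deterministic; ridge-pixel ties
   follow the flood-queue scan order.
5. **Compartment selection.** `centermost` (default) picks the compartment
   nearest the lateral image center by *nearest-pixel* distance, with
   centroid distance then label as tie-breaks. Nearest-pixel rather than
   plain centroid distance is deliberate: the corolla wall forms an
   annular compartment whose centroid falls exactly at the image center it
   does not occupy, and a centroid rule would select it whenever noise
   nudges the gland centroid off-center. `largest`, an explicit label id,
   and a multi-label merge are also available; for annular (female-type)
   glands, whose compartment surrounds the central style, selection by an
   explicit id (e.g. from a probe pixel in the gland footprint) mirrors
   the manual selection a human operator performs.
6. **Lower surface.** The gland base cannot be thresholded (gland tissue
   merges with the receptacle), so it is interpolated: each external
   contour pixel takes the z of the lowest tissue voxel in its column, and
   interior values solve the discrete Laplace equation with those
   Dirichlet values (sparse direct solve), rounded to integer z and
   clamped to the upper surface. Harmonic interpolation is deterministic,
   parameter-free, and exact for flat and planar bases; by the maximum
   principle it cannot oscillate. It cannot, however, reconstruct a base
   that bulges far from its rim values — a deeply domed hidden base is
   flattened. On gently curved bases (sagitta of a few voxels across the
   footprint) the mean absolute error stays within ~2 voxels; that is the
   regime of a gland resting on a receptacle.
7. **Mask, volume, surface.** The gland mask is every voxel between the
   two surfaces over the footprint. Volume is `N·s³·10⁻⁹ mm³`. Surface
   uses the exposed-faces estimator by default: faces shared by a gland
   voxel and an air voxel, ×`s²·10⁻⁶ mm²`, where air is the complement of
   the *global* tissue mask, so gland area pressed against other organs
   (style, receptacle) is not counted as air-contact. A surface-voxel
   count (gland voxels with ≥ 1 air neighbor) is available; the two differ
   by construction and the estimator tag is recorded with every result.
   Face counting is additive over disjoint masks and has a brute-force
   oracle; note that any voxel surface is a Manhattan approximation that
   overestimates smooth areas (≈ 1.5× for a sphere) and does not converge
   to the continuum area with resolution — comparisons are valid within
   one estimator, not across methods.

Identical input and parameters give bit-identical output at every stage.

## Nectar-level reconstruction

A capillary measurement gives the target volume in µL (1 µL = 10⁹ µm³;
at 5 µm spacing one voxel is 125 µm³ = 1.25 × 10⁻⁷ µL). Air voxels
(`intensity < t`, the same threshold as segmentation so the partitions are
complementary) are visited in ascending (z, y, x) order and accumulated
until `n` voxels satisfy `n·vox ≥ target` with `n` minimal — the result is
never under-filled and overshoots by less than one voxel volume; the
overshoot is reported, not redistributed. By default eligibility is
restricted to air 6-connected to the component touching the basal air
slice (nectar pools in the chamber); the literal all-air variant is a
flag. Filling is monotone in the target (masks nest) and idempotent when
re-run at a previous achieved volume. In a convex chamber the filled top
surface varies by ≤ 1 slice — a level, as a liquid forms. Menisci,
capillarity and wetting are not modeled, and the target is reconstructed
exactly as given (no correction for residual nectar in the flower).

## Morphometrics

Cross-sectional gland area: two perpendicular longitudinal sections, one
voxel thick, through the lateral centroid of the gland mask (robust to
off-center crops; a > 5-voxel disagreement with the image center is
logged); per section every in-plane gland voxel counts — an annular gland
shows two lobes per section and both are included — and the mean of the
two sections is returned. This reproduces the known 2D blind spot: male
and female phantoms with near-equal central sections but 2.7× different
true volumes differ < 10% in section area, while the 3D pipeline resolves
the full fold change.

Flower width: maximum per-axis lateral extent of the tissue footprint over
all slices (default), or at a chosen slice (`at_z`) for rim-level
measurement — the anatomical level of "width" is a convention, so both are
explicit.

## Statistical stage

Two-group comparison follows a fixed tree: Shapiro–Wilk on each group,
then Levene's variance test, then Student's t (equal variances) or
Welch's t (unequal), at α = 0.05. Levene uses the mean-centered (original)
form by default, switchable to median-centered (Brown–Forsythe). A
significant Shapiro result sets a `nonparametric_needed` flag but does not
substitute a nonparametric test. Identical samples return t = 0, p = 1.
Under H0 (equal normals, n = 15/group) the procedure's empirical type-I
error sits near the nominal 5% (asserted within [0.035, 0.065] over 2,000
replicates).

Regression is OLS with Pearson r, R² = r², and a two-sided p from the t
transform with n − 2 df; an exact-style permutation p is available for
small cohorts (per-flower studies often have n ≈ 10 per sex). No
multiple-testing correction is applied across correlation panels; the
result metadata says so.

## Bee accessibility

The bee head (a scan-derived mask or the phantom's ellipsoid + proboscis
cylinder) is superimposed rigidly: integer translations and axis flips
only. The insertion search is a deterministic proxy for what was
originally a manual pose: the head is centered laterally on the corolla
opening (the hole in the topmost annular tissue slice) and descends in
1-voxel steps; the descent stops at the first colliding position and the
last collision-free one is reported (depth 0 = head at the rim; a head
wider than the opening stays above). On monotone tube geometries this
equals an exhaustive placement search; it is an explicit accessibility
metric of this package, not a reproduction of any manually posed figure.
Nectar is reachable when the gap from the head's lowest voxel to the
nectar top is at most the proboscis length.

## Phantom generator

The phantom defines the study conditions for all tests. A flower is a
corolla bore (radius 54 voxels) in a solid block on a 6-voxel base cap;
the male gland is a dome of radius 20 voxels (0.1 mm at 5 µm), the female
gland an annulus (inner 12, outer 26, height 27 voxels) around a style of
radius 8 reaching the rim. The female/male defaults give a true
gland-volume ratio of 2.7, the fold-change regime reported between melon
flower sexes, and the annulus reproduces the 2D two-lobes / 3D one-organ
discrepancy. The interior air cavity is one 6-connected component touching
both the basal chamber and the corolla opening. Everything outside the
bore is tissue: the phantom emulates a stack already cropped to the
flower, so the cavity is the only air — the square outer block means the
phantom's "flower width" is its grid extent, a deliberate simplification
(exterior petal shape is out of scope).

Dome voxelization samples each z layer at its slab midpoint, making the
voxel count an unbiased midpoint-rule discretization of the continuum
half-ball (−0.3% at radius 20, error ∝ 1/r). Degradation is Gaussian blur
(σ = 1 voxel, a partial-volume surrogate), then additive Gaussian noise,
then 16-bit quantization; ground truth is always the ideal pre-degradation
geometry, and recovery tolerances absorb the degradation. The generator is
deterministic per seed.

The phantom does not emulate: X-ray physics (scatter, spectra, beam
hardening), trichomes or cell-level texture, petals outside the tube,
residual nectar, or anthers/stigma filling the tube. Passing tests
therefore demonstrate correctness of the geometry pipeline under
controlled contrast and noise, not performance on arbitrary real scans —
in particular, real glands pressed against organs of identical density
will challenge any threshold-based separation.

Synthetic cohorts draw gland volume uniformly and set nectar volume as a
linear response plus Gaussian noise, with the noise chosen in closed form
for a target population correlation; negative simulated volumes are
clipped to zero and flagged. Secondary columns follow a fixed allometry
(areas ∝ volume^(2/3)) so cohort plumbing is fully populated.

## Numerical choices and problem sizes

Default phantom stacks are 116 × 121 × 121 voxels; the test suite and the
acceptance script use this size (and 64³ tubes for the insertion-depth
oracle), which the full pipeline processes in well under a second — large
enough that discretization errors sit within the stated tolerances, small
enough for fast iteration. Tolerances asserted in tests: 2% volume
recovery and Dice ≥ 0.95 on clean phantoms, Dice ≥ 0.85 at noise = 5% of
contrast, 5% on the 2.7× fold change, < 1 voxel fill overshoot, ±0.05 on a
recovered correlation of 0.85 (n = 200). The H-maxima depth default
(h_min = 2) suppresses single-slice noise bumps; under heavy noise a
spurious watershed split can still shave part of the gland (observed worst
case Dice ≈ 0.90 at 5% noise), which the multi-label merge flag remedies
when it matters.

## Known limitations

- Harmonic lower surfaces flatten strongly domed hidden bases (above).
- The exposed-faces surface is estimator-specific; absolute surface areas
  are not comparable across software using different estimators.
- `centermost` selection assumes the gland is the structure nearest the
  flower axis; female-type annular glands around a central style need
  explicit-id selection.
- The insertion search considers axial descent only (no rotation, no
  lateral exploration); it bounds accessibility from below on geometries
  where tilting would help.
- Volumes assume exactly isotropic voxels; anisotropic stacks must be
  resampled upstream.
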