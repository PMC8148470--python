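# Methods

## The solidity descriptor

For a segmented cell `C` (a set of voxels), solidity is

    s(C) = |C| / |L ∩ conv(C)|

where `conv(C)` is the convex hull of the voxel centers and `L` the integer
lattice.  Both numerator and denominator are lattice-point counts rather
than continuous volumes.  This choice has three consequences that the
continuous alternative does not share:

- a digitally convex object (filled cuboid, digital ball) scores exactly 1;
- `s ≤ 1` always, because every object voxel center lies in its own hull;
- the ratio is invariant under axis-aligned translation, axis permutation,
  90° rotation, and any change of voxel spacing (affine maps carry hulls to
  hulls and preserve lattice correspondence).

Hull membership is tested against the facet inequalities of a Qhull convex
hull with slack `1e-9`, so lattice points on the boundary count as inside
(the hull must *contain* the region).  Degenerate voxel sets are handled in
their affine span: the rank of the centered coordinates is determined from
singular values (relative tolerance `1e-6`), candidates from the bounding
box are filtered to the span, and the hull is computed in 2D (coplanar), as
a segment (collinear), or trivially (single voxel, solidity 1).  Lattice
points genuinely off a lattice-spanned plane sit at distances orders of
magnitude above these tolerances, so the tests cannot misclassify them.

Biologically, ramified (resting) microglia leave most of their hull
unfilled and score low; amoeboid (activated) cells approach 1.  Per-eye
summaries pool all cells of an eye's lesion images and average their
solidity (the alternative — averaging per-lesion means — is available via
`aggregate="by_lesion"`).  Cells touching the volume border are excluded
from eye means by default because truncated arms bias solidity upward; the
flag is preserved per cell so users can include them.

## Processing chain and its parameters

1. **Background estimation** — grayscale opening with a flat disk, applied
   per z-plane.  Slice-wise rather than 3D because confocal background is
   dominated by per-plane illumination and the axial step (2.5 µm) is far
   coarser than the lateral pixel size, making a 3D ball badly anisotropic.
   `opening_radius_px` (default 50) must exceed the lateral footprint of
   the cells; the suite's benchmark scenes, sampled at ≈1.52 µm/px, use 10–12 px.
   Opening is anti-extensive, so the estimate never exceeds the image.
2. **Subtraction** — `max(raw − background, 0)`; negative residuals are
   clamped because negative intensities are meaningless and would distort
   the Otsu histogram.
3. **Otsu binarization** — one threshold per stack from the global volume
   histogram (`otsu_bins`, default 256), keeping the mask consistent
   across z.  Candidate thresholds are interior bin edges; the returned
   threshold is the first maximizer of the between-class variance, with
   exact plateau ties (empty bins between modes) resolved to the earliest
   bin at float precision.  Foreground is *strictly above* the threshold,
   making tie behaviour bit-stable.
4. **Majority denoising** — each voxel replaced by the strict-majority
   value of its `(2r+1)³` cube (`median_radius_px`, default 1); border
   voxels use the clipped neighborhood, with exact ties (possible only
   there) resolving to background.  On anisotropic grids this filter
   erodes structures thinner than about two axial planes — see the
   generator notes below.
5. **Object detection** — 26-connected components (diagonal adjacency
   preserves thin-process continuity), labeled in raster order of each
   component's first voxel, then gated to
   `[min_object_voxels, max_object_voxels]` (defaults 30, 10⁵).  The first
   gate is deliberately loose: it keeps small cell *clusters*, which are
   resolved next.
6. **Seeding and splitting** — seeds are local maxima of the xy-smoothed
   (σ = `seed_smooth_sigma_px`, default 2; smoothing is in-plane only, again
   because of axial anisotropy) background-subtracted intensity inside
   foreground, with connected plateaus collapsed to their first raster
   voxel, greedily thinned to a minimum xy separation
   (`seed_min_distance_px`, default 8; brighter seed wins, raster order
   breaks exact ties), and a guaranteed fallback seed (the object's
   smoothed-intensity argmax) for any object left seedless.  Multi-seed
   objects are partitioned by seeded watershed on the negated smoothed
   intensity, constrained to the object; splitting is an exact partition of
   the parent's voxels.  An intensity peak was chosen as the operational
   meaning of a cell's "bright center"; a distance-transform maximum is a
   plausible alternative that is noted but not implemented.
7. **Shape/size filtering** — cells outside
   `[min_cell_voxels, max_cell_voxels]` (defaults 50, 2×10⁴), with
   principal-axis elongation above `max_elongation` (default 12) or
   bounding-box extent below `min_extent` (default 0.02) are discarded.
   Elongation is the largest/smallest eigenvalue ratio of the physical
   voxel-coordinate covariance, regularized by the second moment of a
   single voxel (edge²/12 per axis) so single-voxel or one-plane objects
   get a finite, scale-appropriate value.  Note that in shallow stacks the
   smallest eigenvalue is usually axial, so the criterion also removes
   extreme "pancake" debris; strongly ramified cells confined to one or
   two planes can approach the cutoff.

All parameters live in one YAML config with logged defaults and unknown-key
rejection; the size/shape cutoffs have no canonical published values and
were fixed once against the synthetic generator's cell scale.

## Density, OCT and expression readouts

Stained-area density of a lesion image is the fraction of
maximum-intensity-projection pixels strictly above a threshold.  For group
comparisons one shared Otsu threshold is derived from the pooled histogram
of all images in the run (per-image thresholds would confound the density
contrast); a fixed manual threshold can be configured instead.  Per-eye
mean fractions are expressed as a percentage of the control-group grand
mean, so the control arm averages 100 by construction and the measure is
invariant to global intensity rescaling.

OCT lesion swelling is `(b − c)/c` with `b` the lesion thickness and `c`
the adjacent choroid thickness (µm); `c > 0` is enforced.

qRT-PCR results are `2^(−Ct̄_GOI) / 2^(−Ct̄_NOR)`.  Ct values of multiple
housekeeping normalizers (e.g. GAPDH and snU6) are pooled into one mean
before applying the formula; geometric averaging of the normalizers'
expressions instead would change results only by a per-sample-set constant.

## Statistics

Two-group comparisons use the Mann-Whitney U test (midrank ties), matching
the small per-group sizes (n ≈ 5–15) of the experiments this pipeline
serves.  The p-value is exact — full enumeration of rank assignments — when
the combined sample size is ≤ 12 and tie-free, and otherwise a normal
approximation with tie and continuity corrections; the method used is
recorded in the result.  More than two groups use tie-corrected
Kruskal-Wallis with a χ²(k−1) tail; an all-identical sample is reported as
degenerate rather than raising.  Post-hoc multiple-comparison procedures
are out of scope.  The computations are delegated to scipy.stats behind the
package's interface; the test suite checks them against an independent
enumeration oracle.

## Synthetic data: what it emulates, and what it does not

`synthdata` generates scenes that reproduce the statistical structure the
chain assumes: an ellipsoidal (in voxel units) soma of constant peak
intensity, dimmer random-walk arm tubes of given width, length and
tortuosity emanating from the soma surface and biased toward the imaging
plane (processes of cells in flat-mounted tissue spread laterally), a
linear background ramp plus offset, and additive Gaussian noise clipped at
zero.  Default geometry mirrors the modeled acquisition: a 780 µm square
field at 512 px per side (dx = dy ≈ 1.52 µm), 2.5 µm axial steps, 30 µm
depth.  Everything is a pure function of parameters and one integer seed;
per-cell and per-stack streams are spawned from it by a fixed rule, so any
sub-object regenerates bit-identically.

Default structure sizes are chosen to be *representable* at this sampling:
soma diameter ≥ 11 µm and arm width 6 µm, so every structure spans at
least two axial planes.  Real microglial processes can be thinner than one
axial step; such structures are unresolvable in the sampled volume and are
erased by the majority filter, so ground truth about them could not be
recovered by any method operating on the stack.  Passing tests therefore
demonstrate correct recovery of *resolvable* morphology, not performance
on arbitrarily fine processes.  Other omissions, by design: no PSF, no
depth attenuation, no spectral crosstalk, no autofluorescent debris.

Ground truth records each cell's exact voxel set, phenotype parameters and
true solidity (computed by the same lattice-hull definition on the true
mask).  Where a later cell would overlap an earlier one the voxel stays
with the earlier cell, keeping true masks pairwise disjoint.

## Benchmark problem sizes

The behavioural test suite runs at sizes chosen to keep one scene around a
second while preserving the modeled voxel geometry: recovery scenes use a
420 µm sub-field (276 px) with 10 cells at ≥ 90 µm centroid separation,
noise σ = 8 (4 % of the 200-unit soma intensity), over 50 fixed seeds; the
cohort benchmark uses 5 eyes × 4 lesions × 8 cells per arm
("inhibitor-like" ramified-shifted vs "mimic-like" amoeboid-shifted, i.e.
40 stacks), compares per-eye mean solidity between arms by exact
Mann-Whitney, and rank-correlates measured against true per-cell solidity
(cells matched to ground truth by centroid proximity within 10 voxels).

## Known limitations

- Solidity is reported per the lattice-count definition only; surface-mesh
  hull volumes, Sholl analysis, circularity and fractal descriptors are out
  of scope.
- The watershed split assumes each cell in a cluster exposes one dominant
  intensity maximum; deeply overlapping somata closer than
  `seed_min_distance_px` merge.
- Thresholding is global per stack; strong depth-dependent attenuation
  (not modeled by the generator) would call for per-slice or adaptive
  thresholds, which are deliberately not provided.
- The Fiji-style rolling-ball background, deconvolution and flat-field
  calibration are not implemented; opening-based estimation is the single
  supported background model.
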