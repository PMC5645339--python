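# Methods

`ivdmorph` quantifies the three compartments of a contrast-enhanced microCT
scan of a murine intervertebral disc — annulus fibrosus (AF), nucleus
pulposus (NP), and the notochord remnant (NC) embedded in the NP — from
sparse manual contours plus one intensity threshold, and provides the
reliability and cross-resolution statistics such a semi-automated protocol
needs.  Because no public scan data accompany this problem, every stage is
validated against a synthetic phantom generator with exact, countable ground
truth.  This note records the models, the defaults and why, the numerical
choices, and what the synthetic validation does and does not establish.

## Segmentation model

An operator draws two closed polygons on sparse transverse slices (default
every 30): the outer AF edge (`disc_outer`) and the AF/NP border
(`np_border`).  Dense per-slice polygons are produced by vertex-wise linear
interpolation between the bracketing annotated slices.  Polygon
correspondence is canonicalised first: each polygon is resampled to a fixed
vertex count (default 128) equally spaced by arc length, forced
counter-clockwise, starting at the boundary point hit by the +x ray from the
polygon's area centroid.  For the star-shaped, roughly convex contours of a
disc this gives a deterministic, rotation-consistent correspondence; it is
not intended for strongly non-star-shaped outlines.  Interpolation never
extrapolates beyond the annotated span, and annotated slices return the
(resampled) polygon itself, so the polygon family is continuous in the slice
index.

Rasterization includes a voxel iff its centre lies inside the polygon by the
even-odd rule, with centres exactly on an edge counted as inside.  The
coordinate convention is fixed once: voxel indices are 0-based, a vertex at
physical coordinate x µm lies at voxel index x/spacing, and voxel (i, j)
covers the half-open square [j, j+1) × [i, i+1) in voxel units.  The
tie-inside rule makes counts reproducible; it is implemented as the union of
two signed infinitesimal dilations of the polygon path, which is
orientation-independent.

The whole-disc and NP masks come from the two contour labels; AF is the
exact set difference (whole disc minus NP).  The NC — high-attenuation,
irregular, possibly multi-component — is extracted by thresholding *inside
the NP mask only*, because the AF attenuates similarly to the NC and an
unrestricted threshold would leak into it.  No connected-component or size
filtering is applied: an immature, diffuse NC genuinely consists of many
small components.  The threshold is operator-supplied; `suggest_nc_threshold`
offers Otsu's threshold over the NP-interior histogram as a starting point
and flags low separability when the two Otsu classes are closer than four
pooled standard deviations (a constant interior always flags).  The d′ < 4
cut-off is a heuristic chosen so that a pure-noise Gaussian interior
(d′ ≈ 2.7 for an optimal split of a normal) is flagged while any genuinely
bimodal NP/NC histogram at workable contrast-to-noise is not.

## Preprocessing

Coarse scans are resampled onto the reference grid by spline interpolation
(`rescale_to_spacing`; order 3 by default, orders 1–2 available).
Grid-aligned resampling (`grid_mode`) preserves the physical extent to
within one target voxel.  The boundary is handled by mirror reflection; the
mirror variant is used because its spline prefilter is exact — a constant
stack stays constant to machine precision and a linear ramp is reproduced in
the interior — whereas the alternative reflect prefilter in scipy is
approximate.  Upscaling beyond a factor of 20 per axis is refused as a
resource guard unless forced.

Denoising is a median filter of radius 5 (configurable) with a 2-D disc
neighbourhood applied slice by slice; a 3-D ball is available once the grid
is isotropic.  Slice-wise filtering is the default so that anisotropic
stacks are not mixed across axes before resolution matching.  Edges are
handled by reflection, avoiding a dark halo at the stack border.  The filter
is idempotent on piecewise-constant images away from boundaries and never
produces values outside the input range; both properties are tested.

The default operation order is rescale → filter, so the radius is expressed
in reference-grid voxels; both steps are explicit library calls, so the
opposite order is available to the caller.

## Morphometry

Volume is voxel count × voxel volume (µm³).  NP and NC volumes are also
reported as percentages of whole-disc volume; the NP percentage is inclusive
of its embedded NC, so AF% + NP% = 100 exactly, with NC% reported
separately.

The NC shape metric is the surface-area-to-volume ratio S.a./V. (µm⁻¹):
high for diffuse, scattered morphology, low for compact, block-like
morphology.  Two estimators:

* **mesh** (primary): Gaussian pre-smoothing of the binary mask (σ = 1
  voxel), marching-cubes iso-surface at 0.5, total triangle area with
  vertices scaled to physical µm.  Counting exposed voxel faces
  overestimates a smooth surface by up to 50%, and meshing the *raw* binary
  mask still overestimates a digital sphere by ≈9%; with σ = 1 smoothing the
  sphere error is ≈2.3% at r = 10 voxels, ≈0.3% at r = 20, ≈0.1% at r = 40,
  and a 20-voxel cube is reproduced within 10%.  When a structure is thinner
  than the kernel (the smoothed field never reaches 0.5) the estimator falls
  back to the unsmoothed surface with a warning.  Absolute S.a./V. values
  are estimator-dependent; orderings and trends are the quantities treated
  as meaningful.
* **voxel_faces** (cross-check oracle): exact exposed-face area, used where
  the combinatorial answer is exact (single voxel: 6 µm²; cube: 6L²).

Empty NC masks yield NaN surface area and S.a./V. — a missing value, never
zero, since S.a./V. is undefined without volume.

## Phantom generator

The phantom emulates the study conditions this pipeline is built for: a
PMA-stained disc as a bright AF ring around a dark NP core with a bright NC
inclusion, scanned at 1 µm and 6 µm voxel spacing with additive Gaussian
noise.  Attenuation ordering (AF > NP, NC > NP) is enforced at construction.

Geometry is a polygonal cylinder: each transverse section of the disc and NP
is a regular 128-gon (matching the segmentation resample count) with one
vertex on the +x ray, so arc-length resampling is exactly idempotent and
truth-boundary contours fed through the pipeline reproduce the truth masks
voxel for voxel on noise-free data — this is what makes exact end-to-end
volume recovery a meaningful test rather than a tolerance game.

The NC model: at compactness c ∈ [0, 1] the target NC volume (a fraction of
whole-disc volume, default 5%) is split equally across
round(1 + (1 − c)·K) spheres (K = 12 by default), placed uniformly at random
inside the NP without overlap by rejection sampling.  c = 1 gives a single
compact blob (the mature, condensed notochord); c → 0 gives up to 13
scattered blobs (the neonatal, diffuse morphology).  Since n equal spheres
of fixed total volume have total area ∝ n^(1/3), S.a./V. is non-increasing
in compactness by construction; placement randomness is keyed on
(seed, blob count) so equal blob counts give identical geometry — ties,
never spurious inversions.  `compactness_sweep` verifies the ordering and
retries with a fresh scatter seed before failing.

Defaults (chosen once for separability and realistic proportions; the
problem provides no attenuation calibration): grid 200³ voxels at 1 µm,
disc radius 80 µm, disc height 156 µm, NP radius 45 µm, intensities
NP = 60, AF = 120, NC = 200 arbitrary units, noise σ = 10 (the noisy
recovery experiments use σ = 14 = 10% of the NC–NP contrast), background 0.
The disc height is a multiple of 6 µm so a 6 µm rendering tiles the disc
exactly along the slice axis.  A single integer seed drives all randomness;
identical spec + seed is bit-identical.

Coarser renderings are block averages over integer voxel factors
(`render_at_spacing`), which preserves extent and attenuates noise exactly
as partial-volume averaging would; coarse truth labels use hierarchical
majority vote (disc, then NP within disc, then NC within NP) so nesting
survives downsampling.

What the phantom does *not* emulate: PMA diffusion chemistry, beam
hardening, ring artifacts, detector blur, non-cylindrical disc shape,
endplate curvature, or partial-volume texture inside compartments.  Passing
tests therefore establish the correctness of the algorithms under the
stated image model, not segmentation accuracy on real scans; threshold
choice on real data remains an operator decision.

## Statistics

* **ICC**: hand-implemented two-way mean-squares decomposition.  Default
  form is ICC(2,1) — two-way random effects, absolute agreement, single
  measurement — treating repeated contourings as random raters; ICC(3,1)
  (consistency) is selectable.  95% CIs use the McGraw–Wong F-distribution
  bounds (Satterthwaite df for the agreement form).  The implementation is
  cross-checked in the tests against an explicit sums-of-squares oracle and
  against `pingouin.intraclass_corr`.  Degenerate inputs: zero
  between-subject variance returns 0 with a warning; perfect agreement
  returns 1 with CI (1, 1).
* **Paired t, Pearson**: scipy, with explicit conventions at the
  zero-variance edge (identical pairs → t = 0, p = 1; constant nonzero
  difference → p = 0).  r² is reported alongside r, the convention for
  cross-instrument predictiveness.
* **One-way ANOVA + post hoc**: scipy `f_oneway`; pairwise comparisons by
  Tukey HSD (adjusted, default) or Fisher's protected LSD (unadjusted
  pairwise t on the pooled error mean square, to be read only when the
  omnibus test is significant).  The ambiguous phrase "Tukey's LSD" is
  resolved by implementing both and recording the choice in every report.
* **Cross-resolution report**: per-metric paired t and Pearson r² across
  matched samples from two resolutions, erroring on unmatched sample ids.

Calibration is part of the test suite: under seeded null simulations the
paired t and the ANOVA reject at ≈5% (accepted band 3–7% at 1000
replicates), Tukey p-values dominate LSD p-values, and the null ICC's CI
covers zero at ≈95% across replicates.

## Problem sizes and determinism

The end-to-end recovery experiments run at the full default 200³ grid; the
unit tests and the compactness/cross-resolution experiments use smaller
phantoms (96×120×120 and 120×132×132) that preserve every geometric ratio
that matters (blob radii ≥ 8 voxels, filter radius ≪ blob radius).  One
effect is genuinely scale-dependent: the radius-5 median filter erodes a
curvature-proportional shell from each NC blob, so the recovered NC volume
fraction is biased low by ≈10% at 8-voxel blob radii but only ≈3% at the
full-scale ≈20-voxel radii; the volume-recovery tolerance is therefore
asserted at full scale and the small phantoms check overlap (Dice) only.  All
simulations are seeded; the acceptance script derives every RNG stream from
its single `--seed` argument.

## Known limitations

* Vertex-correspondence morphing assumes roughly star-shaped contours;
  severely lobed outlines would need a different correspondence (e.g.
  optimal cyclic alignment).
* Absolute S.a./V. depends on the estimator; compare only values produced
  by the same estimator and resolution.
* DICOM reading expects a single-series directory with uniform slice
  spacing and standard mm units; RT-STRUCT contours and vendor private tags
  are out of scope (contours use this package's JSON schema).
* The NC threshold is per-sample and operator-owned; Otsu-within-NP is a
  suggestion, not an automation claim.
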