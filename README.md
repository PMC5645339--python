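# ivdmorph

Semi-automated segmentation and morphometry of the murine intervertebral
disc (IVD) from contrast-enhanced microCT.

Staining an excised spine segment with phosphomolybdic acid makes
collagen-rich soft tissue radio-opaque, so microCT resolves three disc
compartments: the annulus fibrosus (AF, bright outer ring), the nucleus
pulposus (NP, dark core), and the notochord remnant (NC), a bright,
irregular inclusion inside the NP whose morphology shifts with age from
diffuse and scattered to compact and block-like.  `ivdmorph` is for
researchers quantifying that development (or its disruption in disc
degeneration) in mouse models: it turns a stack plus a handful of manually
drawn contours into compartment volumes, percentages, and the NC shape
metric, and supplies the statistics needed to argue the measurements are
reliable.

## Pipeline

1. **I/O** — DICOM series, multi-page OME-TIFF or NIfTI-1 stacks with
   explicit µm voxel spacing; contours in a small versioned JSON schema.
2. **Preprocess** — spline resampling of coarse (e.g. 6 µm) scans onto the
   fine (1 µm) reference grid; median filter (radius 5, slice-wise disc).
3. **Segment** — the operator draws a disc-outline and an AF/NP-border
   polygon every ~30 slices; dense masks come from vertex-wise linear
   morphing of the contours, rasterized by the voxel-centre rule.
   AF = whole disc − NP.  The NC is thresholded *inside* the NP
   (Otsu-within-NP is suggested, the operator decides).
4. **Measure** — volumes V = (voxel count) × (voxel volume); compartment
   percentages of total disc volume (AF% + NP% = 100, NC% within NP); NC
   surface area from a smoothed marching-cubes mesh; and the shape metric

   S.a./V. = (NC surface area) / (NC volume)   [µm⁻¹]

   high for a diffuse, scattered notochord, low for a compact one.
5. **Statistics** — ICC(2,1) with 95% F-based CI for contouring
   reliability; paired t and Pearson r² for fine-vs-coarse scanner
   agreement; one-way ANOVA with Tukey HSD or Fisher LSD post hoc for age
   effects.

Because real scans of this kind are not publicly deposited, the package
ships a first-class phantom generator: synthetic discs with exact,
countable ground-truth masks, rendered at 1 µm and 6 µm with noise.  Every
pipeline stage is validated against those phantoms and against brute-force
oracles (see `docs/methods.md`).

## Worked example

Generate a noisy phantom, run the full pipeline on it, and compare with the
generator's ground truth:

```python
from ivdmorph import (PhantomSpec, generate_phantom, median_filter, build_masks,
                      truth_contours, suggest_nc_threshold, compartment_metrics, dice)

spec = PhantomSpec(grid_shape=(96, 120, 120), disc_radius_um=50, disc_height_um=72,
                   np_radius_um=30, nc_target_volume_fraction=0.05,
                   nc_compactness=0.7, noise_sd=10.0, seed=2)
stack, truth = generate_phantom(spec)

filtered = median_filter(stack, radius=5)
contours = truth_contours(spec, step=30)          # operator contours every 30 slices
suggestion = suggest_nc_threshold(filtered, truth.masks.np_)
print(f"suggested NC threshold: {suggestion.value:.1f}")

masks = build_masks(filtered, contours, nc_threshold=suggestion.value)
result = compartment_metrics(masks)
print(f"total volume: {result.total_volume_um3:,.0f} um^3")
print(f"AF {result.af_pct:.1f}%  NP {result.np_pct:.1f}%  NC {result.nc_pct:.2f}%")
print(f"NC S.a./V.: {result.nc_sa_to_v_per_um:.3f} per um")
print(f"NC Dice vs ground truth: {dice(masks.nc, truth.masks.nc):.3f}")
```

prints

```
suggested NC threshold: 129.2
total volume: 565,920 um^3
AF 64.0%  NP 36.0%  NC 4.52%
NC S.a./V.: 0.273 per um
NC Dice vs ground truth: 0.943
```

The suggested threshold falls midway between the NP (60) and NC (200)
intensity levels; the disc/NP volumes match the phantom geometry exactly
(the contours sit on the true boundaries), and the thresholded NC overlaps
the true inclusion at Dice 0.94 despite the noise.  A compactness of 0.7
splits the 5% NC volume across five blobs; sweeping compactness at fixed
volume lowers S.a./V. monotonically — the quantitative signature of the
notochord condensing with age.

The same flow is available from the shell:

```sh
ivdmorph phantom generate --spec spec.json --out ph/ --spacing-um 6
ivdmorph preprocess --in ph/stack_6um.nii --target-spacing-um 1 --median-radius 5 --out filtered.nii
ivdmorph segment --stack filtered.nii --contours ph/contours.json --suggest-threshold --out masks.nii
ivdmorph measure --masks masks.nii --out metrics.csv --mesh-out nc.stl
ivdmorph stats icc --table raters.csv
```

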