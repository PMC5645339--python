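"""Synthetic disc phantoms with exact ground truth.

The phantom emulates a PMA-stained murine intervertebral disc as imaged by
contrast-enhanced microCT: a bright annulus fibrosus (AF) ring surrounding a
dark nucleus pulposus (NP) core, with a bright notochord (NC) inclusion
embedded in the NP whose morphology ranges from scattered/diffuse (many small
blobs, high surface-area-to-volume) to compact (a single blob, low
S.a./V.) — the day-1 → day-10 shape transition, as a generator contract.
Attenuation ordering AF > NP and NC > NP is enforced.

Geometry is a polygonal cylinder: every transverse cross-section of the disc
and the NP is a regular polygon whose vertex count matches the segmentation
module's contour-resampling default, with one vertex on the +x ray from the
centre.  Ground-truth masks are produced by rasterizing those exact polygons,
so truth-boundary contours fed through the segmentation pipeline reproduce
the truth masks voxel for voxel on noise-free data.

The image model is the label geometry painted with per-compartment mean
intensities plus additive Gaussian noise; background (outside the disc) is 0.
CT physics (beam hardening, rings) is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .image_io import (
    DISC_OUTER,
    NP_BORDER,
    Contour,
    ContourSet,
    ImageStack,
    write_contours,
    write_stack,
)
from .morphometry import MorphometryResult, compartment_metrics, sa_to_v
from .segmentation import (
    DEFAULT_VERTEX_COUNT,
    CompartmentMasks,
    rasterize_polygon,
)


class PhantomSizingError(ValueError):
    """The requested geometry does not fit inside the grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic disc phantom.

    Attributes
    ----------
    grid_shape : (n_slices, n_rows, n_cols)
    voxel_spacing_um : per-axis spacing in µm
    disc_radius_um, disc_height_um : whole-disc cylinder dimensions
    np_radius_um : NP core radius, strictly less than ``disc_radius_um``
    nc_target_volume_fraction : NC volume as a fraction of whole-disc
        volume, in [0, 0.2]
    nc_compactness : 0 = scattered multi-blob inclusion, 1 = single blob
    nc_scatter_blobs : maximum extra blobs at compactness 0; the blob count
        is ``round(1 + (1 - compactness) * nc_scatter_blobs)``
    intensity_af, intensity_np, intensity_nc : mean grayscale levels;
        must satisfy AF > NP and NC > NP
    noise_sd : additive Gaussian noise standard deviation
    seed : integer RNG seed; every stochastic choice derives from it
    """

    grid_shape: tuple[int, int, int] = (200, 200, 200)
    voxel_spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    disc_radius_um: float = 80.0
    disc_height_um: float = 156.0
    np_radius_um: float = 45.0
    nc_target_volume_fraction: float = 0.05
    nc_compactness: float = 0.7
    nc_scatter_blobs: int = 12
    intensity_af: float = 120.0
    intensity_np: float = 60.0
    intensity_nc: float = 200.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(v) for v in self.grid_shape))
        object.__setattr__(
            self, "voxel_spacing_um", tuple(float(v) for v in self.voxel_spacing_um)
        )
        if any(n < 1 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel_spacing_um must be strictly positive")
        for name in ("disc_radius_um", "disc_height_um", "np_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.np_radius_um < self.disc_radius_um:
            raise ValueError("np_radius_um must be < disc_radius_um")
        if not 0.0 <= self.nc_target_volume_fraction <= 0.2:
            raise ValueError("nc_target_volume_fraction must lie in [0, 0.2]")
        if not 0.0 <= self.nc_compactness <= 1.0:
            raise ValueError("nc_compactness must lie in [0, 1]")
        if self.nc_scatter_blobs < 0:
            raise ValueError("nc_scatter_blobs must be >= 0")
        if not (self.intensity_af > self.intensity_np and self.intensity_nc > self.intensity_np):
            raise ValueError(
                "attenuation ordering violated: need intensity_af > intensity_np "
                "and intensity_nc > intensity_np"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_blobs(self) -> int:
        """Number of NC sub-blobs implied by the compactness level."""
        return int(round(1 + (1.0 - self.nc_compactness) * self.nc_scatter_blobs))

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class PhantomTruth:
    """Exact noise-free labels and reference metrics of one phantom."""

    masks: CompartmentMasks
    reference_metrics: MorphometryResult
    spec: PhantomSpec
    nc_centers_um: tuple[tuple[float, float, float], ...] = ()
    nc_blob_radius_um: float = 0.0

    def __post_init__(self) -> None:
        m = self.masks
        if np.any(m.nc & ~m.np_) or np.any(m.np_ & ~m.whole_disc):
            raise ValueError("truth masks violate NC ⊆ NP ⊆ whole-disc nesting")


# ---------------------------------------------------------------------------
# Geometry construction
# ---------------------------------------------------------------------------

def _cross_section_polygon(
    radius_um: float, center_um: tuple[float, float], n_vertices: int = DEFAULT_VERTEX_COUNT
) -> np.ndarray:
    """Regular ``n_vertices``-gon with a vertex on the +x ray from the centre."""
    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    return np.column_stack(
        [center_um[0] + radius_um * np.cos(theta), center_um[1] + radius_um * np.sin(theta)]
    )


def _disc_slice_span(spec: PhantomSpec) -> tuple[int, int]:
    """First and last slice index occupied by the disc (inclusive)."""
    sz = spec.voxel_spacing_um[0]
    h_slices = int(round(spec.disc_height_um / sz))
    if h_slices < 1:
        raise PhantomSizingError("disc_height_um is thinner than one slice")
    nz = spec.grid_shape[0]
    if h_slices > nz:
        raise PhantomSizingError(
            f"disc height {spec.disc_height_um} µm needs {h_slices} slices but the "
            f"grid has only {nz}"
        )
    lo = (nz - h_slices) // 2
    return lo, lo + h_slices - 1


def _inplane_center_um(spec: PhantomSpec) -> tuple[float, float]:
    _, sy, sx = spec.voxel_spacing_um
    _, ny, nx = spec.grid_shape
    return (nx * sx / 2.0, ny * sy / 2.0)


def _check_fits(spec: PhantomSpec) -> None:
    _, sy, sx = spec.voxel_spacing_um
    _, ny, nx = spec.grid_shape
    cx, cy = _inplane_center_um(spec)
    if spec.disc_radius_um > min(cx, nx * sx - cx, cy, ny * sy - cy):
        raise PhantomSizingError(
            f"disc radius {spec.disc_radius_um} µm exceeds the in-plane half-extent "
            f"of the {spec.grid_shape} grid at spacing {spec.voxel_spacing_um} µm"
        )
    _disc_slice_span(spec)  # raises if too tall


def truth_contours(spec: PhantomSpec, step: int = 30) -> ContourSet:
    """Truth-boundary contours drawn every ``step`` slices.

    Emulates the operator's sparse contouring on a phantom: disc-outline and
    AF/NP-border polygons at every ``step``-th occupied slice, with the last
    occupied slice always annotated so the interpolation span covers the
    whole disc.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    lo, hi = _disc_slice_span(spec)
    slices = sorted(set(range(lo, hi + 1, step)) | {hi})
    center = _inplane_center_um(spec)
    entries = []
    for s in slices:
        entries.append(Contour(DISC_OUTER, s, _cross_section_polygon(spec.disc_radius_um, center)))
        entries.append(Contour(NP_BORDER, s, _cross_section_polygon(spec.np_radius_um, center)))
    return ContourSet(tuple(entries))


def _truth_cylinder_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boolean whole-disc and NP volumes from the exact cross-section polygons."""
    nz, ny, nx = spec.grid_shape
    _, sy, sx = spec.voxel_spacing_um
    center = _inplane_center_um(spec)
    disc2d = rasterize_polygon(
        _cross_section_polygon(spec.disc_radius_um, center), (ny, nx), (sy, sx)
    )
    np2d = rasterize_polygon(
        _cross_section_polygon(spec.np_radius_um, center), (ny, nx), (sy, sx)
    )
    lo, hi = _disc_slice_span(spec)
    disc = np.zeros(spec.grid_shape, dtype=bool)
    np_mask = np.zeros(spec.grid_shape, dtype=bool)
    disc[lo : hi + 1] = disc2d
    np_mask[lo : hi + 1] = np2d
    return disc, np_mask


def _place_nc_blobs(
    spec: PhantomSpec, disc_voxels: int
) -> tuple[list[np.ndarray], float]:
    """Choose NC blob centres (µm) and the common blob radius.

    The target NC volume is split equally across ``spec.n_blobs`` spheres
    placed inside the NP without overlap; placement randomness derives from
    ``(seed, n_blobs)`` only, so equal blob counts at different compactness
    levels yield identical geometry (ties, never inversions, in the
    S.a./V.-vs-compactness contract).
    """
    frac = spec.nc_target_volume_fraction
    if frac == 0.0:
        return [], 0.0
    sz, sy, sx = spec.voxel_spacing_um
    voxel_um3 = sz * sy * sx
    target_um3 = frac * disc_voxels * voxel_um3
    n = spec.n_blobs
    radius = (3.0 * target_um3 / (4.0 * np.pi * n)) ** (1.0 / 3.0)
    min_spacing = max(spec.voxel_spacing_um)
    if radius < 2.0 * min_spacing:
        raise PhantomSizingError(
            f"NC blobs of radius {radius:.2f} µm are below 2 voxels at spacing "
            f"{min_spacing} µm; raise nc_target_volume_fraction or compactness"
        )
    cx, cy = _inplane_center_um(spec)
    lo, hi = _disc_slice_span(spec)
    z0, z1 = lo * sz, (hi + 1) * sz
    # keep blobs strictly inside the NP polygon (inradius) and disc height
    np_inradius = spec.np_radius_um * np.cos(np.pi / DEFAULT_VERTEX_COUNT)
    r_max = np_inradius - radius - min_spacing
    z_lo = z0 + radius + sz
    z_hi = z1 - radius - sz
    if r_max < 0 or z_lo >= z_hi:
        raise PhantomSizingError(
            f"{n} NC blob(s) of radius {radius:.2f} µm do not fit inside the NP "
            f"(radius {spec.np_radius_um} µm, height {spec.disc_height_um} µm)"
        )
    rng = np.random.default_rng([spec.seed, 0, n])
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 5000 * n:
            raise PhantomSizingError(
                f"could not place {n} non-overlapping NC blobs of radius "
                f"{radius:.2f} µm inside the NP after {attempts} attempts"
            )
        rr = r_max * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(z_lo, z_hi)
        cand = np.array([z, cy + rr * np.sin(th), cx + rr * np.cos(th)])
        gap = 2.0 * radius + min_spacing
        if all(np.linalg.norm(cand - c) >= gap for c in centers):
            centers.append(cand)
    return centers, radius


def _nc_mask(
    spec: PhantomSpec, centers: Sequence[np.ndarray], radius: float, np_mask: np.ndarray
) -> np.ndarray:
    nc = np.zeros(spec.grid_shape, dtype=bool)
    if not centers:
        return nc
    sz, sy, sx = spec.voxel_spacing_um
    r2 = radius * radius
    for c in centers:
        # voxel-centre-in-sphere test on the blob's bounding box only
        iz0 = max(int((c[0] - radius) / sz) - 1, 0)
        iz1 = min(int((c[0] + radius) / sz) + 2, spec.grid_shape[0])
        iy0 = max(int((c[1] - radius) / sy) - 1, 0)
        iy1 = min(int((c[1] + radius) / sy) + 2, spec.grid_shape[1])
        ix0 = max(int((c[2] - radius) / sx) - 1, 0)
        ix1 = min(int((c[2] + radius) / sx) + 2, spec.grid_shape[2])
        zc = (np.arange(iz0, iz1) + 0.5) * sz - c[0]
        yc = (np.arange(iy0, iy1) + 0.5) * sy - c[1]
        xc = (np.arange(ix0, ix1) + 0.5) * sx - c[2]
        d2 = zc[:, None, None] ** 2 + yc[None, :, None] ** 2 + xc[None, None, :] ** 2
        nc[iz0:iz1, iy0:iy1, ix0:ix1] |= d2 <= r2
    nc &= np_mask  # geometric placement guarantees this is a no-op
    return nc


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def build_truth(spec: PhantomSpec) -> PhantomTruth:
    """Construct the exact noise-free labels and reference metrics."""
    _check_fits(spec)
    disc, np_mask = _truth_cylinder_masks(spec)
    centers, radius = _place_nc_blobs(spec, int(disc.sum()))
    nc = _nc_mask(spec, centers, radius, np_mask)
    masks = CompartmentMasks(disc, disc & ~np_mask, np_mask, nc, spec.voxel_spacing_um)
    metrics = compartment_metrics(masks)
    return PhantomTruth(
        masks,
        metrics,
        spec,
        tuple(tuple(float(v) for v in c) for c in centers),
        float(radius),
    )


def _paint(spec: PhantomSpec, masks: CompartmentMasks) -> np.ndarray:
    img = np.zeros(spec.grid_shape, dtype=np.float64)
    img[masks.af] = spec.intensity_af
    img[masks.np_] = spec.intensity_np
    img[masks.nc] = spec.intensity_nc
    return img


def _native_noisy_image(spec: PhantomSpec, masks: CompartmentMasks) -> np.ndarray:
    img = _paint(spec, masks)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 1])
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img


def generate_phantom(spec: PhantomSpec) -> tuple[ImageStack, PhantomTruth]:
    """Generate a noisy disc phantom and its exact ground truth.

    Identical ``spec`` (including ``seed``) gives bit-identical output.
    Geometry that does not fit inside the grid raises
    :class:`PhantomSizingError`.
    """
    truth = build_truth(spec)
    stack = ImageStack(_native_noisy_image(spec, truth.masks), spec.voxel_spacing_um)
    return stack, truth


def _integer_factors(
    truth_spacing: Sequence[float], spacing_um: Sequence[float]
) -> tuple[int, int, int]:
    factors = []
    for want, have in zip(spacing_um, truth_spacing):
        if want < have - 1e-9:
            raise ValueError(
                f"requested spacing {want} µm is finer than the native {have} µm"
            )
        f = want / have
        if abs(f - round(f)) > 1e-6:
            raise ValueError(
                f"requested spacing {want} µm is not an integer multiple of the "
                f"native {have} µm; block-average resampling needs integer factors"
            )
        factors.append(int(round(f)))
    return tuple(factors)


def _block_reduce(arr: np.ndarray, factors: tuple[int, int, int], reduce: str) -> np.ndarray:
    fz, fy, fx = factors
    nz, ny, nx = (s // f for s, f in zip(arr.shape, factors))
    trimmed = arr[: nz * fz, : ny * fy, : nx * fx]
    blocks = trimmed.reshape(nz, fz, ny, fy, nx, fx)
    if reduce == "mean":
        return blocks.mean(axis=(1, 3, 5))
    if reduce == "fraction":
        return blocks.astype(np.float64).mean(axis=(1, 3, 5))
    raise ValueError(reduce)


def render_at_spacing(
    truth: PhantomTruth, spacing_um: Sequence[float] | float
) -> ImageStack:
    """Render the phantom on a coarser grid by block-average downsampling.

    Emulates scanning the same specimen on a lower-resolution system: the
    native noisy image (deterministic in the phantom seed) is averaged over
    integer voxel blocks, which preserves physical extent and attenuates
    noise exactly as partial-volume averaging would.  Native spacing returns
    the identical native stack.
    """
    if np.isscalar(spacing_um):
        spacing_um = (float(spacing_um),) * 3
    spacing_um = tuple(float(v) for v in spacing_um)
    factors = _integer_factors(truth.spec.voxel_spacing_um, spacing_um)
    native = _native_noisy_image(truth.spec, truth.masks)
    if factors == (1, 1, 1):
        return ImageStack(native, truth.spec.voxel_spacing_um)
    coarse = _block_reduce(native, factors, "mean")
    return ImageStack(coarse, spacing_um)


def downsample_truth_masks(
    truth: PhantomTruth, spacing_um: Sequence[float] | float
) -> CompartmentMasks:
    """Truth labels on a coarser grid by hierarchical majority vote.

    A coarse voxel belongs to the disc when >=50% of its fine voxels do;
    within the disc the same rule assigns NP, and within the NP the NC —
    the hierarchy preserves NC ⊆ NP ⊆ disc on the coarse grid.
    """
    if np.isscalar(spacing_um):
        spacing_um = (float(spacing_um),) * 3
    spacing_um = tuple(float(v) for v in spacing_um)
    factors = _integer_factors(truth.spec.voxel_spacing_um, spacing_um)
    disc = _block_reduce(truth.masks.whole_disc, factors, "fraction") >= 0.5
    np_mask = disc & (_block_reduce(truth.masks.np_, factors, "fraction") >= 0.5)
    nc = np_mask & (_block_reduce(truth.masks.nc, factors, "fraction") >= 0.5)
    return CompartmentMasks(disc, disc & ~np_mask, np_mask, nc, spacing_um)


def compactness_sweep(
    base: PhantomSpec, levels: Sequence[float], max_retries: int = 5
) -> list[PhantomTruth]:
    """Generate equal-NC-volume phantoms across compactness levels.

    ``levels`` must be sorted ascending in [0, 1]; the NC volume fraction is
    held fixed at ``base.nc_target_volume_fraction``.  The returned truths
    have non-increasing NC S.a./V. in compactness; if voxelization breaks the
    ordering the offending phantom is regenerated with a fresh scatter seed
    up to ``max_retries`` times, then an error is raised.
    """
    levels = list(levels)
    if any(not 0.0 <= c <= 1.0 for c in levels):
        raise ValueError("compactness levels must lie in [0, 1]")
    if levels != sorted(levels):
        raise ValueError("compactness levels must be sorted ascending")
    truths: list[PhantomTruth] = []
    prev_sav = np.inf
    for c in levels:
        spec = replace(base, nc_compactness=c)
        truth = build_truth(spec)
        sav = sa_to_v(truth.masks.nc, spec.voxel_spacing_um)
        retries = 0
        while sav > prev_sav and retries < max_retries:
            retries += 1
            spec = replace(spec, seed=spec.seed + 100_003)
            truth = build_truth(spec)
            sav = sa_to_v(truth.masks.nc, spec.voxel_spacing_um)
        if sav > prev_sav:
            raise RuntimeError(
                f"S.a./V. failed to be non-increasing at compactness {c} after "
                f"{max_retries} scatter-seed retries"
            )
        truths.append(truth)
        prev_sav = sav
    return truths


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_phantom(
    truth: PhantomTruth,
    out_dir: str | Path,
    stack: ImageStack | None = None,
    format: str = "nifti",
    contour_step: int = 30,
) -> dict[str, Path]:
    """Write a phantom to disk: image, truth labels, contours, JSON sidecar.

    Truth masks go out as an unsigned-8-bit label volume (0 background,
    1 AF, 2 NP, 3 NC); the sidecar records the spec and reference metrics.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"nifti": ".nii", "tiff": ".tif"}[format]
    if stack is None:
        stack, _ = generate_phantom(truth.spec)
    paths = {
        "stack": write_stack(stack, out_dir / f"stack{ext}", format),
        "labels": write_stack(
            ImageStack(truth.masks.label_volume(), truth.masks.spacing_um),
            out_dir / f"truth_labels{ext}",
            format,
        ),
        "contours": write_contours(
            truth_contours(truth.spec, contour_step), out_dir / "contours.json"
        ),
    }
    sidecar = out_dir / "phantom.json"
    sidecar.write_text(
        json.dumps(
            {
                "spec": json.loads(truth.spec.to_json()),
                "reference_metrics": truth.reference_metrics.as_dict(),
                "nc_blob_radius_um": truth.nc_blob_radius_um,
                "nc_centers_um": [list(c) for c in truth.nc_centers_um],
            },
            indent=1,
        )
    )
    paths["sidecar"] = sidecar
    return paths
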