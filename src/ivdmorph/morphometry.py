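"""Voxel volumetry and surface-area-to-volume shape metrics.

Volumes are voxel counts times the physical voxel volume.  Compartment
volumes are additionally normalised to a percentage of total disc volume so
discs of different sizes can be compared; the NP percentage is reported
inclusive of its embedded NC (so AF% + NP% = 100), with the NC percentage
reported separately.

The notochord's surface-area-to-volume ratio (S.a./V., µm⁻¹) is the shape
metric: a high value means a diffuse, scattered structure with more surface
than bulk; a low value means a compact, block-like structure.

Two surface-area estimators are provided.  The primary ``mesh`` method
pre-smooths the binary mask with a small Gaussian and triangulates the 0.5
iso-surface (marching cubes): counting exposed voxel faces overestimates a
smooth surface by up to ~50%, and meshing the raw binary mask still
overestimates a sphere by ~9%, while the smoothed mesh is within a couple of
percent at radii of ten voxels and converges as the structure grows.  The
exact combinatorial ``voxel_faces`` count is retained as a cross-check
oracle for axis-aligned shapes (a cube's exposed-face area is exactly 6L²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .segmentation import CompartmentMasks


class MorphometryError(ValueError):
    pass


CSV_COLUMNS = [
    "sample_id",
    "total_volume_um3",
    "af_volume_um3",
    "np_volume_um3",
    "nc_volume_um3",
    "af_pct",
    "np_pct",
    "nc_pct",
    "nc_surface_area_um2",
    "nc_sa_to_v_per_um",
]


@dataclass(frozen=True)
class MorphometryResult:
    """Absolute and normalised compartment morphometry of one disc."""

    total_volume_um3: float
    af_volume_um3: float
    np_volume_um3: float
    nc_volume_um3: float
    af_pct: float
    np_pct: float
    nc_pct: float
    nc_surface_area_um2: float  # NaN when the NC mask is empty
    nc_sa_to_v_per_um: float    # NaN when the NC mask is empty

    def __post_init__(self) -> None:
        if self.total_volume_um3 <= 0:
            raise MorphometryError("total disc volume must be positive")
        for name in ("af_volume_um3", "np_volume_um3", "nc_volume_um3"):
            if getattr(self, name) < 0:
                raise MorphometryError(f"{name} must be >= 0")
        if not np.isclose(
            self.af_volume_um3 + self.np_volume_um3,
            self.total_volume_um3,
            rtol=1e-9,
            atol=0.0,
        ):
            raise MorphometryError("AF + NP volume must equal the total disc volume")
        if abs(self.af_pct + self.np_pct - 100.0) > 1e-9 * 100.0:
            raise MorphometryError("AF% + NP% must equal 100")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in CSV_COLUMNS[1:]}

    def as_row(self, sample_id: str) -> dict[str, object]:
        return {"sample_id": sample_id, **self.as_dict()}


def volume(mask: np.ndarray, spacing_um: Sequence[float]) -> float:
    """Mask volume in µm³: voxel count times per-voxel volume."""
    mask = np.asarray(mask, bool)
    spacing = tuple(float(s) for s in spacing_um)
    if any(s <= 0 for s in spacing):
        raise MorphometryError(f"spacing must be positive, got {spacing_um}")
    return float(int(mask.sum()) * np.prod(spacing))


def surface_area(
    mask: np.ndarray,
    spacing_um: Sequence[float],
    method: str = "mesh",
    smooth_sigma: float = 1.0,
) -> float:
    """Surface area of a boolean mask in µm².

    Parameters
    ----------
    method : {'mesh', 'voxel_faces'}
        ``mesh``: triangle area of the 0.5 iso-surface of the (Gaussian
        pre-smoothed) mask, vertices scaled to physical µm.  ``voxel_faces``:
        exact exposed-face area.
    smooth_sigma : float
        Pre-smoothing sigma in voxels for the mesh method; falls back to the
        unsmoothed surface (with a warning) when the structure is thinner
        than the kernel.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise MorphometryError(
            "surface area of an empty mask is undefined; report S.a./V. as missing"
        )
    spacing = tuple(float(s) for s in spacing_um)
    if method == "voxel_faces":
        return _voxel_face_area(mask, spacing)
    if method != "mesh":
        raise ValueError(f"unknown method {method!r}")
    from scipy.ndimage import gaussian_filter
    from skimage.measure import marching_cubes, mesh_surface_area

    f = np.pad(mask.astype(np.float32), 1)
    if smooth_sigma > 0:
        smoothed = gaussian_filter(f, smooth_sigma)
        if smoothed.max() <= 0.5:
            warnings.warn(
                "structure thinner than the smoothing kernel; meshing the raw mask",
                UserWarning,
                stacklevel=2,
            )
        else:
            f = smoothed
    verts, faces, _, _ = marching_cubes(f, level=0.5, spacing=spacing)
    return float(mesh_surface_area(verts, faces))


def _voxel_face_area(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    padded = np.pad(mask, 1)
    total = 0.0
    for axis in range(3):
        face = np.prod([s for i, s in enumerate(spacing) if i != axis])
        total += float(np.count_nonzero(np.diff(padded, axis=axis))) * face
    return total


def sa_to_v(
    mask: np.ndarray,
    spacing_um: Sequence[float],
    method: str = "mesh",
    smooth_sigma: float = 1.0,
) -> float:
    """Surface-area-to-volume ratio in µm⁻¹; NaN for an empty mask."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        return float("nan")
    return surface_area(mask, spacing_um, method, smooth_sigma) / volume(mask, spacing_um)


def compartment_metrics(masks: CompartmentMasks) -> MorphometryResult:
    """All morphometry fields for one compartment segmentation."""
    sp = masks.spacing_um
    total = volume(masks.whole_disc, sp)
    if total == 0:
        raise MorphometryError("whole-disc mask is empty; total volume is zero")
    af = volume(masks.af, sp)
    np_vol = volume(masks.np_, sp)
    nc_vol = volume(masks.nc, sp)
    if masks.nc.any():
        area = surface_area(masks.nc, sp, method="mesh")
        ratio = area / nc_vol
    else:
        area = float("nan")
        ratio = float("nan")
    return MorphometryResult(
        total_volume_um3=total,
        af_volume_um3=af,
        np_volume_um3=np_vol,
        nc_volume_um3=nc_vol,
        af_pct=100.0 * af / total,
        np_pct=100.0 * np_vol / total,
        nc_pct=100.0 * nc_vol / total,
        nc_surface_area_um2=area,
        nc_sa_to_v_per_um=ratio,
    )


def export_nc_mesh(
    mask: np.ndarray,
    spacing_um: Sequence[float],
    path: str | Path,
    smooth_sigma: float = 1.0,
) -> Path:
    """Export the NC iso-surface as an STL mesh (for 3-D rendering)."""
    import trimesh
    from scipy.ndimage import gaussian_filter
    from skimage.measure import marching_cubes

    mask = np.asarray(mask, bool)
    if not mask.any():
        raise MorphometryError("cannot mesh an empty mask")
    f = np.pad(mask.astype(np.float32), 1)
    if smooth_sigma > 0:
        smoothed = gaussian_filter(f, smooth_sigma)
        if smoothed.max() > 0.5:
            f = smoothed
    verts, faces, _, _ = marching_cubes(f, level=0.5, spacing=tuple(spacing_um))
    mesh = trimesh.Trimesh(vertices=verts, faces=faces)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)
    return path
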