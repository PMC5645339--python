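"""Reading and writing CT stacks and contour annotations.

Stacks are 3-D grayscale volumes with explicit per-axis voxel spacing in
micrometres, ordered ``(slice, row, column)``.  Supported on-disk formats are
DICOM series (read-only), multi-page OME-TIFF and NIfTI-1 (read/write).
Contours — the manually drawn disc-outline and AF/NP-border polygons — are
interchanged as a small versioned JSON schema (see :func:`read_contours`).

Coordinate convention: voxel indices are 0-based; a vertex at physical
coordinate ``x`` µm lies at voxel index ``x / spacing``; voxel ``(i, j)``
covers the half-open square ``[j, j+1) x [i, i+1)`` in voxel units, so its
centre sits at ``(j + 0.5, i + 0.5)``.  In-plane vertex coordinates are
``(x, y)`` with ``x`` along the column axis and ``y`` along the row axis.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

DISC_OUTER = "disc_outer"
NP_BORDER = "np_border"
CONTOUR_LABELS = (DISC_OUTER, NP_BORDER)

CONTOUR_SCHEMA_VERSION = 1

_MICRON_ALIASES = {"um", "µm", "micron", "microns", "micrometer", "micrometre"}


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ContourSchemaError(FormatError):
    """A contour JSON file violates the documented schema."""


@dataclass(frozen=True)
class ImageStack:
    """A 3-D grayscale intensity volume with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Grayscale intensities in arbitrary attenuation units.
    spacing_um : tuple of float
        Voxel spacing per axis ``(slice, row, col)`` in µm; strictly positive.
    intensity_units : str
        Free-text unit label; microCT attenuation is uncalibrated here.
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]
    intensity_units: str = "a.u."

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or vox.shape[0] < 1:
            raise ValueError(f"stack must be 3-D with >=1 slice, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("stack contains non-finite intensities")
        spacing = tuple(float(s) for s in self.spacing_um)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing_um must be 3 positive values, got {self.spacing_um}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing_um", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def physical_extent_um(self) -> tuple[float, float, float]:
        """Physical size of the volume per axis in µm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_um))


@dataclass(frozen=True)
class Contour:
    """One closed planar polygon at a fixed slice index.

    ``vertices`` is an ``(n, 2)`` array of ``(x, y)`` positions in µm with the
    closing vertex repeated (``vertices[0] == vertices[-1]``).
    """

    label: str
    slice_index: int
    vertices: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in CONTOUR_LABELS:
            raise ContourSchemaError(
                f"unknown contour label {self.label!r}; expected one of {CONTOUR_LABELS}"
            )
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise ContourSchemaError(f"vertices must be (n, 2), got shape {verts.shape}")
        if not np.allclose(verts[0], verts[-1]):
            verts = np.vstack([verts, verts[:1]])  # store closed
        if len(verts) - 1 < 3:
            raise ContourSchemaError(
                f"polygon at ({self.label!r}, slice {self.slice_index}) has "
                f"{len(verts) - 1} vertices; need >=3"
            )
        if not np.all(np.isfinite(verts)):
            raise ContourSchemaError(
                f"polygon at ({self.label!r}, slice {self.slice_index}) has non-finite vertices"
            )
        if not _polygon_is_simple(verts):
            raise ContourSchemaError(
                f"polygon at ({self.label!r}, slice {self.slice_index}) is self-intersecting"
            )
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "slice_index", int(self.slice_index))

    @property
    def ring(self) -> np.ndarray:
        """Vertices without the repeated closing vertex."""
        return self.vertices[:-1]


@dataclass(frozen=True)
class ContourSet:
    """Labelled sparse-slice contour annotations for one stack."""

    entries: tuple[Contour, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        entries = tuple(
            sorted(self.entries, key=lambda c: (c.label, c.slice_index))
        )
        seen: set[tuple[str, int]] = set()
        for c in entries:
            key = (c.label, c.slice_index)
            if key in seen:
                raise ContourSchemaError(f"duplicate contour for {key}")
            seen.add(key)
        _check_containment(entries)
        object.__setattr__(self, "entries", entries)

    def for_label(self, label: str) -> list[Contour]:
        return [c for c in self.entries if c.label == label]

    def slice_indices(self, label: str) -> list[int]:
        return [c.slice_index for c in self.for_label(label)]

    def __len__(self) -> int:
        return len(self.entries)


def _polygon_is_simple(closed_vertices: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    poly = Polygon(closed_vertices)
    return poly.is_valid and poly.is_simple and poly.area > 0


def _check_containment(entries: Sequence[Contour]) -> None:
    """At slices carrying both labels the NP border must lie inside the disc edge."""
    from shapely.geometry import Polygon

    by_slice: dict[int, dict[str, Contour]] = {}
    for c in entries:
        by_slice.setdefault(c.slice_index, {})[c.label] = c
    for s, labelled in by_slice.items():
        if DISC_OUTER in labelled and NP_BORDER in labelled:
            outer = Polygon(labelled[DISC_OUTER].vertices)
            inner = Polygon(labelled[NP_BORDER].vertices)
            if not outer.covers(inner):
                raise ContourSchemaError(
                    f"np_border polygon at slice {s} is not contained in the "
                    f"disc_outer polygon at the same slice"
                )


# ---------------------------------------------------------------------------
# Stack I/O
# ---------------------------------------------------------------------------

def read_stack(path: str | Path, format: str | None = None) -> ImageStack:
    """Read a CT stack from a DICOM series directory, a TIFF or a NIfTI file.

    Parameters
    ----------
    path : path
        A directory (DICOM series) or a single file.
    format : {'dicom_series', 'tiff', 'nifti'}, optional
        Inferred from the path when omitted.

    Returns
    -------
    ImageStack
        Spacing is taken from format metadata; missing or inconsistent
        spacing raises :class:`FormatError` — there are no silent defaults.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "dicom_series":
        return _read_dicom_series(path)
    if fmt == "tiff":
        return _read_tiff(path)
    if fmt == "nifti":
        return _read_nifti(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_stack(stack: ImageStack, path: str | Path, format: str | None = None) -> Path:
    """Write a stack as OME-TIFF or NIfTI-1 with spacing recorded in metadata.

    Lossless for integer data. DICOM writing is out of scope.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff":
        _write_tiff(stack, path)
    elif fmt == "nifti":
        _write_nifti(stack, path)
    elif fmt == "dicom_series":
        raise ValueError("DICOM writing is not supported")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if path.is_dir():
        return "dicom_series"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".dcm"):
        return "dicom_series"
    raise ValueError(f"cannot infer stack format from {path}")


def _read_dicom_series(path: Path) -> ImageStack:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm") if path.is_dir() else [path]
    if not files:
        raise FormatError(f"no .dcm files found under {path}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise FormatError(f"mixed DICOM series in {path}: SeriesInstanceUIDs {sorted(map(str, uids))}")

    for ds in datasets:
        if not hasattr(ds, "PixelSpacing") or not hasattr(ds, "ImagePositionPatient"):
            raise FormatError(
                "DICOM slice missing PixelSpacing or ImagePositionPatient; "
                "cannot establish voxel spacing"
            )
    pixel_spacings = {tuple(float(v) for v in ds.PixelSpacing) for ds in datasets}
    if len(pixel_spacings) != 1:
        raise FormatError(f"inconsistent in-plane PixelSpacing across series: {pixel_spacings}")
    row_mm, col_mm = pixel_spacings.pop()

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(zs) < 2:
        raise FormatError("DICOM series needs >=2 slices to establish slice spacing")
    steps = np.diff(zs)
    if np.any(steps <= 0):
        raise FormatError("duplicate or non-monotone DICOM slice positions")
    if (steps.max() - steps.min()) > 1e-3 * steps.mean():
        raise FormatError(
            f"non-uniform DICOM slice spacing: steps range "
            f"{steps.min():.6g}..{steps.max():.6g} mm (a slice may be missing)"
        )
    slice_mm = float(steps.mean())

    vox = np.stack([ds.pixel_array for ds in datasets])
    # DICOM spatial attributes are in mm; convert to µm.
    spacing_um = (slice_mm * 1000.0, row_mm * 1000.0, col_mm * 1000.0)
    return ImageStack(vox, spacing_um)


def _write_tiff(stack: ImageStack, path: Path) -> None:
    import tifffile

    sz, sy, sx = stack.spacing_um
    tifffile.imwrite(
        path,
        stack.voxels,
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": sz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": sy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": sx,
            "PhysicalSizeXUnit": "µm",
        },
    )


def _read_tiff(path: Path) -> ImageStack:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        vox = tf.asarray()
        ome = tf.ome_metadata
    if vox.ndim == 2:
        vox = vox[None]
    if vox.ndim != 3:
        raise FormatError(f"TIFF at {path} decodes to shape {vox.shape}; expected a 3-D stack")
    if ome is None:
        raise FormatError(f"TIFF at {path} carries no OME metadata; voxel spacing unknown")
    spacing = _spacing_from_ome(ome, path)
    return ImageStack(vox, spacing)


def _spacing_from_ome(ome_xml: str, path: Path) -> tuple[float, float, float]:
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        raise FormatError(f"OME metadata in {path} has no Pixels element")
    out = []
    for axis in ("Z", "Y", "X"):
        val = pixels.get(f"PhysicalSize{axis}")
        unit = (pixels.get(f"PhysicalSize{axis}Unit") or "µm").lower()
        if val is None:
            raise FormatError(f"OME metadata in {path} lacks PhysicalSize{axis}")
        if unit not in _MICRON_ALIASES:
            raise FormatError(f"unsupported spacing unit {unit!r} in {path}; expected µm")
        out.append(float(val))
    return tuple(out)


def _write_nifti(stack: ImageStack, path: Path) -> None:
    import nibabel as nib

    sz, sy, sx = stack.spacing_um
    # nibabel's fastest-varying axis first: store as (col, row, slice)
    data = np.ascontiguousarray(stack.voxels.T)
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_xyzt_units(xyz="micron")
    nib.save(img, str(path))


def _read_nifti(path: Path) -> ImageStack:
    import nibabel as nib

    img = nib.load(str(path))
    xyz_unit, _ = img.header.get_xyzt_units()
    if xyz_unit not in ("micron", "um"):
        raise FormatError(
            f"NIfTI at {path} declares spatial units {xyz_unit!r}; this pipeline "
            f"requires explicit micron units (no silent defaults)"
        )
    sx, sy, sz = (float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"NIfTI at {path} has shape {data.shape}; expected 3-D")
    return ImageStack(np.ascontiguousarray(data.T), (sz, sy, sx))


# ---------------------------------------------------------------------------
# Contour I/O
# ---------------------------------------------------------------------------

def read_contours(path: str | Path) -> ContourSet:
    """Read a contour annotation file (JSON).

    Schema (``schema_version`` 1)::

        {
          "schema_version": 1,
          "units": "um" | "voxel",
          "voxel_spacing_um": [row_um, col_um],   # required when units == "voxel"
          "contours": [
            {"label": "disc_outer" | "np_border",
             "slice": <int>,
             "vertices": [[x, y], ...]}           # closed or open ring
          ]
        }

    Vertices are converted to µm using the file's declared units.  Validation
    errors (self-intersection, <3 vertices, duplicate (label, slice), NP
    border outside the disc outline) raise :class:`ContourSchemaError` naming
    the offending entry.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    version = doc.get("schema_version")
    if version != CONTOUR_SCHEMA_VERSION:
        raise ContourSchemaError(
            f"unsupported schema_version {version!r}; expected {CONTOUR_SCHEMA_VERSION}"
        )
    units = doc.get("units", "um")
    if units in _MICRON_ALIASES:
        scale = np.array([1.0, 1.0])
    elif units == "voxel":
        spacing = doc.get("voxel_spacing_um")
        if spacing is None or len(spacing) != 2:
            raise ContourSchemaError(
                "units == 'voxel' requires voxel_spacing_um: [row_um, col_um]"
            )
        row_um, col_um = (float(v) for v in spacing)
        scale = np.array([col_um, row_um])  # vertices are (x, y) = (col, row)
    else:
        raise ContourSchemaError(f"unknown units {units!r}; expected 'um' or 'voxel'")

    entries = []
    for i, item in enumerate(doc.get("contours", [])):
        try:
            verts = np.asarray(item["vertices"], dtype=float) * scale
            entries.append(Contour(item["label"], int(item["slice"]), verts))
        except (KeyError, TypeError) as exc:
            raise ContourSchemaError(f"malformed contour entry #{i}: {exc}") from exc
    return ContourSet(tuple(entries))


def write_contours(contours: ContourSet, path: str | Path) -> Path:
    """Write a ContourSet to the JSON interchange format (always in µm)."""
    path = Path(path)
    doc = {
        "schema_version": CONTOUR_SCHEMA_VERSION,
        "units": "um",
        "contours": [
            {
                "label": c.label,
                "slice": c.slice_index,
                "vertices": np.asarray(c.vertices).tolist(),
            }
            for c in contours.entries
        ],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1))
    return path
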