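"""Sparse-contour segmentation of the disc into AF, NP and NC compartments.

The workflow mirrors semi-automated contouring of contrast-enhanced microCT:
an operator draws a disc-outline and an AF/NP-border polygon every ~30
transverse slices; the polygons are morphed by linear inter-slice
interpolation into dense per-slice polygons, rasterized into solid whole-disc
and NP masks, the AF is the set difference, and the highly attenuating
notochord (NC) is extracted by thresholding *inside* the NP mask (the AF
attenuates similarly to the NC, so an unrestricted threshold would leak).

Polygon correspondence for morphing: both bracketing polygons are resampled
to a fixed vertex count by arc length, counter-clockwise, starting at the
boundary point hit by the +x ray from the polygon centroid; interpolation is
then vertex-wise linear.  This is deterministic and exact for star-shaped
disc contours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np

from .image_io import DISC_OUTER, NP_BORDER, Contour, ContourSet, ImageStack

DEFAULT_VERTEX_COUNT = 128


class SegmentationError(ValueError):
    """Raised when contours or masks cannot form a valid segmentation."""


class LowSeparabilityWarning(UserWarning):
    """The NP interior histogram shows no clear bright (NC) class."""


@dataclass(frozen=True)
class CompartmentMasks:
    """Co-registered boolean masks for whole disc, AF, NP and NC.

    Invariants (validated on construction): nc ⊆ np ⊆ whole_disc,
    af = whole_disc AND NOT np, all masks share one grid and spacing.
    """

    whole_disc: np.ndarray
    af: np.ndarray
    np_: np.ndarray
    nc: np.ndarray
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        masks = {
            "whole_disc": np.asarray(self.whole_disc, bool),
            "af": np.asarray(self.af, bool),
            "np_": np.asarray(self.np_, bool),
            "nc": np.asarray(self.nc, bool),
        }
        shapes = {m.shape for m in masks.values()}
        if len(shapes) != 1:
            raise SegmentationError(f"masks must share one grid, got shapes {shapes}")
        spacing = tuple(float(s) for s in self.spacing_um)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise SegmentationError(f"spacing_um must be 3 positive values, got {self.spacing_um}")
        if np.any(masks["np_"] & ~masks["whole_disc"]):
            raise SegmentationError("NP mask is not contained in the whole-disc mask")
        if np.any(masks["nc"] & ~masks["np_"]):
            raise SegmentationError("NC mask is not contained in the NP mask")
        if np.any(masks["af"] != (masks["whole_disc"] & ~masks["np_"])):
            raise SegmentationError("AF mask must equal whole_disc AND NOT np")
        for k, v in masks.items():
            object.__setattr__(self, k, v)
        object.__setattr__(self, "spacing_um", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.whole_disc.shape

    def label_volume(self) -> np.ndarray:
        """Encode the compartments as uint8 labels 0=bg, 1=AF, 2=NP, 3=NC."""
        out = np.zeros(self.shape, dtype=np.uint8)
        out[self.af] = 1
        out[self.np_] = 2
        out[self.nc] = 3
        return out

    @classmethod
    def from_label_volume(
        cls, labels: np.ndarray, spacing_um: tuple[float, float, float]
    ) -> "CompartmentMasks":
        labels = np.asarray(labels)
        nc = labels == 3
        np_ = (labels == 2) | nc
        af = labels == 1
        return cls(af | np_, af, np_, nc, spacing_um)


class ThresholdSuggestion(NamedTuple):
    value: float
    low_separability: bool


# ---------------------------------------------------------------------------
# Polygon machinery
# ---------------------------------------------------------------------------

def _as_ring(polygon: np.ndarray) -> np.ndarray:
    """Return an open (n, 2) ring from open or closed vertex input."""
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise SegmentationError(f"polygon must be (n, 2), got shape {verts.shape}")
    if len(verts) > 1 and np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    if len(verts) < 3:
        raise SegmentationError(f"polygon needs >=3 distinct vertices, got {len(verts)}")
    return verts


def _signed_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _centroid(ring: np.ndarray) -> np.ndarray:
    """Area centroid by the shoelace formula."""
    x, y = ring[:, 0], ring[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * np.sum(cross)
    if abs(area) < 1e-300:
        return ring.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    return np.array([cx, cy])


def _ray_start_point(ring: np.ndarray) -> tuple[int, float]:
    """Locate the boundary point hit by the +x ray from the centroid.

    Returns ``(edge_index, t)``: the crossing lies on the edge from vertex
    ``edge_index`` to the next vertex at fractional position ``t``.
    """
    c = _centroid(ring)
    n = len(ring)
    best: tuple[float, int, float] | None = None  # (distance, edge, t)
    for i in range(n):
        p, q = ring[i] - c, ring[(i + 1) % n] - c
        dy = q[1] - p[1]
        if dy == 0.0:
            if p[1] == 0.0:  # horizontal edge on the ray
                for t, pt in ((0.0, p), (1.0, q)):
                    if pt[0] > 0 and (best is None or pt[0] < best[0]):
                        best = (pt[0], i, t)
            continue
        t = -p[1] / dy
        if 0.0 <= t < 1.0:
            x = p[0] + t * (q[0] - p[0])
            if x > 0 and (best is None or x < best[0]):
                best = (x, i, t)
    if best is None:
        # centroid outside (very non-star polygon): fall back to vertex 0
        return 0, 0.0
    return best[1], best[2]


def resample_polygon(polygon: np.ndarray, n_vertices: int = DEFAULT_VERTEX_COUNT) -> np.ndarray:
    """Resample a polygon to ``n_vertices`` equally spaced by arc length.

    The output ring is counter-clockwise and starts at the boundary point on
    the +x ray from the centroid, giving a canonical vertex correspondence
    for vertex-wise morphing.  Resampling a regular ``n_vertices``-gon that
    has a vertex on that ray is exactly idempotent.
    """
    ring = _as_ring(polygon)
    if _signed_area(ring) < 0:
        ring = ring[::-1]
    edge, t = _ray_start_point(ring)
    # rotate so the ring starts at the crossing edge, then drop arc before it
    ring = np.roll(ring, -edge, axis=0)
    start = ring[0] + t * (ring[1 % len(ring)] - ring[0])
    pts = np.vstack([start, ring[1:], ring[:1]])  # start .. around .. back to v0
    # snap: if start coincides with a vertex, avoid a zero-length segment
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seglen > 1e-12])
    pts = pts[keep]
    closed = np.vstack([pts, pts[:1]])
    seglen = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total <= 0:
        raise SegmentationError("degenerate polygon with zero perimeter")
    targets = np.arange(n_vertices) * (total / n_vertices)
    idx = np.searchsorted(arclen, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seglen) - 1)
    frac = (targets - arclen[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
    out = closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])
    return out


def interpolate_contours(
    contours: ContourSet,
    label: str,
    slice_range: Iterable[int],
    n_vertices: int = DEFAULT_VERTEX_COUNT,
) -> dict[int, np.ndarray]:
    """Morph sparse contours into a dense per-slice polygon dictionary.

    For each requested slice the bracketing annotated polygons are resampled
    to ``n_vertices`` canonical vertices and blended vertex-wise linearly in
    the slice index.  Annotated slices return the resampled version of their
    own polygon, so the map is continuous in the slice index.

    Raises
    ------
    SegmentationError
        If fewer than 2 contours exist for the label, or a requested slice
        lies outside the annotated span (no extrapolation).
    """
    anns = contours.for_label(label)
    if len(anns) < 2:
        raise SegmentationError(
            f"label {label!r} has {len(anns)} annotated slice(s); need >=2 to interpolate"
        )
    slices = np.array([c.slice_index for c in anns])
    polys = [resample_polygon(c.ring, n_vertices) for c in anns]
    lo, hi = slices[0], slices[-1]
    out: dict[int, np.ndarray] = {}
    for s in slice_range:
        if s < lo or s > hi:
            raise SegmentationError(
                f"slice {s} outside annotated span [{lo}, {hi}] for label {label!r}; "
                f"extrapolation is not performed"
            )
        j = int(np.searchsorted(slices, s, side="right"))
        if slices[j - 1] == s:
            out[s] = polys[j - 1].copy()
            continue
        s0, s1 = slices[j - 1], slices[j]
        t = (s - s0) / (s1 - s0)
        out[s] = (1.0 - t) * polys[j - 1] + t * polys[j]
    return out


def rasterize_polygon(
    polygon: np.ndarray,
    grid_shape: tuple[int, int],
    spacing_um: tuple[float, float],
) -> np.ndarray:
    """Rasterize a closed polygon (µm coordinates) onto a 2-D voxel grid.

    A voxel is included iff its centre lies inside the polygon by the
    even-odd rule; centres exactly on an edge count as inside (reproducible
    counts).  The polygon must lie within the grid's physical bounds.
    """
    ring = _as_ring(polygon)
    n_rows, n_cols = (int(v) for v in grid_shape)
    row_um, col_um = (float(v) for v in spacing_um)
    # work in voxel units
    vx = ring[:, 0] / col_um
    vy = ring[:, 1] / row_um
    bad = (vx < 0) | (vx > n_cols) | (vy < 0) | (vy > n_rows)
    if np.any(bad):
        offenders = ring[bad][:5].tolist()
        raise SegmentationError(
            f"polygon exits the grid (shape {grid_shape}, spacing {spacing_um} µm); "
            f"offending vertices (µm): {offenders}"
        )
    from matplotlib.path import Path as MplPath

    verts = np.column_stack([vx, vy])
    path = MplPath(np.vstack([verts, verts[:1]]), closed=True)

    j0, j1 = int(np.floor(vx.min() - 0.5)), int(np.ceil(vx.max() + 0.5))
    i0, i1 = int(np.floor(vy.min() - 0.5)), int(np.ceil(vy.max() + 0.5))
    j0, i0 = max(j0, 0), max(i0, 0)
    j1, i1 = min(j1, n_cols), min(i1, n_rows)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    if j1 <= j0 or i1 <= i0:
        return mask
    xs = np.arange(j0, j1) + 0.5
    ys = np.arange(i0, i1) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    eps = 1e-9
    # union of the two signed dilations makes edge-centred ties inside,
    # independent of path orientation
    inside = path.contains_points(pts, radius=eps) | path.contains_points(pts, radius=-eps)
    mask[i0:i1, j0:j1] = inside.reshape(i1 - i0, j1 - j0)
    return mask


# ---------------------------------------------------------------------------
# Mask building
# ---------------------------------------------------------------------------

def _label_mask_volume(
    contours: ContourSet,
    label: str,
    shape: tuple[int, int, int],
    spacing_um: tuple[float, float, float],
    n_vertices: int,
) -> np.ndarray:
    slices = contours.slice_indices(label)
    lo = max(slices[0], 0)
    hi = min(slices[-1], shape[0] - 1)
    vol = np.zeros(shape, dtype=bool)
    if hi < lo:
        return vol
    dense = interpolate_contours(contours, label, range(lo, hi + 1), n_vertices)
    for s, poly in dense.items():
        vol[s] = rasterize_polygon(poly, shape[1:], spacing_um[1:])
    return vol


def build_masks(
    stack: ImageStack,
    contours: ContourSet,
    nc_threshold: float,
    n_vertices: int = DEFAULT_VERTEX_COUNT,
) -> CompartmentMasks:
    """Build the three-compartment segmentation from contours + NC threshold.

    whole-disc and NP masks come from contour interpolation and per-slice
    rasterization; AF is the whole disc minus the NP; the NC is every voxel
    inside the NP whose (already filtered) intensity is >= ``nc_threshold``.

    An empty NP mask is an error; an empty NC mask is only a warning, since
    young or degenerate discs may genuinely lack resolvable notochord.
    """
    shape = stack.shape
    whole = _label_mask_volume(contours, DISC_OUTER, shape, stack.spacing_um, n_vertices)
    np_mask = _label_mask_volume(contours, NP_BORDER, shape, stack.spacing_um, n_vertices)
    if not np_mask.any():
        raise SegmentationError("NP mask is empty; check the np_border contours")
    if np.any(np_mask & ~whole):
        raise SegmentationError(
            "interpolated NP mask escapes the whole-disc mask; contours are inconsistent"
        )
    nc = np_mask & (stack.voxels >= nc_threshold)
    if not nc.any():
        warnings.warn(
            f"NC mask is empty at threshold {nc_threshold} "
            f"(stack maximum inside NP: {stack.voxels[np_mask].max():g})",
            UserWarning,
            stacklevel=2,
        )
    af = whole & ~np_mask
    return CompartmentMasks(whole, af, np_mask, nc, stack.spacing_um)


def suggest_nc_threshold(stack: ImageStack, np_mask: np.ndarray) -> ThresholdSuggestion:
    """Suggest an NC threshold: Otsu's method over the NP interior.

    The returned value is a starting point the operator may override.  When
    the NP-interior histogram shows no clear bright class (constant interior,
    or the two Otsu classes are separated by less than 4 pooled standard
    deviations) the suggestion carries ``low_separability=True`` and a
    :class:`LowSeparabilityWarning` is emitted.
    """
    np_mask = np.asarray(np_mask, bool)
    if not np_mask.any():
        raise SegmentationError("np_mask is empty; cannot suggest a threshold")
    values = stack.voxels[np_mask].astype(float)
    if np.ptp(values) == 0:
        warnings.warn(
            "NP interior is constant; no NC class to threshold",
            LowSeparabilityWarning,
            stacklevel=2,
        )
        return ThresholdSuggestion(float(values[0]), True)
    from skimage.filters import threshold_otsu

    thr = float(threshold_otsu(values))
    low, high = values[values < thr], values[values >= thr]
    pooled_sd = np.sqrt(0.5 * (np.var(low) + np.var(high))) if len(low) and len(high) else 0.0
    if pooled_sd == 0.0:
        separation = np.inf if len(low) and len(high) else 0.0
    else:
        separation = (high.mean() - low.mean()) / pooled_sd
    low_sep = bool(separation < 4.0)
    if low_sep:
        warnings.warn(
            f"NP-interior histogram separability is low (d'={separation:.2f}); "
            f"the NC may be absent",
            LowSeparabilityWarning,
            stacklevel=2,
        )
    return ThresholdSuggestion(thr, low_sep)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
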