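"""Resolution matching and denoising applied before segmentation.

Coarse scans are rescaled onto the reference (fine) grid with polynomial
spline interpolation — default cubic, the common high-quality resampling
choice — and a median filter (default radius 5, matching the pipeline this
package reimplements) suppresses noise while preserving compartment edges.

The median neighbourhood is a 2-D disc applied slice by slice by default:
filtering within transverse planes avoids mixing axes while the stack may
still be anisotropic; a 3-D ball is available once the grid is isotropic.
Edges are handled by reflection, which avoids a dark halo at stack borders.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .image_io import ImageStack


class PreprocessError(ValueError):
    pass


def rescale_to_spacing(
    stack: ImageStack,
    target_spacing_um: Sequence[float] | float,
    order: int = 3,
    max_factor: float = 20.0,
    force: bool = False,
) -> ImageStack:
    """Resample a stack onto a new voxel spacing by spline interpolation.

    Parameters
    ----------
    target_spacing_um : float or per-axis triple
        Requested output spacing in µm (strictly positive).
    order : {1, 2, 3}
        Polynomial interpolation order (3 = cubic, the default).
    max_factor, force
        Upscaling beyond ``max_factor`` per axis is refused as a resource
        guard unless ``force`` is set.

    The physical extent is preserved (grid-aligned resampling); a constant
    stack stays constant and a linear ramp is reproduced in the interior.
    """
    if np.isscalar(target_spacing_um):
        target_spacing_um = (float(target_spacing_um),) * 3
    target = tuple(float(v) for v in target_spacing_um)
    if any(t <= 0 for t in target):
        raise PreprocessError(f"target spacing must be positive, got {target_spacing_um}")
    if order not in (1, 2, 3):
        raise PreprocessError(f"interpolation order must be 1, 2 or 3, got {order}")
    factors = tuple(s / t for s, t in zip(stack.spacing_um, target))
    if factors == (1.0, 1.0, 1.0):
        return ImageStack(stack.voxels.copy(), target, stack.intensity_units)
    if max(factors) > max_factor and not force:
        raise PreprocessError(
            f"upscale factor {max(factors):.1f} exceeds the guard of {max_factor} "
            f"per axis; pass force=True to override"
        )
    # 'mirror' has an exact spline prefilter (a constant stays constant to
    # machine precision); 'reflect' in scipy is approximate near edges
    out = ndi.zoom(
        stack.voxels.astype(np.float64),
        factors,
        order=order,
        mode="mirror",
        grid_mode=True,
    )
    return ImageStack(out, target, stack.intensity_units)


def _disc_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return (y * y + x * x <= r * r)[None, :, :]


def _ball_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    z, y, x = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return z * z + y * y + x * x <= r * r


def median_filter(
    stack: ImageStack, radius: int = 5, footprint: str = "disk"
) -> ImageStack:
    """Median-filter a stack with a disc (slice-wise) or ball neighbourhood.

    Every voxel is replaced by the median of the intensities within the
    stated radius; edges are handled by reflection.  Idempotent on
    piecewise-constant images away from boundaries, and never produces a
    value outside the input range.
    """
    if radius < 1:
        raise PreprocessError(f"radius must be >= 1, got {radius}")
    size = 2 * int(radius) + 1
    if footprint == "disk":
        if size > min(stack.shape[1:]):
            raise PreprocessError(
                f"filter diameter {size} exceeds the in-plane extent {stack.shape[1:]}"
            )
        fp = _disc_footprint(radius)
    elif footprint == "ball":
        if size > min(stack.shape):
            raise PreprocessError(
                f"filter diameter {size} exceeds the smallest axis of {stack.shape}"
            )
        fp = _ball_footprint(radius)
    else:
        raise ValueError(f"unknown footprint {footprint!r}; use 'disk' or 'ball'")
    out = ndi.median_filter(stack.voxels, footprint=fp, mode="reflect")
    return ImageStack(out, stack.spacing_um, stack.intensity_units)
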