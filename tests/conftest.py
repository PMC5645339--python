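import numpy as np
import pytest

from ivdmorph.phantom import PhantomSpec, build_truth, generate_phantom


SMALL_KW = dict(
    grid_shape=(96, 120, 120),
    voxel_spacing_um=(1.0, 1.0, 1.0),
    disc_radius_um=50.0,
    disc_height_um=72.0,
    np_radius_um=30.0,
    nc_target_volume_fraction=0.05,
    nc_compactness=0.7,
)


def small_spec(**overrides) -> PhantomSpec:
    """A fast ~1 s phantom used throughout the unit tests."""
    kw = dict(SMALL_KW, noise_sd=0.0, seed=3)
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free small phantom: (spec, stack, truth)."""
    spec = small_spec()
    stack, truth = generate_phantom(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Small phantom with noise at 10% of the NC-NP contrast."""
    spec = small_spec(noise_sd=14.0)
    stack, truth = generate_phantom(spec)
    return spec, stack, truth


def brute_force_point_in_polygon(px: float, py: float, ring: np.ndarray) -> bool:
    """Even-odd rule with points on an edge counted as inside.

    Independent oracle: explicit edge walk, no shared code with the
    implementation under test.
    """
    n = len(ring)
    inside = False
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        scale = max(1.0, abs(x2 - x1) + abs(y2 - y1))
        if abs(cross) < 1e-12 * scale:
            if (
                min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12
                and min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12
            ):
                return True
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def brute_force_rasterize(ring_um: np.ndarray, grid_shape, spacing_um) -> np.ndarray:
    """Rasterization oracle: test every voxel centre against the polygon."""
    n_rows, n_cols = grid_shape
    row_um, col_um = spacing_um
    ring_vox = np.column_stack([ring_um[:, 0] / col_um, ring_um[:, 1] / row_um])
    out = np.zeros((n_rows, n_cols), dtype=bool)
    for i in range(n_rows):
        for j in range(n_cols):
            out[i, j] = brute_force_point_in_polygon(j + 0.5, i + 0.5, ring_vox)
    return out


def brute_force_median(vol: np.ndarray, radius: int) -> np.ndarray:
    """Median-filter oracle: explicitly gather and sort each disc neighbourhood."""
    r = radius
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    fp = yy * yy + xx * xx <= r * r
    pad = np.pad(vol, ((0, 0), (r, r), (r, r)), mode="symmetric")
    out = np.zeros_like(vol)
    for z in range(vol.shape[0]):
        for i in range(vol.shape[1]):
            for j in range(vol.shape[2]):
                neigh = np.sort(pad[z, i : i + 2 * r + 1, j : j + 2 * r + 1][fp])
                out[z, i, j] = neigh[len(neigh) // 2]
    return out


def regular_polygon(radius: float, center=(0.0, 0.0), n: int = 64) -> np.ndarray:
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)])


def digital_ball(radius_vox: int, pad: int = 3) -> np.ndarray:
    n = 2 * radius_vox + 2 * pad + 1
    c = n / 2
    z, y, x = np.mgrid[:n, :n, :n]
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_vox**2
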