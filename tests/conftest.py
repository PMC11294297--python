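import numpy as np
import pytest

from kidosim.grids import GridGeometry, VOI, VoxelGrid
from kidosim.phantom import OrganSpec, default_volume_multipliers, rasterize_organ


@pytest.fixture()
def small_geom() -> GridGeometry:
    """A 24^3 isotropic 2 mm grid for cheap geometric tests."""
    return GridGeometry((24, 24, 24), (2.0, 2.0, 2.0), (-23.0, -23.0, -23.0))


@pytest.fixture()
def ct_like_geom() -> GridGeometry:
    """A small CT-like grid: 5 mm slices, ~1.1 mm in-plane."""
    return GridGeometry((20, 80, 80), (5.0, 1.105, 1.105), (-47.5, -43.6, -43.6))


@pytest.fixture()
def spect_like_geom() -> GridGeometry:
    """A SPECT-like 4.42 mm isotropic grid covering the CT-like grid."""
    return GridGeometry((23, 21, 21), (4.42, 4.42, 4.42), (-48.6, -44.2, -44.2))


def sphere_voi(radius_mm: float, geom: GridGeometry, center=(0.0, 0.0, 0.0),
               label: str = "sphere") -> VOI:
    """Binary sphere mask by voxel-center membership (independent of phantom)."""
    zz = geom.axis_centers(0)[:, None, None] - center[0]
    yy = geom.axis_centers(1)[None, :, None] - center[1]
    xx = geom.axis_centers(2)[None, None, :] - center[2]
    mask = (zz**2 + yy**2 + xx**2 <= radius_mm**2).astype(float)
    return VOI(mask, geom, label)


def fractional_sphere_voi(volume_mL: float, spacing: float = 4.42,
                          margin_mm: float = 30.0, label: str = "sphere") -> VOI:
    """Fractional sphere of a given volume on an isotropic grid, via the
    phantom rasteriser with unit axis ratios."""
    r = (volume_mL * 1000.0 * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = r + margin_mm
    n = int(np.ceil(2 * half / spacing))
    geom = GridGeometry((n, n, n), (spacing,) * 3,
                        (-(n - 1) / 2 * spacing,) * 3)
    spec = OrganSpec(label, volume_mL, (0.0, 0.0, 0.0), axis_ratios=(1.0, 1.0, 1.0))
    return rasterize_organ(spec, "B_L", geom).with_label(label)
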