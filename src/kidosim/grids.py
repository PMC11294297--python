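"""Voxel grids, volumes of interest, resampling, propagation and quantification.

All arrays are indexed (z, y, x) with 0-based indices; ``spacing`` and
``origin`` follow the same axis order and are in millimetres.  ``origin`` is
the physical coordinate of the *center* of voxel (0, 0, 0), so voxel ``i``
along an axis covers the interval ``origin + (i - 0.5) * dz`` to
``origin + (i + 0.5) * dz``.

The module carries both SPECT-resolution activity-concentration images
(Bq/mL) and CT-resolution delineations (binary or fractional masks), and
implements the operations a serial SPECT/CT quantification workflow needs:

* CT -> SPECT resampling of a delineated mask by supersampled
  fraction-of-voxel coverage (large downsampling factors alias volumes under
  nearest-neighbour resampling, so coverage fractions are the default);
* propagation of a single delineation to other time points without any
  geometric modification (the "single-VOI" dosimetry shortcut);
* optional integer-voxel translation alignment of a mask onto an emission
  image (a surrogate for manually nudging a CT contour onto SPECT);
* mask-weighted mean activity concentration inside a VOI.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "GridGeometry",
    "VoxelGrid",
    "VOI",
    "PropagationStrategy",
    "STRATEGY_MODES",
    "resample_field",
    "resample_voi",
    "propagate_voi",
    "align_voi",
    "mean_concentration",
    "save_nifti",
    "load_voxelgrid",
    "load_voi",
]


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and origin of a regular voxel grid (axis order z, y, x)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("geometry must be 3-dimensional")
        if any(n <= 0 for n in self.shape):
            raise ValueError("shape entries must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_mL(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def extent(self, axis: int) -> tuple[float, float]:
        """Physical interval covered by the grid along one axis (voxel edges)."""
        lo = self.origin[axis] - 0.5 * self.spacing[axis]
        return lo, lo + self.shape[axis] * self.spacing[axis]


@dataclass
class VoxelGrid:
    """A 3D scalar field (activity concentration in Bq/mL, or label ids)."""

    values: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VoxelGrid values must be a rank-3 array")
        if tuple(self.values.shape) != tuple(self.geometry.shape):
            raise ValueError("values shape does not match geometry shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VoxelGrid values must be finite")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.geometry.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.geometry.origin


@dataclass
class VOI:
    """A binary or fractional mask bound to a grid geometry.

    ``label`` names the organ and the time point it was delineated at, e.g.
    ``"kidney_L:D0"``.  Fractional values in [0, 1] arise from coverage
    resampling and are valid weights for quantification.
    """

    mask: np.ndarray
    geometry: GridGeometry
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.float64)
        if self.mask.ndim != 3:
            raise ValueError("VOI mask must be a rank-3 array")
        if tuple(self.mask.shape) != tuple(self.geometry.shape):
            raise ValueError("mask shape does not match geometry shape")
        if np.any(self.mask < -1e-9) or np.any(self.mask > 1 + 1e-9):
            raise ValueError("mask values must lie in [0, 1]")
        self.mask = np.clip(self.mask, 0.0, 1.0)

    @property
    def volume_mL(self) -> float:
        return float(self.mask.sum()) * self.geometry.voxel_volume_mL

    def with_label(self, label: str) -> "VOI":
        return VOI(self.mask, self.geometry, label)


STRATEGY_MODES = ("reference", "single_D0", "single_D1", "single_D2", "single_D7")


@dataclass(frozen=True)
class PropagationStrategy:
    """How delineations are carried across time points.

    ``reference`` uses the tag-matched delineation at every time point (one
    VOI per time point); each ``single_Dk`` reuses the delineation from time
    point Dk for all time points without geometric modification.  ``align``
    enables integer-voxel translation onto each emission image before
    quantification.
    """

    mode: str
    align: bool = False
    max_shift_voxels: int = 2

    def __post_init__(self) -> None:
        if self.mode not in STRATEGY_MODES:
            raise ValueError(f"unknown strategy mode {self.mode!r}")

    @property
    def source_tag(self) -> str | None:
        """The single delineation tag this strategy reuses (None = reference)."""
        if self.mode == "reference":
            return None
        return self.mode.split("_", 1)[1]


def _overlap_or_raise(src: GridGeometry, tgt: GridGeometry) -> None:
    for ax in range(3):
        slo, shi = src.extent(ax)
        tlo, thi = tgt.extent(ax)
        if shi <= tlo or thi <= slo:
            raise ValueError("VOI outside target grid")


def _overlap_matrix(source: GridGeometry, target: GridGeometry, axis: int) -> np.ndarray:
    """(n_target, n_source) matrix of interval-overlap fractions along one axis.

    Entry (i, a) is the fraction of target voxel i's extent covered by source
    voxel a; rows sum to <= 1 (less where the target sticks out of the source).
    """
    t_lo = target.origin[axis] - 0.5 * target.spacing[axis] + np.arange(
        target.shape[axis]
    ) * target.spacing[axis]
    t_hi = t_lo + target.spacing[axis]
    s_lo = source.origin[axis] - 0.5 * source.spacing[axis] + np.arange(
        source.shape[axis]
    ) * source.spacing[axis]
    s_hi = s_lo + source.spacing[axis]
    ov = np.minimum(t_hi[:, None], s_hi[None, :]) - np.maximum(
        t_lo[:, None], s_lo[None, :]
    )
    return np.clip(ov, 0.0, None) / target.spacing[axis]


def resample_field(
    values: np.ndarray,
    source: GridGeometry,
    target: GridGeometry,
    supersample: int | None = None,
) -> np.ndarray:
    """Volume-weighted resampling of a scalar field onto a target geometry.

    Each target voxel receives the volume-weighted average of the source
    values over its physical extent, computed exactly by separable
    interval-overlap weights (the limit of infinitely fine supersampling of
    the target voxel); regions outside the source grid contribute zero.  For
    a mask this is exactly the fraction of the target voxel's physical
    volume covered by the source mask, and total volume is conserved
    wherever the target grid covers the source.

    ``supersample`` is accepted for call-site compatibility and ignored:
    the overlap computation is exact.
    """
    values = np.asarray(values, dtype=np.float64)
    wz = _overlap_matrix(source, target, 0)
    wy = _overlap_matrix(source, target, 1)
    wx = _overlap_matrix(source, target, 2)
    out = np.einsum("za,abc->zbc", wz, values, optimize=True)
    out = np.einsum("yb,zbc->zyc", wy, out, optimize=True)
    out = np.einsum("xc,zyc->zyx", wx, out, optimize=True)
    return out


def resample_voi(
    voi: VOI,
    target: GridGeometry,
    binarize_threshold: float | str = 0.5,
    supersample: int = 4,
) -> VOI:
    """Resample a VOI onto a target geometry by fraction-of-voxel coverage.

    ``binarize_threshold`` may be a fraction in [0, 1] (mask thresholded at
    that coverage) or the string ``"fractional"`` to keep coverage fractions,
    which preserves total volume and is the mode used for quantification.
    """
    _overlap_or_raise(voi.geometry, target)
    frac = resample_field(voi.mask, voi.geometry, target, supersample=supersample)
    if isinstance(binarize_threshold, str):
        if binarize_threshold != "fractional":
            raise ValueError("binarize_threshold must be a fraction or 'fractional'")
        mask = frac
    else:
        if not 0.0 <= float(binarize_threshold) <= 1.0:
            raise ValueError("binarize_threshold must lie in [0, 1]")
        mask = (frac >= float(binarize_threshold)).astype(np.float64)
    if mask.sum() <= 0:
        raise ValueError("VOI outside target grid")
    return VOI(mask, target, voi.label)


def propagate_voi(source: VOI, timepoints: list[str]) -> dict[str, VOI]:
    """Reuse one delineation at several time points without geometry change.

    The returned masks are bit-identical to the source; only the time tag in
    the label differs.  This models applying a single CT delineation to a
    series of SPECT acquisitions.
    """
    if not timepoints:
        raise ValueError("timepoints must be non-empty")
    organ = source.label.split(":", 1)[0] if source.label else ""
    out: dict[str, VOI] = {}
    for tag in timepoints:
        label = f"{organ}:{tag}" if organ else tag
        out[tag] = VOI(source.mask.copy(), source.geometry, label)
    return out


def _shift_mask(mask: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    """Integer-voxel translation with zero fill (no wrap-around)."""
    out = np.zeros_like(mask)
    src_sl, dst_sl = [], []
    for ax, s in enumerate(shift):
        n = mask.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            src_sl.append(slice(0, n - s))
            dst_sl.append(slice(s, n))
        else:
            src_sl.append(slice(-s, n))
            dst_sl.append(slice(0, n + s))
    out[tuple(dst_sl)] = mask[tuple(src_sl)]
    return out


def align_voi(image: VoxelGrid, voi: VOI, max_shift_voxels: int) -> VOI:
    """Translate a VOI (integer voxels) to maximize the mean image value inside.

    Searches all shifts within +/- ``max_shift_voxels`` per axis; ties are
    broken by the smallest shift magnitude, then lexicographically in (z, y, x).
    A surrogate for manually nudging a CT contour onto the SPECT uptake.
    """
    if max_shift_voxels < 0:
        raise ValueError("max_shift_voxels must be >= 0")
    if tuple(image.geometry.shape) != tuple(voi.geometry.shape):
        raise ValueError("image and VOI must share geometry")
    if max_shift_voxels == 0:
        return voi
    m = max_shift_voxels
    best: tuple[float, float, tuple[int, int, int]] | None = None
    vals = np.asarray(image.values, dtype=np.float64)
    for shift in itertools.product(range(-m, m + 1), repeat=3):
        shifted = _shift_mask(voi.mask, shift)
        w = shifted.sum()
        if w <= 0:
            continue
        score = float((vals * shifted).sum() / w)
        key = (-score, float(np.dot(shift, shift)), shift)
        if best is None or key < best:
            best = key
    assert best is not None
    shift = best[2]
    return VOI(_shift_mask(voi.mask, shift), voi.geometry, voi.label)


def mean_concentration(image: VoxelGrid, voi: VOI) -> float:
    """Mask-weighted mean of the image inside the VOI (Bq/mL for SPECT images)."""
    if tuple(image.geometry.shape) != tuple(voi.geometry.shape):
        raise ValueError("image and VOI must share geometry")
    w = voi.mask.sum()
    if w <= 0:
        raise ValueError("zero-volume VOI")
    return float((np.asarray(image.values, dtype=np.float64) * voi.mask).sum() / w)


# ---------------------------------------------------------------------------
# NIfTI-1 I/O.  Arrays are stored with axes reordered to (x, y, z) and an
# affine of diag(dx, dy, dz) plus the origin translation, so spacing and
# origin round-trip through the header.


def _affine(geometry: GridGeometry) -> np.ndarray:
    aff = np.eye(4)
    dz, dy, dx = geometry.spacing
    oz, oy, ox = geometry.origin
    aff[0, 0], aff[1, 1], aff[2, 2] = dx, dy, dz
    aff[:3, 3] = (ox, oy, oz)
    return aff


def save_nifti(obj: VoxelGrid | VOI, path: str) -> None:
    """Write a grid or VOI as NIfTI-1; binary masks as uint8, else float32."""
    if isinstance(obj, VOI):
        data = obj.mask
        binary = np.all((data == 0) | (data == 1))
        data = data.astype(np.uint8 if binary else np.float32)
        geometry = obj.geometry
    else:
        data = np.asarray(obj.values, dtype=np.float32)
        geometry = obj.geometry
    img = nib.Nifti1Image(np.ascontiguousarray(data.transpose(2, 1, 0)), _affine(geometry))
    nib.save(img, path)


def _geometry_from(img: nib.Nifti1Image) -> GridGeometry:
    aff = img.affine
    dx, dy, dz = (float(abs(aff[i, i])) for i in range(3))
    ox, oy, oz = (float(aff[i, 3]) for i in range(3))
    nx, ny, nz = img.shape[:3]
    return GridGeometry((int(nz), int(ny), int(nx)), (dz, dy, dx), (oz, oy, ox))


def load_voxelgrid(path: str) -> VoxelGrid:
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64).transpose(2, 1, 0)
    return VoxelGrid(data, _geometry_from(img))


def load_voi(path: str, label: str = "") -> VOI:
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64).transpose(2, 1, 0)
    return VOI(data, _geometry_from(img), label)
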