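"""Voxel-grid, VOI resampling, propagation, alignment and quantification."""

import itertools

import numpy as np
import pytest
from scipy.ndimage import binary_erosion, gaussian_filter

from kidosim.grids import (
    VOI,
    GridGeometry,
    PropagationStrategy,
    VoxelGrid,
    align_voi,
    load_voi,
    load_voxelgrid,
    mean_concentration,
    propagate_voi,
    resample_voi,
    save_nifti,
)

from .conftest import sphere_voi


class TestResampleVOI:
    def test_identity_on_same_geometry(self, small_geom):
        voi = sphere_voi(15.0, small_geom)
        out = resample_voi(voi, small_geom, "fractional")
        np.testing.assert_array_equal(out.mask, voi.mask)

    def test_single_fine_voxel_fraction(self):
        """A 1 mm^3 voxel lands in one coarse voxel with ~(1/4.42)^3 coverage."""
        fine = GridGeometry((9, 9, 9), (1.0, 1.0, 1.0), (-4.0, -4.0, -4.0))
        coarse = GridGeometry((3, 3, 3), (4.42, 4.42, 4.42), (-4.42, -4.42, -4.42))
        mask = np.zeros(fine.shape)
        mask[4, 4, 4] = 1.0
        out = resample_voi(VOI(mask, fine), coarse, "fractional", supersample=16)
        nz = np.nonzero(out.mask)
        assert len(nz[0]) == 1 and tuple(a[0] for a in nz) == (1, 1, 1)
        # sub-point quantisation bounds the recovered volume around 1 mm^3
        vol_mm3 = out.volume_mL * 1000.0
        assert 0.5 <= vol_mm3 <= 1.5

    def test_sphere_volume_conserved_ct_to_spect(self):
        """CT->SPECT fractional resampling preserves a 30 mm sphere's volume
        to within 1% of the analytic 4/3 pi r^3."""
        ct = GridGeometry((26, 116, 116), (2.5, 1.0, 1.0), (-31.25, -57.5, -57.5))
        spect = GridGeometry((16, 27, 27), (4.42, 4.42, 4.42), (-33.1, -57.5, -57.5))
        voi = sphere_voi(30.0, ct)
        out = resample_voi(voi, spect, "fractional")
        analytic = 4.0 / 3.0 * np.pi * 30.0**3 / 1000.0
        assert out.volume_mL == pytest.approx(analytic, rel=0.01)

    def test_binarize_threshold_gives_binary_mask(self, small_geom):
        voi = sphere_voi(15.0, small_geom)
        coarse = GridGeometry((12, 12, 12), (4.0, 4.0, 4.0), (-23.0, -23.0, -23.0))
        out = resample_voi(voi, coarse, 0.5)
        assert set(np.unique(out.mask)) <= {0.0, 1.0}
        assert out.volume_mL > 0

    def test_disjoint_extents_raise(self, small_geom):
        far = GridGeometry((4, 4, 4), (2.0, 2.0, 2.0), (500.0, 500.0, 500.0))
        with pytest.raises(ValueError, match="outside target grid"):
            resample_voi(sphere_voi(10.0, small_geom), far, "fractional")


class TestPropagateVOI:
    def test_identity_single_tag(self, small_geom):
        voi = sphere_voi(12.0, small_geom, label="kidney_L:D0")
        out = propagate_voi(voi, ["D0"])
        np.testing.assert_array_equal(out["D0"].mask, voi.mask)

    def test_masks_bit_identical_across_tags(self, small_geom):
        voi = sphere_voi(12.0, small_geom, label="kidney_L:D7")
        out = propagate_voi(voi, ["D0", "D1", "D2", "D7"])
        assert set(out) == {"D0", "D1", "D2", "D7"}
        for tag, v in out.items():
            np.testing.assert_array_equal(v.mask, voi.mask)
            assert v.volume_mL == voi.volume_mL  # exactly
            assert v.label == f"kidney_L:{tag}"

    def test_empty_timepoints_raise(self, small_geom):
        with pytest.raises(ValueError):
            propagate_voi(sphere_voi(12.0, small_geom), [])


class TestAlignVOI:
    def test_uniform_image_zero_shift(self, small_geom):
        img = VoxelGrid(np.full(small_geom.shape, 3.0), small_geom)
        voi = sphere_voi(10.0, small_geom)
        out = align_voi(img, voi, 3)
        np.testing.assert_array_equal(out.mask, voi.mask)

    def test_recovers_known_displacement(self, small_geom):
        """Hot sphere shifted +2 voxels in x: exhaustive search finds it."""
        hot = sphere_voi(10.0, small_geom, center=(0.0, 0.0, 4.0)).mask
        img = VoxelGrid(hot * 100.0, small_geom)
        voi = sphere_voi(10.0, small_geom)
        out = align_voi(img, voi, 3)
        # independent exhaustive oracle over the 7^3 shift grid
        best = None
        for shift in itertools.product(range(-3, 4), repeat=3):
            m = np.roll(voi.mask, shift, axis=(0, 1, 2))
            score = (img.values * m).sum() / m.sum()
            key = (-score, float(np.dot(shift, shift)), shift)
            if best is None or key < best:
                best = key
        assert best[2] == (0, 0, 2)
        np.testing.assert_array_equal(
            out.mask, np.roll(voi.mask, (0, 0, 2), axis=(0, 1, 2))
        )

    def test_zero_max_shift_is_identity(self, small_geom):
        img = VoxelGrid(np.random.default_rng(0).random(small_geom.shape), small_geom)
        voi = sphere_voi(10.0, small_geom)
        assert align_voi(img, voi, 0) is voi


class TestMeanConcentration:
    def test_constant_field(self, small_geom):
        img = VoxelGrid(np.full(small_geom.shape, 7.25), small_geom)
        assert mean_concentration(img, sphere_voi(9.0, small_geom)) == pytest.approx(7.25)

    def test_zero_field(self, small_geom):
        img = VoxelGrid(np.zeros(small_geom.shape), small_geom)
        assert mean_concentration(img, sphere_voi(9.0, small_geom)) == 0.0

    def test_two_voxel_mean(self, small_geom):
        values = np.zeros(small_geom.shape)
        values[0, 0, 0], values[0, 0, 1] = 10.0, 30.0
        mask = np.zeros(small_geom.shape)
        mask[0, 0, 0] = mask[0, 0, 1] = 1.0
        assert mean_concentration(VoxelGrid(values, small_geom), VOI(mask, small_geom)) == 20.0

    def test_zero_volume_voi_raises(self, small_geom):
        img = VoxelGrid(np.ones(small_geom.shape), small_geom)
        with pytest.raises(ValueError, match="zero-volume"):
            mean_concentration(img, VOI(np.zeros(small_geom.shape), small_geom))

    @pytest.mark.parametrize("shift", [(1, 0, 0), (0, -2, 1), (2, 2, 2)])
    def test_invariant_under_common_rigid_shift(self, small_geom, shift):
        rng = np.random.default_rng(5)
        img = VoxelGrid(rng.random(small_geom.shape), small_geom)
        voi = sphere_voi(8.0, small_geom)
        ref = mean_concentration(img, voi)
        shifted_img = VoxelGrid(np.roll(img.values, shift, axis=(0, 1, 2)), small_geom)
        shifted_voi = VOI(np.roll(voi.mask, shift, axis=(0, 1, 2)), small_geom)
        assert mean_concentration(shifted_img, shifted_voi) == pytest.approx(ref, rel=1e-12)


def test_interior_voi_reads_higher_on_blurred_object(small_geom):
    """For a uniform object blurred by any positive PSF, a strictly interior
    VOI has a mean >= the full-VOI mean — the mechanism behind the positive
    single-VOI concentration biases on a swollen organ."""
    voi = sphere_voi(14.0, small_geom)
    for sigma_vox in (0.5, 1.0, 2.5):
        blurred = gaussian_filter(voi.mask * 50.0, sigma_vox, mode="constant")
        img = VoxelGrid(blurred, small_geom)
        eroded = VOI(binary_erosion(voi.mask.astype(bool)).astype(float), small_geom)
        assert mean_concentration(img, eroded) >= mean_concentration(img, voi)


class TestTypesAndIO:
    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            GridGeometry((4, 4, 4), (0.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            GridGeometry((4, 4), (1.0, 1.0))  # type: ignore[arg-type]

    def test_voxelgrid_rejects_nonfinite(self, small_geom):
        values = np.zeros(small_geom.shape)
        values[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            VoxelGrid(values, small_geom)

    def test_voi_mask_range_checked(self, small_geom):
        with pytest.raises(ValueError):
            VOI(np.full(small_geom.shape, 1.5), small_geom)

    def test_strategy_modes(self):
        assert PropagationStrategy("reference").source_tag is None
        assert PropagationStrategy("single_D7").source_tag == "D7"
        with pytest.raises(ValueError):
            PropagationStrategy("single_D9")

    def test_nifti_round_trip(self, tmp_path, small_geom):
        rng = np.random.default_rng(2)
        grid = VoxelGrid(rng.random(small_geom.shape).astype(np.float32), small_geom)
        p = tmp_path / "img.nii.gz"
        save_nifti(grid, str(p))
        back = load_voxelgrid(str(p))
        assert back.geometry == small_geom
        np.testing.assert_allclose(back.values, grid.values, rtol=1e-6)

        voi = sphere_voi(10.0, small_geom)
        pm = tmp_path / "mask.nii.gz"
        save_nifti(voi, str(pm))
        back_voi = load_voi(str(pm), "sphere")
        np.testing.assert_array_equal(back_voi.mask, voi.mask)
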