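"""Synthetic phantom generator: volumes, kinetics truth, SPECT rendering."""

import numpy as np
import pytest

from kidosim.grids import GridGeometry
from kidosim.phantom import (
    AcquisitionSpec,
    KineticsTruth,
    OrganCollisionError,
    OrganSpec,
    default_ct_geometry,
    default_spect_geometry,
    default_volume_multipliers,
    make_phantom,
    rasterize_organ,
    render_spect,
    true_concentration,
)


@pytest.fixture(scope="module")
def ct_geom():
    return default_ct_geometry()


class TestVolumes:
    def test_baseline_volume_hits_target_within_half_voxel(self, ct_geom):
        spec = OrganSpec("kidney_L", 130.6, (0.0, 0.0, -50.0))
        voi = rasterize_organ(spec, "B_L", ct_geom)
        assert abs(voi.volume_mL - 130.6) <= 0.5 * ct_geom.voxel_volume_mL

    def test_multiplier_scales_volume(self, ct_geom):
        spec = OrganSpec(
            "kidney_L", 100.0, (0.0, 0.0, -50.0),
            volume_multipliers={"D1": 1.1007},
        )
        voi = rasterize_organ(spec, "D1", ct_geom)
        assert voi.volume_mL == pytest.approx(110.07, abs=0.01)

    def test_bean_shape_volume(self, ct_geom):
        spec = OrganSpec("kidney_L", 120.0, (0.0, 0.0, -50.0), shape="bean")
        voi = rasterize_organ(spec, "B_L", ct_geom)
        assert voi.volume_mL == pytest.approx(120.0, abs=0.3 * ct_geom.voxel_volume_mL)

    def test_default_multipliers(self):
        kid = default_volume_multipliers("kidney_L")
        assert kid == {"B_L": 1.0, "D0": 1.0877, "D1": 1.1007, "D2": 1.0110, "D7": 1.0110}
        spl = default_volume_multipliers("spleen")
        assert all(v == 1.0 for v in spl.values())


class TestMakePhantom:
    def test_collision_raises(self, ct_geom):
        a = OrganSpec("a", 150.0, (0.0, 0.0, -20.0))
        b = OrganSpec("b", 150.0, (0.0, 0.0, 20.0))
        with pytest.raises(OrganCollisionError):
            make_phantom([a, b], "B_L", ct_geom)

    def test_touching_but_disjoint_ok(self, ct_geom):
        a = OrganSpec("a", 30.0, (0.0, 0.0, -30.0), axis_ratios=(1.0, 1.0, 1.0))
        b = OrganSpec("b", 30.0, (0.0, 0.0, 30.0), axis_ratios=(1.0, 1.0, 1.0))
        labels, vois = make_phantom([a, b], "B_L", ct_geom)
        assert set(np.unique(labels.values)) == {0, 1, 2}
        assert vois["a"].volume_mL == pytest.approx(30.0, abs=0.1)

    def test_label_map_matches_vois(self, ct_geom):
        a = OrganSpec("a", 60.0, (0.0, 0.0, -40.0))
        labels, vois = make_phantom([a], "B_L", ct_geom)
        core = vois["a"].mask > 0.5
        assert np.all(labels.values[core] == 1)


class TestKineticsTruth:
    def test_zero_at_time_zero(self):
        tr = KineticsTruth(2.0, 1.0, 0.01, 0.05, 0.5, mode="concentration_primary")
        organ = OrganSpec("k", 100.0, (0, 0, 0))
        assert true_concentration(tr, organ, 0.0) == 0.0

    def test_frozen_evaluation(self):
        # 2e^-0.24 + e^-1.2 - 3e^-12, high-precision oracle value
        tr = KineticsTruth(2.0, 1.0, 0.01, 0.05, 0.5, mode="concentration_primary")
        organ = OrganSpec("k", 100.0, (0, 0, 0))
        assert true_concentration(tr, organ, 24.0) == pytest.approx(1.874432, abs=1e-6)

    def test_activity_mode_is_concentration_over_volume(self):
        ta = KineticsTruth(200.0, 100.0, 0.01, 0.05, 0.5, mode="activity_primary")
        tc = KineticsTruth(200.0, 100.0, 0.01, 0.05, 0.5, mode="concentration_primary")
        organ = OrganSpec(
            "k", 100.0, (0, 0, 0), volume_multipliers={"D1": 1.1007}
        )
        c_act = true_concentration(ta, organ, 24.0, tag="D1")
        c_conc = true_concentration(tc, organ, 24.0)
        assert c_act == pytest.approx(c_conc / 110.07, rel=1e-12)

    def test_swelling_dilutes_concentration(self):
        ta = KineticsTruth(200.0, 100.0, 0.01, 0.05, 0.5, mode="activity_primary")
        organ = OrganSpec("k", 100.0, (0, 0, 0), volume_multipliers={"D1": 1.1007})
        assert true_concentration(ta, organ, 24.0, tag="D1") < true_concentration(
            ta, organ, 24.0, tag="B_L"
        )

    def test_scaled_to_peak(self):
        tr = KineticsTruth.scaled_to_peak(3.0e5, volume_mL=100.0)
        organ = OrganSpec("k", 100.0, (0, 0, 0))
        tt = np.linspace(0, 500, 2000)
        peaks = [true_concentration(tr, organ, t) for t in tt]
        assert max(peaks) == pytest.approx(3.0e5, rel=1e-3)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticsTruth(1.0, 1.0, -0.01, 0.05, 0.5)


@pytest.fixture(scope="module")
def small_scene():
    ct = GridGeometry((24, 100, 100), (5.0, 1.105, 1.105), (-57.5, -54.7, -54.7))
    spect = GridGeometry((27, 26, 26), (4.42, 4.42, 4.42), (-57.5, -55.25, -55.25))
    organ = OrganSpec("k", 80.0, (0.0, 0.0, 0.0))
    voi = rasterize_organ(organ, "B_L", ct)
    return ct, spect, {"k": voi}


class TestRenderSpect:
    def test_zero_concentration_gives_zero_image(self, small_scene):
        _, spect, vois = small_scene
        img = render_spect(vois, {"k": 0.0}, AcquisitionSpec(), spect)
        assert np.all(img.values == 0.0)

    def test_fwhm_zero_equals_downsampled_painting(self, small_scene):
        from kidosim.grids import resample_field

        ct, spect, vois = small_scene
        img = render_spect(vois, {"k": 500.0}, AcquisitionSpec(psf_fwhm_mm=0.0), spect)
        expect = resample_field(vois["k"].mask * 500.0, ct, spect)
        np.testing.assert_array_equal(img.values, expect)

    def test_blur_conserves_total_activity(self, small_scene):
        _, spect, vois = small_scene
        img = render_spect(vois, {"k": 1000.0}, AcquisitionSpec(psf_fwhm_mm=12.0), spect)
        total = img.values.sum() * spect.voxel_volume_mL
        true_total = 1000.0 * vois["k"].volume_mL
        assert total == pytest.approx(true_total, rel=1e-3)

    def test_rendering_linear_in_concentration(self, small_scene):
        _, spect, vois = small_scene
        img1 = render_spect(vois, {"k": 300.0}, AcquisitionSpec(), spect)
        img3 = render_spect(vois, {"k": 900.0}, AcquisitionSpec(), spect)
        np.testing.assert_allclose(img3.values, 3.0 * img1.values, rtol=1e-12, atol=1e-12)

    def test_poisson_noise_reproducible_with_seed(self, small_scene):
        _, spect, vois = small_scene
        acq = AcquisitionSpec(noise="poisson", seed=11)
        a = render_spect(vois, {"k": 2e5}, acq, spect)
        b = render_spect(vois, {"k": 2e5}, acq, spect)
        np.testing.assert_array_equal(a.values, b.values)
        c = render_spect(vois, {"k": 2e5}, AcquisitionSpec(noise="poisson", seed=12), spect)
        assert not np.array_equal(a.values, c.values)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionSpec(psf_fwhm_mm=-1.0)


def test_time_jitter_within_ranges():
    acq = AcquisitionSpec(time_jitter=True, seed=3)
    times = acq.sample_times()
    from kidosim.phantom import TIME_JITTER_RANGES_H

    for tag, t in times.items():
        lo, hi = TIME_JITTER_RANGES_H[tag]
        assert lo <= t <= hi
    assert times != acq.times_h


def test_default_geometries():
    ct = default_ct_geometry()
    sp = default_spect_geometry()
    assert ct.spacing == (5.0, 1.105, 1.105)
    assert sp.spacing == (4.42, 4.42, 4.42)
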