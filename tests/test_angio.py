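"""Capillary-density chain: gating, upsampling, FAZ, thresholding, RCD."""

import numpy as np
import pytest

from macuquant import angio, geometry, synth
from macuquant.angio import (
    Angiogram,
    VesselMaps,
    adaptive_threshold,
    capillary_map,
    detect_faz,
    global_threshold,
    noise_floor,
    quality_filter,
    rcd,
    rcd_profile,
    upsample,
)

MM_PX = 3.0 / 1024


def make_angiogram(intensity, ssi=65.0, layer="SRCL"):
    return Angiogram(intensity, layer=layer, signal_strength_index=ssi,
                     laterality="OD")


@pytest.fixture(scope="module")
def phantom():
    spec = synth.AngioPhantomSpec(capillary_fraction=0.637, seed=1)
    return synth.make_angiogram_phantom(spec)


class TestQualityFilter:
    @pytest.mark.parametrize("ssi,expected", [(41.0, True), (40.0, False),
                                              (40.0001, True), (10.0, False)])
    def test_strict_threshold(self, ssi, expected):
        ok, _ = quality_filter(make_angiogram(np.zeros((304, 304)), ssi))
        assert ok is expected

    def test_missing_ssi_fails_with_reason(self):
        ok, reason = quality_filter(make_angiogram(np.zeros((304, 304)), None))
        assert not ok and reason == "missing SSI"


class TestUpsample:
    def test_constant_preserved(self):
        up = upsample(make_angiogram(np.full((304, 304), 37.0)))
        assert up.shape == (1024, 1024)
        np.testing.assert_allclose(up, 37.0, atol=1e-9)

    def test_linear_ramp_preserved(self):
        ramp = np.tile(np.linspace(0, 100, 304), (304, 1))
        up = upsample(make_angiogram(ramp))
        # bicubic interpolation reproduces linear functions away from edges
        interior = up[100:-100, 100:-100]
        expected = np.tile(np.linspace(0, 100, 1024), (1024, 1))[100:-100, 100:-100]
        assert np.abs(interior - expected).max() < 0.5

    def test_round_trip_correlation(self, phantom):
        from skimage import transform

        a, _ = phantom
        up = upsample(a)
        back = transform.resize(up, a.intensity.shape, order=3,
                                anti_aliasing=True, preserve_range=True)
        r = np.corrcoef(back.ravel(), a.intensity.ravel())[0, 1]
        assert r > 0.99


class TestDetectFAZ:
    def test_disk_area_within_five_percent(self):
        spec = synth.AngioPhantomSpec(faz_shape="disk", seed=3)
        a, truth = synth.make_angiogram_phantom(spec)
        faz = detect_faz(upsample(a), MM_PX)
        assert not faz.fallback
        assert faz.area_mm2 == pytest.approx(np.pi * 0.30**2, rel=0.05)

    def test_ellipse_area_within_seven_percent(self):
        spec = synth.AngioPhantomSpec(faz_shape="ellipse", seed=9)
        a, truth = synth.make_angiogram_phantom(spec)
        faz = detect_faz(upsample(a), MM_PX)
        assert not faz.fallback
        assert faz.area_mm2 == pytest.approx(truth.faz_area_mm2, rel=0.07)

    def test_irregular_area_within_seven_percent(self):
        spec = synth.AngioPhantomSpec(faz_shape="irregular", seed=10)
        a, truth = synth.make_angiogram_phantom(spec)
        faz = detect_faz(upsample(a), MM_PX)
        assert faz.area_mm2 == pytest.approx(truth.faz_area_mm2, rel=0.07)

    def test_fully_perfused_falls_back_with_warning(self):
        # uniform flow signal everywhere: no avascular/perfused interface
        rng = np.random.default_rng(4)
        img = 100.0 + rng.normal(0, 3.0, (304, 304))
        a = make_angiogram(img)
        with pytest.warns(RuntimeWarning, match="0.60 mm disk"):
            faz = detect_faz(upsample(a), MM_PX)
        assert faz.fallback
        assert faz.area_mm2 == pytest.approx(np.pi * 0.30**2)


class TestNoiseFloor:
    def test_all_zero_interior(self):
        img = np.ones((64, 64))
        mask = np.zeros((64, 64), bool)
        mask[20:40, 20:40] = True
        img[mask] = 0.0
        assert noise_floor(img, mask) == 0.0

    def test_k_zero_returns_mean(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 50, (64, 64))
        mask = np.zeros((64, 64), bool)
        mask[10:50, 10:50] = True
        assert noise_floor(img, mask, k=0.0) == pytest.approx(img[mask].mean())

    def test_iid_noise_mean_plus_two_sd(self):
        rng = np.random.default_rng(1)
        img = rng.normal(10, 5, (256, 256))
        mask = np.ones((256, 256), bool)
        assert noise_floor(img, mask, k=2.0) == pytest.approx(20.0, abs=0.3)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            noise_floor(np.ones((8, 8)), np.zeros((8, 8), bool))


def draw_vessel(img, col, width_px, value=200.0):
    img[:, col:col + width_px] = value
    return img


class TestGlobalThreshold:
    def test_width_filter_keeps_only_wide_vessel(self):
        img = np.zeros((512, 512))
        w15 = max(int(round(15 / (MM_PX * 1000))), 1)   # 15 μm wide
        w40 = int(round(40 / (MM_PX * 1000)))           # 40 μm wide
        draw_vessel(img, 100, w15)
        draw_vessel(img, 300, w40)
        min_width_px = 25 / (MM_PX * 1000)
        out = global_threshold(img, threshold=20.0, min_width_px=min_width_px)
        assert out[:, 300:300 + w40].all()
        assert not out[:, 100:100 + w15].any()

    def test_below_threshold_everywhere_empty(self):
        out = global_threshold(np.full((64, 64), 5.0), threshold=10.0,
                               min_width_px=3)
        assert not out.any()

    def test_phantom_wide_vessel_survives_mesh_removed(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 30, (512, 512))  # capillary-ish background
        w40 = int(round(40 / (MM_PX * 1000)))
        draw_vessel(img, 250, w40, 200.0)
        out = global_threshold(img, threshold=20.0,
                               min_width_px=25 / (MM_PX * 1000))
        assert out[:, 250:250 + w40].all()
        assert out.sum() <= out[:, 250:250 + w40].size * 1.05


class TestAdaptiveThreshold:
    def test_constant_image_empty(self):
        out = adaptive_threshold(np.full((128, 128), 42.0), window_px=21)
        assert not out.any()

    def test_window_validation(self):
        with pytest.raises(ValueError):
            adaptive_threshold(np.zeros((32, 32)), window_px=20)

    def test_mesh_fraction_recovered(self, phantom):
        a, truth = phantom
        up = upsample(a)
        window = int(round(0.20 / MM_PX)) | 1
        out = adaptive_threshold(up, window, offset=5.0)
        grid = geometry.FoveaCenteredGrid.for_enface(1024, 3.0, "OD")
        taz = geometry.make_taz_mask(grid).pixels
        detected = out[taz].mean()
        true_frac = (truth.capillary_mask | truth.large_vessel_mask)[taz].mean()
        assert detected == pytest.approx(true_frac, abs=0.02)

    def test_offset_monotonicity(self, phantom):
        """Raising the offset (lowering the local threshold) never removes
        detections; equivalently regional RCD is monotone in the offset."""
        a, _ = phantom
        up = upsample(a)
        prev = None
        for offset in (0.0, 3.0, 6.0):
            out = adaptive_threshold(up, 69, offset=offset)
            if prev is not None:
                assert np.all(prev <= out)
            prev = out


class TestVesselMaps:
    def test_set_identities(self):
        rng = np.random.default_rng(3)
        adaptive = rng.random((32, 32)) > 0.4
        large = adaptive & (rng.random((32, 32)) > 0.7)
        maps = VesselMaps.from_components(large, adaptive)
        assert np.array_equal(capillary_map(maps), adaptive & ~large)
        # large pixels outside the adaptive map are forced into the union
        large2 = rng.random((32, 32)) > 0.8
        maps2 = VesselMaps.from_components(large2, adaptive)
        assert np.all(maps2.large_only <= maps2.all_vessels)
        assert (maps2.capillary_only.sum()
                == maps2.all_vessels.sum() - maps2.large_only.sum())

    def test_large_empty_capillary_is_all(self):
        all_v = np.ones((8, 8), bool)
        maps = VesselMaps.from_components(np.zeros((8, 8), bool), all_v)
        assert np.array_equal(maps.capillary_only, all_v)

    def test_large_equals_all_capillary_empty(self):
        v = np.ones((8, 8), bool)
        maps = VesselMaps.from_components(v, v)
        assert not maps.capillary_only.any()

    def test_violated_subset_rejected(self):
        with pytest.raises(ValueError):
            VesselMaps(np.ones((4, 4), bool), np.zeros((4, 4), bool),
                       np.zeros((4, 4), bool))


class TestRCD:
    @pytest.fixture
    def grid(self):
        return geometry.FoveaCenteredGrid.for_enface(256, 3.0, "OD")

    def test_full_coverage_is_hundred(self, grid):
        mask = geometry.make_taz_mask(grid)
        assert rcd(np.ones((256, 256), bool), mask) == 100.0

    def test_half_coverage_is_fifty(self, grid):
        mask = geometry.make_taz_mask(grid)
        vessels = np.zeros((256, 256), bool)
        idx = np.flatnonzero(mask.pixels.ravel())[::2]
        vessels.ravel()[idx] = True
        assert rcd(vessels, mask) == pytest.approx(50.0, abs=0.5)

    def test_empty_mask_rejected(self, grid):
        empty = geometry.RegionMask(grid, "empty", np.zeros((256, 256), bool))
        with pytest.raises(ValueError):
            rcd(np.ones((256, 256), bool), empty)


class TestRCDProfile:
    @pytest.fixture(scope="class")
    def profile(self, phantom):
        a, truth = phantom
        prof, maps = rcd_profile(a, run_faz_detection=False)
        return prof, maps, truth

    def test_gate_failure_raises(self):
        a = make_angiogram(np.zeros((304, 304)), ssi=35.0)
        with pytest.raises(ValueError, match="quality gate"):
            rcd_profile(a)

    def test_taz_equals_ring_area_weighted_mean(self, profile):
        prof, _, _ = profile
        grid = geometry.FoveaCenteredGrid.for_enface(1024, 3.0, "OD")
        rings = geometry.make_ring_series(grid)
        weights = np.array([rings[n].pixel_count for n in geometry.RING_NAMES])
        ring_vals = np.array([prof.values[n] for n in geometry.RING_NAMES])
        weighted = (weights * ring_vals).sum() / weights.sum()
        assert prof.values["TAZ"] == pytest.approx(weighted, abs=0.1)

    def test_taz_equals_sector_area_weighted_mean(self, profile):
        prof, _, _ = profile
        grid = geometry.FoveaCenteredGrid.for_enface(1024, 3.0, "OD")
        sectors = geometry.make_sector_masks(grid)
        weights = np.array([sectors[n].pixel_count for n in geometry.SECTOR_NAMES])
        vals = np.array([prof.values[n] for n in geometry.SECTOR_NAMES])
        weighted = (weights * vals).sum() / weights.sum()
        assert prof.values["TAZ"] == pytest.approx(weighted, abs=0.1)

    def test_uniform_phantom_rings_agree(self):
        """A uniform mesh with no large vessels yields near-identical ring
        densities (C1 excepted: it carries the terminal capillary ring that
        delimits the FAZ, so it is denser by construction)."""
        spec = synth.AngioPhantomSpec(capillary_fraction=0.637, seed=2,
                                      n_large_vessels=0)
        a, _ = synth.make_angiogram_phantom(spec)
        prof, _ = rcd_profile(a, run_faz_detection=False)
        ring_vals = [prof.values[n] for n in geometry.RING_NAMES]
        assert max(ring_vals[1:]) - min(ring_vals[1:]) <= 2.0
        assert ring_vals[0] > max(ring_vals[1:])

    def test_control_level_phantom_recovery(self, phantom):
        """A phantom built at the control superficial-layer TAZ density
        (63.7%) is recovered within 2 percentage points."""
        a, truth = phantom
        prof, _ = rcd_profile(a, run_faz_detection=False)
        assert prof.values["TAZ"] == pytest.approx(
            100 * truth.region_capillary_fraction["TAZ"], abs=2.0)
        assert prof.values["TAZ"] == pytest.approx(63.7, abs=2.5)

    def test_determinism_bit_identical(self, phantom):
        a, _ = phantom
        p1, m1 = rcd_profile(a, run_faz_detection=False)
        p2, m2 = rcd_profile(a, run_faz_detection=False)
        assert p1.values == p2.values
        assert np.array_equal(m1.capillary_only, m2.capillary_only)

    def test_numerator_mode_all_increases_density(self, phantom):
        a, _ = phantom
        cap, _ = rcd_profile(a, run_faz_detection=False)
        allv, _ = rcd_profile(a, rcd_numerator="all", run_faz_detection=False)
        for k in cap.values:
            assert allv.values[k] >= cap.values[k]
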