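"""Chart detection: bright regions, shape filter, partner search, grid,
sampling, saturation, and the full candidate-iteration search."""

from dataclasses import replace

import numpy as np
import pytest

from chartcal.detection import (DetectionConfig, PatchSample, check_saturation,
                                detect_chart, filter_shapes,
                                find_black_partner, find_bright_regions)
from chartcal.synthetic import CameraModel, SceneSpec, render_scene

CFG = DetectionConfig()


def _gray(h, w, value=110):
    return np.full((h, w, 3), value, dtype=np.uint8)


class TestBrightRegions:
    def test_uniform_dark_image_yields_nothing(self):
        assert find_bright_regions(_gray(100, 100, 0), CFG) == []

    def test_single_white_square_bbox(self):
        img = _gray(200, 300)
        img[50:90, 60:110] = 250
        regions = find_bright_regions(img, CFG)
        assert len(regions) == 1
        assert regions[0].bbox == (50, 60, 90, 110)
        assert regions[0].area == 40 * 50
        assert regions[0].fill_ratio == pytest.approx(1.0)

    def test_rejects_single_channel_image(self):
        with pytest.raises(ValueError):
            find_bright_regions(np.zeros((10, 10), dtype=np.uint8), CFG)

    def test_synthetic_scene_contains_white_patch(self, identity_scene, chart):
        img, gt = identity_scene
        regions = find_bright_regions(img, CFG)
        white_ctr = gt.patch_centers[chart.layout.index_of_white - 1]
        dists = [np.hypot(*(r.centroid - white_ctr)) for r in regions]
        assert min(dists) < 2.0


class TestShapeFilter:
    def test_speck_and_huge_regions_discarded(self):
        img = _gray(2000, 3000, 0)
        img[0:3, 0:3] = 255                  # 9-px speck
        img[100:1800, 100:2800] = 255        # ~76% of the image
        regions = find_bright_regions(img, CFG)
        assert filter_shapes(regions, img.shape[:2], CFG) == []

    def test_l_shaped_region_fails_rectangularity(self):
        img = _gray(500, 500, 0)
        img[100:180, 100:140] = 255
        img[140:180, 100:180] = 255          # L-shape, fill ratio ~ 0.7
        regions = find_bright_regions(img, CFG)
        assert len(regions) == 1
        assert regions[0].fill_ratio < 0.85
        assert filter_shapes(regions, img.shape[:2], CFG) == []

    def test_candidate_order_is_by_fill_ratio_then_area(self):
        img = _gray(1000, 1000, 0)
        img[100:140, 100:140] = 255          # square, fill 1.0
        img[300:340, 300:360] = 255          # larger rect, fill 1.0
        rr, cc = np.mgrid[0:39, 0:39]
        disk = (rr - 19) ** 2 + (cc - 19) ** 2 <= 19**2
        img[600:639, 600:639][disk] = 255    # disk, fill ~ pi/4
        regions = find_bright_regions(img, CFG)
        cands = filter_shapes(regions, img.shape[:2],
                              replace(CFG, min_fill_ratio=0.5))
        assert [c.area for c in cands[:2]] == [40 * 60, 40 * 40]
        assert cands[-1].fill_ratio < 0.85


class TestBlackPartner:
    def test_partner_found_on_synthetic_chart(self, identity_scene, chart):
        img, gt = identity_scene
        regions = filter_shapes(find_bright_regions(img, CFG),
                                img.shape[:2], CFG)
        black, direction = find_black_partner(img, regions[0],
                                              chart.layout, CFG)
        true_black = gt.patch_centers[chart.layout.index_of_black - 1]
        assert black is not None
        assert np.hypot(*(black - true_black)) < gt.scene.patch_size / 2

    def test_rotated_chart_partner_direction(self, identity_scene, chart):
        img, _ = identity_scene
        rot = np.rot90(img, 1).copy()
        regions = filter_shapes(find_bright_regions(rot, CFG),
                                rot.shape[:2], CFG)
        black, direction = find_black_partner(rot, regions[0],
                                              chart.layout, CFG)
        assert black is not None
        # white->black axis now points up the rows
        assert abs(direction[0]) > abs(direction[1])

    def test_lone_white_square_has_no_partner(self, chart):
        img = _gray(480, 640)
        img[200:240, 300:340] = 250
        regions = filter_shapes(find_bright_regions(img, CFG),
                                img.shape[:2], CFG)
        black, _ = find_black_partner(img, regions[0], chart.layout, CFG)
        assert black is None


class TestSamplingAndSaturation:
    def test_uniform_patches_sample_exactly(self, noiseless_scene, chart):
        img, gt = noiseless_scene
        result = detect_chart(img, chart)
        assert result.accepted
        ref = chart.srgb_array().astype(float)
        means = np.array([s.mean for s in result.samples])
        assert np.abs(means - ref).max() <= 1.0  # quantisation only

    def test_24_unique_indices(self, identity_scene, chart):
        img, _ = identity_scene
        result = detect_chart(img, chart)
        assert sorted(s.index for s in result.samples) == list(range(1, 25))

    def test_noisy_mean_close_to_truth(self, chart):
        img, gt = render_scene(SceneSpec(seed=77),
                               CameraModel.identity(noise_sd=2.0), chart)
        result = detect_chart(img, chart)
        ref = chart.srgb_array().astype(float)
        for s in result.samples:
            sem = 2.0 / np.sqrt(s.n_pixels)
            assert np.abs(s.mean - ref[s.index - 1]).max() < 3 * sem + 1.0

    @pytest.mark.parametrize("mean,expected_flags", [
        ((254.0, 120.0, 120.0), (True, False, False)),   # 254 > 255-3
        ((2.0, 120.0, 120.0), (True, False, False)),     # 2 < 3
        ((128.0, 128.0, 128.0), (False, False, False)),
        ((252.9, 2.9, 128.0), (True, True, False)),
    ])
    def test_saturation_rule(self, mean, expected_flags):
        s = check_saturation(PatchSample(1, np.array(mean), 100), CFG)
        assert tuple(s.saturated) == expected_flags
        assert s.proper == (not any(expected_flags))

    def test_saturation_agrees_with_brute_force(self, rng):
        """Classifier vs per-channel brute force on 1,000 random samples."""
        means = rng.uniform(0, 255, size=(1000, 3))
        for m in means:
            s = check_saturation(PatchSample(1, m, 100), CFG)
            brute = [bool(c > 255 - CFG.delta or c < CFG.delta) for c in m]
            assert list(s.saturated) == brute


class TestDetectChart:
    def test_clean_scene_accepted_with_correct_grid(self, identity_scene,
                                                    chart):
        img, gt = identity_scene
        result = detect_chart(img, chart)
        assert result.accepted
        assert len(result.samples) == 24
        assert result.n_saturated == 0
        err = np.abs(result.grid.centers() - gt.patch_centers).max()
        assert err < 1.0

    def test_determinism(self, identity_scene, chart):
        img, _ = identity_scene
        r1 = detect_chart(img, chart)
        r2 = detect_chart(img, chart)
        assert np.array_equal(
            np.array([s.mean for s in r1.samples]),
            np.array([s.mean for s in r2.samples]))
        assert np.allclose(r1.grid.affine(), r2.grid.affine())

    def test_no_chart_returns_diagnostics_not_exception(self, chart):
        result = detect_chart(_gray(480, 640), chart)
        assert not result.accepted
        assert result.diagnostics

    def test_sticker_rejected_chart_found(self, identity_scene, chart):
        img, gt = identity_scene
        img = img.copy()
        img[40:80, 40:80] = 250              # decoy white sticker
        result = detect_chart(img, chart)
        assert result.accepted
        err = np.abs(result.grid.centers() - gt.patch_centers).max()
        assert err < 1.0
        assert any("no black partner" in d for d in result.diagnostics)

    def test_heavily_saturated_scene_rejected(self, chart):
        img, _ = render_scene(
            SceneSpec(seed=13),
            CameraModel(matrix=np.eye(3), wb_gains=np.ones(3),
                        exposure_ev=1.0, gamma=2.2, noise_sd=1.0),
            chart)
        result = detect_chart(img, chart)  # default cap: 5 saturated patches
        assert not result.accepted
        assert any("saturated" in d for d in result.diagnostics)

    def test_mirrored_chart_detected(self, chart):
        img, gt = render_scene(SceneSpec(seed=14, mirror=True),
                               CameraModel.identity(noise_sd=1.0), chart)
        result = detect_chart(img, chart)
        assert result.accepted
        assert np.abs(result.grid.centers() - gt.patch_centers).max() < 1.0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_rotation_equivariance(self, noiseless_scene, chart, k):
        """Detection succeeds on 90-degree rotations with identical means."""
        img, _ = noiseless_scene
        base = detect_chart(img, chart)
        rot = detect_chart(np.rot90(img, k).copy(), chart)
        assert base.accepted and rot.accepted
        m0 = np.array([s.mean for s in base.samples])
        mk = np.array([s.mean for s in rot.samples])
        assert np.abs(m0 - mk).max() <= 1.0

    @pytest.mark.parametrize("patch_size", [16.0, 28.0, 64.0])
    def test_scale_invariance(self, chart, patch_size):
        spec = SceneSpec(seed=15, patch_size=patch_size)
        img, gt = render_scene(spec, CameraModel.identity(noise_sd=1.0), chart)
        result = detect_chart(img, chart)
        assert result.accepted
        assert np.abs(result.grid.centers() - gt.patch_centers).max() < 1.5

    def test_jpeg_compression_degrades_gracefully(self, identity_scene,
                                                  chart):
        """Quality-90 JPEG: detection still succeeds; sampled means drift by
        at most a few code values relative to the lossless render."""
        import io
        from PIL import Image
        img, _ = identity_scene
        buf = io.BytesIO()
        Image.fromarray(img).save(buf, format="JPEG", quality=90)
        jpg = np.asarray(Image.open(io.BytesIO(buf.getvalue())))
        result = detect_chart(jpg, chart)
        assert result.accepted
        base = detect_chart(img, chart)
        m0 = np.array([s.mean for s in base.samples])
        mj = np.array([s.mean for s in result.samples])
        assert np.abs(m0 - mj).max() < 5.0

    def test_report_is_json_serialisable(self, identity_scene, chart):
        import json
        img, _ = identity_scene
        rep = detect_chart(img, chart).to_report()
        parsed = json.loads(json.dumps(rep))
        assert parsed["accepted"] and len(parsed["samples"]) == 24
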