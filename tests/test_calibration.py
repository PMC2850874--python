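"""Calibration: tone-curve fitting, polynomial fitting, application, quality
gating and the end-to-end pipeline."""

import numpy as np
import pytest

from chartcal import colorimetry as cm
from chartcal.calibration import (CalibrationConfig, CalibrationError,
                                  apply_calibration, assess_quality,
                                  calibrate_image, fit_calibration,
                                  fit_polynomial, fit_tone_curves)
from chartcal.detection import DetectionConfig, PatchSample, check_saturation
from chartcal.synthetic import CameraModel, SceneSpec, render_scene


def make_samples(chart, cam: CameraModel):
    """Noise-free, unquantised patch samples straight from the camera model."""
    codes = cam.expose(chart.linear_array())
    return [PatchSample(index=i + 1, mean=codes[i], n_pixels=400)
            for i in range(24)]


class TestToneCurves:
    def test_gamma_camera_recovered(self, chart):
        cam = CameraModel(matrix=np.eye(3), wb_gains=np.ones(3), gamma=2.2,
                          noise_sd=0.0)
        luts = fit_tone_curves(make_samples(chart, cam), chart)
        for lut in luts:
            top = lut.anchors[-1, 0]
            codes = np.linspace(0, top, 500)
            assert np.abs(lut(codes) - (codes / 255.0) ** 2.2).max() < 0.01

    def test_identity_linear_camera_gives_linear_ramp(self, chart):
        cam = CameraModel(matrix=np.eye(3), wb_gains=np.ones(3), gamma=1.0,
                          noise_sd=0.0)
        luts = fit_tone_curves(make_samples(chart, cam), chart)
        for lut in luts:
            top = lut.anchors[-1, 0]
            codes = np.linspace(0, top, 500)
            assert np.abs(lut(codes) - codes / 255.0).max() < 0.01

    def test_luts_are_monotone(self, chart):
        cam = CameraModel(noise_sd=0.0)
        for lut in fit_tone_curves(make_samples(chart, cam), chart):
            assert np.all(np.diff(lut.table) >= 0)

    def test_non_monotone_anchors_error(self, chart):
        samples = make_samples(chart, CameraModel.identity())
        samples[19].mean = np.array([10.0, 10.0, 10.0])  # corrupt neutral_8
        with pytest.raises(CalibrationError, match="monotone"):
            fit_tone_curves(samples, chart)

    def test_too_few_neutrals_error(self, chart):
        samples = make_samples(chart, CameraModel.identity())
        for s in samples:
            if s.index in (19, 20, 21):
                s.saturated = np.array([True, False, False])
        with pytest.raises(CalibrationError, match="neutral"):
            fit_tone_curves(samples, chart)

    def test_clamps_above_brightest_anchor(self, chart):
        cam = CameraModel(matrix=np.eye(3), wb_gains=np.ones(3), gamma=2.2,
                          noise_sd=0.0)
        luts = fit_tone_curves(make_samples(chart, cam), chart)
        top_code, top_y = luts[0].anchors[-1]
        assert luts[0](255.0) == pytest.approx(top_y)


class TestPolynomial:
    def test_identity_recovery(self, chart):
        """Samples already linear: transform ~ identity-affine, dE < 0.1."""
        cam = CameraModel(matrix=np.eye(3), wb_gains=np.ones(3), gamma=1.0,
                          noise_sd=0.0)
        samples = make_samples(chart, cam)
        luts = fit_tone_curves(samples, chart)
        tr = fit_polynomial(samples, chart, luts, degree=1)
        model = fit_calibration(samples, chart)
        rep = assess_quality(model, samples, chart)
        assert max(rep.de_per_patch.values()) < 0.1
        # affine part ~ identity (up to the code scale), offset ~ 0
        assert np.allclose(tr.coef[:3], np.eye(3), atol=0.02)
        assert np.allclose(tr.coef[3], 0.0, atol=0.01)

    def test_known_mixing_matrix_recovered(self, chart):
        M = np.array([[.8, .15, .05], [.1, .8, .1], [.05, .2, .75]])
        cam = CameraModel(matrix=M, wb_gains=np.ones(3), gamma=1.0,
                          noise_sd=0.0)
        samples = make_samples(chart, cam)
        model = fit_calibration(samples, chart)
        rep = assess_quality(model, samples, chart)
        assert max(rep.de_per_patch.values()) < 0.1

    def test_insufficient_patches_error(self, chart):
        samples = make_samples(chart, CameraModel.identity())[:9]
        luts = fit_tone_curves(make_samples(chart, CameraModel.identity()),
                               chart)
        with pytest.raises(CalibrationError, match="proper patches"):
            fit_polynomial(samples, chart, luts, degree=1)

    def test_degree2_needs_more_patches_than_terms(self, chart):
        samples = make_samples(chart, CameraModel.identity())[:9]
        luts = fit_tone_curves(make_samples(chart, CameraModel.identity()),
                               chart)
        with pytest.raises(CalibrationError):
            fit_polynomial(samples, chart, luts, degree=2)

    def test_degree2_supported_on_full_chart(self, chart):
        samples = make_samples(chart, CameraModel(noise_sd=0.0))
        model = fit_calibration(samples, chart,
                                CalibrationConfig(poly_degree=2))
        rep = assess_quality(model, samples, chart)
        assert rep.median_fit < 1.0


class TestApplyAndQuality:
    def test_identity_model_reproduces_image(self, chart):
        """sRGB-coded camera: pixels in the anchored code range round-trip.

        Below the darkest wedge anchor the tone curve is extrapolated (the
        chart carries no information there), so the check covers codes from
        the black patch upward.
        """
        samples = make_samples(chart, CameraModel.identity())
        model = fit_calibration(samples, chart)
        lo = int(np.ceil(model.luts[0].anchors[1, 0]))
        hi = int(np.floor(model.luts[0].anchors[-1, 0]))  # clamp beyond white
        img = np.linspace(lo, hi, 48).astype(np.uint8).reshape(4, 4, 3)
        out = apply_calibration(img, model)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 1

    def test_permuted_reference_fails_quality(self, chart):
        samples = make_samples(chart, CameraModel.identity())
        perm = list(samples)
        means = [s.mean for s in perm]
        for s, m in zip(perm, means[::-1]):   # scramble sample<->patch pairing
            s.mean = m
        try:
            model = fit_calibration(perm, chart)
            rep = assess_quality(model, perm, chart)
            assert not rep.passed
        except CalibrationError:
            pass  # scrambled neutrals may already break the tone-curve fit

    def test_saturation_exclusion_does_not_hurt_proper_patches(self, chart):
        """Fitting without clipped patches is never worse for proper ones."""
        cam = CameraModel(matrix=np.eye(3), wb_gains=np.ones(3),
                          exposure_ev=0.5, gamma=2.2, noise_sd=0.0)
        samples = [check_saturation(s, DetectionConfig())
                   for s in make_samples(chart, cam)]
        proper = [s for s in samples if s.proper]
        model_ex = fit_calibration(samples, chart)
        rep_ex = assess_quality(model_ex, proper, chart)
        # force-include clipped patches in the fit
        forced = [PatchSample(s.index, s.mean, s.n_pixels) for s in samples]
        model_in = fit_calibration(forced, chart)
        rep_in = assess_quality(model_in, proper, chart)
        med_ex = np.median([rep_ex.de_per_patch[s.index] for s in proper])
        med_in = np.median([rep_in.de_per_patch[s.index] for s in proper])
        assert med_ex <= med_in + 1e-9


class TestEndToEnd:
    def test_clean_scene_calibrates_below_2_de(self, chart):
        img, _ = render_scene(SceneSpec(seed=21),
                              CameraModel(noise_sd=1.0), chart)
        cal, det, model = calibrate_image(img, chart)
        assert cal is not None
        assert model.quality.median_fit < 2.0

    def test_no_chart_returns_diagnostics(self, chart):
        img = np.full((480, 640, 3), 110, dtype=np.uint8)
        cal, det, model = calibrate_image(img, chart)
        assert cal is None and model is None
        assert det.diagnostics

    def test_180_rotation_gives_same_patch_colours(self, chart):
        img, _ = render_scene(SceneSpec(seed=22),
                              CameraModel(noise_sd=1.0), chart)
        cal0, det0, m0 = calibrate_image(img, chart)
        cal2, det2, m2 = calibrate_image(np.rot90(img, 2).copy(), chart)
        lab0 = m0.samples_to_lab(np.array([s.mean for s in det0.samples]))
        lab2 = m2.samples_to_lab(np.array([s.mean for s in det2.samples]))
        assert cm.delta_e_ab(lab0, lab2).max() < 0.5

    def test_already_srgb_image_nearly_unchanged(self, chart):
        """Idempotence in the limit: sRGB chart scene recalibrates to < 1 dE."""
        img, _ = render_scene(SceneSpec(seed=23), CameraModel.identity(),
                              chart)
        cal, det, model = calibrate_image(img, chart)
        assert max(model.quality.de_per_patch.values()) < 1.0

    def test_calibration_reduces_median_de(self, chart):
        img, _ = render_scene(SceneSpec(seed=24, illuminant="A"),
                              CameraModel(noise_sd=2.0), chart)
        cal, det, model = calibrate_image(img, chart)
        means = np.array([s.mean for s in det.samples])
        de_cal = cm.delta_e_ab(model.samples_to_lab(means), chart.lab_array())
        de_raw = cm.delta_e_ab(cm.srgb8_to_lab(means), chart.lab_array())
        assert np.median(de_cal) < np.median(de_raw)
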