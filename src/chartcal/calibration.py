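"""Camera -> sRGB colour calibration from detected chart patches.

Two-stage model: (1) three per-channel tone-curve look-up tables, estimated
from the grayscale wedge, map device code values to linear intensities;
(2) a least-squares polynomial (affine by default) maps the linearised
device triples onto the chart's reference linear-sRGB triples.  Saturated
("improper") patches are excluded from both fits.  Calibration quality is
judged by the dE_ab between calibrated patch colours and the reference
values, and a failed quality gate sends chart detection back to the
candidate search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from . import colorimetry as cm
from .chart import ReferenceChart
from .detection import (DetectionConfig, DetectionResult, PatchSample,
                        detect_chart)

__all__ = [
    "CalibrationConfig",
    "ToneCurveLUT",
    "ColorTransform",
    "QualityReport",
    "CalibrationModel",
    "CalibrationError",
    "fit_tone_curves",
    "fit_polynomial",
    "apply_calibration",
    "assess_quality",
    "calibrate_image",
]

DEFAULT_FIT_HALF = tuple(range(13, 25))  # patches used in split-half calibration


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibrationConfig:
    poly_degree: int = 1
    ceiling_fit: float = 10.0        # quality gate: median dE over fit patches
    ceiling_holdout: float = 15.0    # ... over proper patches outside the fit
    min_fit_patches: int = 10
    min_neutral_patches: int = 4
    fit_half: tuple[int, ...] = DEFAULT_FIT_HALF  # split-half protocol only


@dataclass
class ToneCurveLUT:
    """Device-code -> linear-intensity tone curve for one channel.

    ``table`` is the 256-entry export used for whole-image application;
    fractional code values (patch means) evaluate the continuous curve
    itself when available, so the fitted anchors are reproduced exactly.
    """

    table: np.ndarray                   # (256,) monotone non-decreasing
    anchors: np.ndarray                 # (k, 2) (code, linear) pairs used
    curve: object = None                # continuous callable, optional

    def __post_init__(self):
        if np.any(np.diff(self.table) < -1e-12):
            raise CalibrationError("tone curve LUT must be monotone")

    def __call__(self, codes) -> np.ndarray:
        """Evaluate at (possibly fractional) code values."""
        c = np.asarray(codes, float)
        if self.curve is not None:
            return self.curve(c)
        return np.interp(c, np.arange(256), self.table)


@dataclass
class ColorTransform:
    """Polynomial map from linearised device RGB to linear sRGB."""

    degree: int
    coef: np.ndarray                    # (n_terms, 3)

    def __call__(self, linear_rgb: np.ndarray) -> np.ndarray:
        return _monomials(np.asarray(linear_rgb, float), self.degree) @ self.coef


@dataclass
class QualityReport:
    de_per_patch: dict[int, float]      # calibrated sample vs reference, dE_ab
    fit_indices: tuple[int, ...]
    holdout_indices: tuple[int, ...]
    median_fit: float
    median_holdout: float               # nan when no proper holdout patches
    passed: bool


@dataclass
class CalibrationModel:
    luts: tuple[ToneCurveLUT, ToneCurveLUT, ToneCurveLUT]
    transform: ColorTransform
    fit_indices: tuple[int, ...]
    quality: QualityReport | None = None

    def linearize(self, codes: np.ndarray) -> np.ndarray:
        """Apply the three LUTs to (..., 3) device code values."""
        c = np.asarray(codes, float)
        return np.stack([self.luts[i](c[..., i]) for i in range(3)], axis=-1)

    def samples_to_lab(self, means: np.ndarray) -> np.ndarray:
        """Calibrated Lab of (..., 3) device-code patch means."""
        lin = self.transform(self.linearize(means))
        return cm.xyz_to_lab(cm.linear_to_xyz(lin))


def _monomials(rgb: np.ndarray, degree: int) -> np.ndarray:
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    ones = np.ones_like(r)
    terms = [r, g, b, ones]
    if degree >= 2:
        terms += [r * r, g * g, b * b, r * g, r * b, g * b]
    if degree not in (1, 2):
        raise ValueError("poly_degree must be 1 or 2")
    return np.stack(terms, axis=-1)


def n_terms(degree: int) -> int:
    return 4 if degree == 1 else 10


class _LogLogCurve:
    """Monotone PCHIP through (code, linear) anchors in log-log coordinates.

    Exact for pure power-law (gamma) responses; continues below the darkest
    anchor as the power law through the origin matching that anchor's local
    log-log slope, and clamps above the brightest anchor.
    """

    def __init__(self, codes: np.ndarray, ys: np.ndarray):
        self.codes = codes
        self.ys = ys
        self._interp = PchipInterpolator(np.log(codes), np.log(ys))
        self.toe_slope = max(float(self._interp(np.log(codes[0]), 1)), 1e-6)

    def __call__(self, c) -> np.ndarray:
        c = np.asarray(c, float)
        out = np.empty(c.shape)
        lo = c < self.codes[0]
        hi = c > self.codes[-1]
        zero = c <= 0
        mid = ~lo & ~hi
        out[mid] = np.exp(self._interp(np.log(c[mid])))
        with np.errstate(invalid="ignore"):
            out[lo] = self.ys[0] * np.power(c[lo] / self.codes[0], self.toe_slope)
        out[zero] = 0.0
        out[hi] = self.ys[-1]
        return out


def fit_tone_curves(samples: list[PatchSample], chart: ReferenceChart,
                    cfg: CalibrationConfig | None = None):
    """Estimate the three tone-curve LUTs from the proper grayscale patches.

    Each channel's anchors pair the patch's mean device code with the patch's
    reference relative luminance Y (D65 white = 1); (0, 0) is prepended and
    codes beyond the brightest anchor clamp to its value.  Interpolation is
    monotone piecewise-cubic (PCHIP) in log-log coordinates, which represents
    any pure power-law (gamma) response exactly; below the darkest anchor the
    curve continues as the power law through the origin that matches the
    anchor and its local log-log slope.
    """
    cfg = cfg or CalibrationConfig()
    layout = chart.layout
    by_index = {s.index: s for s in samples}
    neutral = [by_index[i] for i in layout.neutral_row_indices
               if i in by_index and by_index[i].proper]
    if len(neutral) < cfg.min_neutral_patches:
        raise CalibrationError(
            f"need >= {cfg.min_neutral_patches} proper neutral patches, "
            f"got {len(neutral)}")
    y_by_index = dict(zip(layout.neutral_row_indices, chart.neutral_luminances()))
    luts = []
    grid = np.arange(256, dtype=float)
    for ch in range(3):
        codes = np.array([s.mean[ch] for s in neutral])
        ys = np.array([y_by_index[s.index] for s in neutral])
        order = np.argsort(codes)
        codes, ys = codes[order], ys[order]
        x = np.concatenate([[0.0], codes])
        y = np.concatenate([[0.0], ys])
        if np.any(np.diff(x) <= 0) or np.any(np.diff(y) <= 0):
            raise CalibrationError(
                f"channel {ch}: non-monotone tone-curve anchors "
                f"(codes {x.round(2).tolist()}, targets {y.round(4).tolist()})")
        curve = _LogLogCurve(codes, ys)
        table = np.maximum.accumulate(np.clip(curve(grid), 0.0, None))
        luts.append(ToneCurveLUT(table=table, anchors=np.column_stack([x, y]),
                                 curve=curve))
    return tuple(luts)


def fit_polynomial(samples: list[PatchSample], chart: ReferenceChart,
                   luts, degree: int = 1,
                   cfg: CalibrationConfig | None = None) -> ColorTransform:
    """Least-squares polynomial from linearised proper samples to reference
    linear sRGB."""
    cfg = cfg or CalibrationConfig()
    proper = [s for s in samples if s.proper]
    need = max(cfg.min_fit_patches, n_terms(degree))
    if len(proper) < need:
        raise CalibrationError(
            f"need >= {need} proper patches for degree {degree}, got {len(proper)}")
    model = CalibrationModel(luts=tuple(luts),
                             transform=ColorTransform(degree, np.zeros(1)),
                             fit_indices=())
    lin = model.linearize(np.array([s.mean for s in proper]))
    X = _monomials(lin, degree)
    target = chart.linear_array()[[s.index - 1 for s in proper]]
    coef, _, rank, _ = np.linalg.lstsq(X, target, rcond=None)
    if rank < X.shape[1]:
        raise CalibrationError(f"rank-deficient design matrix (rank {rank} < "
                               f"{X.shape[1]})")
    return ColorTransform(degree=degree, coef=coef)


def fit_calibration(samples: list[PatchSample], chart: ReferenceChart,
                    cfg: CalibrationConfig | None = None,
                    fit_indices: tuple[int, ...] | None = None) -> CalibrationModel:
    """Tone curves + polynomial in one step.

    ``fit_indices`` restricts the polynomial fit to a subset of patches
    (split-half protocol); tone curves always use the proper grayscale
    patches available in that subset.
    """
    cfg = cfg or CalibrationConfig()
    subset = samples if fit_indices is None else [
        s for s in samples if s.index in fit_indices]
    luts = fit_tone_curves(subset, chart, cfg)
    transform = fit_polynomial(subset, chart, luts, cfg.poly_degree, cfg)
    used = tuple(sorted(s.index for s in subset if s.proper))
    return CalibrationModel(luts=luts, transform=transform, fit_indices=used)


def assess_quality(model: CalibrationModel, samples: list[PatchSample],
                   chart: ReferenceChart,
                   cfg: CalibrationConfig | None = None) -> QualityReport:
    """dE_ab of calibrated patch samples against the reference values.

    Pass requires the median over fit patches and the median over proper
    non-fit patches (when any exist) to stay under the configured ceilings.
    """
    cfg = cfg or CalibrationConfig()
    ref = chart.lab_array()
    de = {}
    for s in samples:
        lab = model.samples_to_lab(s.mean)
        de[s.index] = float(cm.delta_e_ab(lab, ref[s.index - 1]))
    fit = tuple(i for i in model.fit_indices if i in de)
    holdout = tuple(s.index for s in samples
                    if s.proper and s.index not in model.fit_indices)
    med_fit = float(np.median([de[i] for i in fit])) if fit else float("nan")
    med_hold = float(np.median([de[i] for i in holdout])) if holdout else float("nan")
    passed = bool(fit) and med_fit <= cfg.ceiling_fit and (
        not holdout or med_hold <= cfg.ceiling_holdout)
    report = QualityReport(de_per_patch=de, fit_indices=fit,
                           holdout_indices=holdout, median_fit=med_fit,
                           median_holdout=med_hold, passed=passed)
    model.quality = report
    return report


def apply_calibration(image: np.ndarray, model: CalibrationModel) -> np.ndarray:
    """Map a whole 8-bit device-RGB image to 8-bit sRGB through the model."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) image")
    if img.dtype != np.uint8:
        raise ValueError("expected an 8-bit image")
    # integer codes index the LUT directly; polynomial + sRGB encode per pixel
    lin = np.stack([model.luts[i].table[img[..., i]] for i in range(3)], axis=-1)
    out = model.transform(lin)
    return cm.encode_srgb(out)


def calibrate_image(image: np.ndarray, chart: ReferenceChart,
                    det_cfg: DetectionConfig | None = None,
                    cal_cfg: CalibrationConfig | None = None):
    """Full pipeline: detect -> fit -> quality gate -> apply.

    Returns ``(calibrated_image | None, DetectionResult, CalibrationModel | None)``.
    The quality assessment is the gate supplied to chart detection, so a
    candidate that detects geometrically but calibrates poorly is rejected
    and the search continues.
    """
    det_cfg = det_cfg or DetectionConfig()
    cal_cfg = cal_cfg or CalibrationConfig()

    def gate(samples: list[PatchSample]):
        try:
            model = fit_calibration(samples, chart, cal_cfg)
        except CalibrationError:
            return False, None
        report = assess_quality(model, samples, chart, cal_cfg)
        return report.passed, model

    result = detect_chart(image, chart, det_cfg, quality_gate=gate)
    if not result.accepted:
        return None, result, None
    model: CalibrationModel = result.gate_payload
    calibrated = apply_calibration(image, model)
    return calibrated, result, model


def calibration_report(model: CalibrationModel,
                       result: DetectionResult | None = None) -> dict:
    """JSON-serialisable calibration report."""
    rep = {
        "poly_degree": model.transform.degree,
        "coefficients": model.transform.coef.tolist(),
        "lut_anchors": [lut.anchors.tolist() for lut in model.luts],
        "fit_indices": list(model.fit_indices),
    }
    if model.quality is not None:
        q = model.quality
        rep["quality"] = {
            "de_per_patch": {str(k): round(v, 4) for k, v in q.de_per_patch.items()},
            "median_fit": q.median_fit,
            "median_holdout": q.median_holdout,
            "passed": q.passed,
        }
    if result is not None:
        rep["detection"] = result.to_report()
    return rep
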