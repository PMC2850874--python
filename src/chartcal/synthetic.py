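"""Seeded synthetic scenes: a colour chart (and optionally a wound) pushed
through a parametric camera model, with full ground truth.

The generator emulates studio shots of the 24-patch chart on a grey
background under a factorial grid of conditions — illuminant colour
temperature, exposure bias, white-balance state — plus hand-held wound
photographs for the rotation-reproducibility experiment.  Scene radiometry
is deliberately simple (flat patches, per-channel illuminant scaling,
global exposure): just enough physics to exercise every stage of chart
detection and calibration, not a renderer.

Camera pipeline per pixel: scene linear sRGB -> illuminant tint ->
white-balance gains -> 3x3 channel mixing -> exposure (2^EV) -> clip ->
per-channel gamma encode (or the sRGB curve) -> additive Gaussian noise in
code values -> clip -> quantise to 8 bits.  Everything is deterministic for
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import ndimage
from skimage import draw

from . import colorimetry as cm
from .chart import ChartLayout, ReferenceChart, load_reference

__all__ = [
    "CameraModel",
    "WoundSpec",
    "SceneSpec",
    "GroundTruth",
    "ILLUMINANTS",
    "render_scene",
    "render_wound_scene",
    "condition_grid",
    "samples_from_ground_truth",
]

# Per-channel linear scaling applied to scene colours, emulating the cabinet
# illuminants relative to D65 (a spectral model is out of scope).
ILLUMINANTS = {
    "D65": np.array([1.00, 1.00, 1.00]),   # noon daylight, 6504 K
    "TL84": np.array([1.10, 1.00, 0.85]),  # cool-white fluorescent, ~4000 K
    "A": np.array([1.25, 1.00, 0.65]),     # tungsten, ~2856 K
}

# A failed auto-white-balance: fixed cool preset matching none of the cabinet
# illuminants, so a mismatched-WB image differs from every correct-WB one.
MISMATCHED_WB_GAINS = np.array([0.75, 1.00, 1.30])

# "Correct" white balance per illuminant: the camera's discrete preset, close
# to (but not exactly) the inverse of the actual illuminant tint — as with a
# real camera, a small residual cast remains even with the right setting.
WB_PRESETS = {
    "D65": np.array([1.00, 1.00, 1.00]),
    "TL84": np.array([1.0 / 1.06, 1.00, 1.0 / 0.89]),
    "A": np.array([1.0 / 1.32, 1.00, 1.0 / 0.60]),
}

_DEFAULT_MATRIX = np.array([
    [0.86, 0.16, 0.02],
    [0.09, 0.82, 0.07],
    [0.03, 0.14, 0.88],
])


@dataclass(frozen=True)
class CameraModel:
    """Parametric in-camera processing model."""

    matrix: np.ndarray = field(default_factory=lambda: _DEFAULT_MATRIX.copy())
    wb_gains: np.ndarray = field(default_factory=lambda: np.ones(3))
    exposure_ev: float = 0.0
    gamma: float | None = 1.8      # encoding gamma; None = exact sRGB curve
    noise_sd: float = 2.0          # additive Gaussian noise, code values
    clip: bool = True

    def __post_init__(self):
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if np.any(np.asarray(self.wb_gains) <= 0) or self.noise_sd < 0:
            raise ValueError("gains must be > 0 and noise_sd >= 0")

    @staticmethod
    def identity(noise_sd: float = 0.0) -> "CameraModel":
        """A camera that encodes scene colours exactly as sRGB."""
        return CameraModel(matrix=np.eye(3), wb_gains=np.ones(3),
                           exposure_ev=0.0, gamma=None, noise_sd=noise_sd)

    def expose(self, linear_scene: np.ndarray, tint=None) -> np.ndarray:
        """Scene linear sRGB -> noise-free float code values (0..255)."""
        lin = np.asarray(linear_scene, float)
        if tint is not None:
            lin = lin * np.asarray(tint, float)
        # white balance acts on the sensor channels, before colour mixing
        lin = lin * np.asarray(self.wb_gains, float)
        mixed = lin @ np.asarray(self.matrix, float).T * 2.0 ** self.exposure_ev
        if self.clip:
            mixed = np.clip(mixed, 0.0, 1.0)
        else:
            mixed = np.clip(mixed, 0.0, None)
        if self.gamma is None:
            return cm.encode_srgb_float(mixed)
        return 255.0 * mixed ** (1.0 / self.gamma)


@dataclass(frozen=True)
class WoundSpec:
    """A mottled ellipse standing in for a wound bed."""

    center: tuple[float, float] = (360.0, 320.0)   # (row, col)
    semi_axes: tuple[float, float] = (70.0, 110.0)
    base_lab: tuple[float, float, float] = (48.0, 32.0, 18.0)  # desaturated red
    mottle_amplitude: float = 0.15     # relative amplitude on linear intensity
    roi_half: tuple[float, float] = (30.0, 60.0)   # ROI half-extent (row, col)


@dataclass(frozen=True)
class SceneSpec:
    """Chart-bearing scene description; fully determines the render with the
    camera and the seed."""

    width: int = 640
    height: int = 480
    background_srgb: tuple[int, int, int] = (110, 110, 110)
    chart_center: tuple[float, float] = (240.0, 320.0)  # (row, col)
    patch_size: float = 40.0           # patch side, px
    rotation_deg: float = 0.0
    mirror: bool = False
    illuminant: str = "D65"
    wound: WoundSpec | None = None
    seed: int = 0

    def tint(self) -> np.ndarray:
        return ILLUMINANTS[self.illuminant]


@dataclass
class GroundTruth:
    """Renderer-side truth for validating detection and calibration."""

    patch_centers: np.ndarray          # (24, 2) (row, col) px
    window_half: float                 # half-size of the central 50% window
    patch_linear: np.ndarray           # (24, 3) tinted linear colour, pre-camera
    scene: SceneSpec
    camera: CameraModel
    chart_corners: np.ndarray          # (4, 2) outer corners of the chart
    roi_polygon: np.ndarray | None = None  # (k, 2) (row, col) vertices

    def windows(self) -> list[tuple[int, int, int, int]]:
        out = []
        for ctr in self.patch_centers:
            r0 = int(round(ctr[0] - self.window_half))
            c0 = int(round(ctr[1] - self.window_half))
            r1 = int(round(ctr[0] + self.window_half))
            c1 = int(round(ctr[1] + self.window_half))
            out.append((r0, c0, r1, c1))
        return out


def _chart_geometry(spec: SceneSpec, layout: ChartLayout):
    """Patch polygons and centres in image coordinates."""
    p = spec.patch_size
    pitch = p * (1 + layout.gap_fraction)
    border = 0.35 * p
    w = (layout.cols - 1) * pitch + p + 2 * border
    h = (layout.rows - 1) * pitch + p * layout.patch_aspect + 2 * border
    th = np.deg2rad(spec.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    mir = np.diag([1.0, -1.0 if spec.mirror else 1.0])
    xform = rot @ mir
    ctr = np.asarray(spec.chart_center, float)

    def to_image(local):  # local (row, col) about chart centre
        return (np.atleast_2d(local) @ xform.T) + ctr

    corners = to_image(np.array([[-h / 2, -w / 2], [-h / 2, w / 2],
                                 [h / 2, w / 2], [h / 2, -w / 2]]))
    cells = []
    centers = np.zeros((layout.n_patches, 2))
    for idx in range(1, layout.n_patches + 1):
        r, c = layout.cell_of(idx)
        cr = -h / 2 + border + r * pitch + p / 2
        cc = -w / 2 + border + c * pitch + p / 2
        half = p / 2
        quad = np.array([[cr - half, cc - half], [cr - half, cc + half],
                         [cr + half, cc + half], [cr + half, cc - half]])
        cells.append(to_image(quad))
        centers[idx - 1] = to_image(np.array([cr, cc]))[0]
    return corners, cells, centers


def render_scene(spec: SceneSpec, cam: CameraModel,
                 chart: ReferenceChart | None = None):
    """Render the scene through the camera; returns ``(image8, GroundTruth)``."""
    chart = chart or load_reference()
    layout = chart.layout
    corners, cells, centers = _chart_geometry(spec, layout)
    H, W = spec.height, spec.width
    if (corners[:, 0].min() < 0 or corners[:, 1].min() < 0
            or corners[:, 0].max() >= H or corners[:, 1].max() >= W):
        raise ValueError("chart extends outside the image")

    tint = spec.tint()
    bg_lin = cm.decode_srgb(np.asarray(spec.background_srgb, float))
    surround_lin = np.full(3, 0.02)          # chart's matte black frame
    patch_lin = np.clip(chart.linear_array(), 0.0, None)

    codes = np.empty((H, W, 3), dtype=float)
    codes[:] = cam.expose(bg_lin, tint)
    rr, cc = draw.polygon(corners[:, 0], corners[:, 1], shape=(H, W))
    codes[rr, cc] = cam.expose(surround_lin, tint)
    for idx, quad in enumerate(cells):
        rr, cc = draw.polygon(quad[:, 0], quad[:, 1], shape=(H, W))
        codes[rr, cc] = cam.expose(patch_lin[idx], tint)

    rng = np.random.default_rng(spec.seed)
    roi_poly = None
    if spec.wound is not None:
        roi_poly = _render_wound(codes, spec, cam, tint, rng)
    if cam.noise_sd > 0:
        codes = codes + rng.normal(0.0, cam.noise_sd, size=codes.shape)
    img = np.clip(np.rint(codes), 0, 255).astype(np.uint8)

    gt = GroundTruth(
        patch_centers=centers,
        window_half=0.25 * spec.patch_size,   # central 50% of the cell
        patch_linear=patch_lin * tint,
        scene=spec,
        camera=cam,
        chart_corners=corners,
        roi_polygon=roi_poly,
    )
    return img, gt


def _render_wound(codes: np.ndarray, spec: SceneSpec, cam: CameraModel,
                  tint: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Paint the wound ellipse in place; returns the ROI polygon."""
    w = spec.wound
    H, Wd = codes.shape[:2]
    rr, cc = draw.ellipse(w.center[0], w.center[1], w.semi_axes[0],
                          w.semi_axes[1], shape=(H, Wd))
    base_lin = np.clip(cm.lab_to_linear(np.asarray(w.base_lab, float)), 0, None)
    if w.mottle_amplitude > 0:
        coarse = rng.standard_normal((8, 8))
        fld = ndimage.zoom(coarse, (H / 8, Wd / 8), order=3)[:H, :Wd]
        fld = fld / max(np.abs(fld).max(), 1e-9)
        factor = 1.0 + w.mottle_amplitude * fld[rr, cc]
    else:
        factor = np.ones(len(rr))
    lin = np.clip(base_lin[None, :] * factor[:, None], 0.0, None)
    codes[rr, cc] = cam.expose(lin, tint)
    hr, hc = w.roi_half
    r0, c0 = w.center
    return np.array([[r0 - hr, c0 - hc], [r0 - hr, c0 + hc],
                     [r0 + hr, c0 + hc], [r0 + hr, c0 - hc]])


def render_wound_scene(spec: SceneSpec, cam: CameraModel,
                       chart: ReferenceChart | None = None):
    """Render a wound-bearing scene; errors if the spec has no wound."""
    if spec.wound is None:
        raise ValueError("SceneSpec.wound must be set for a wound scene")
    return render_scene(spec, cam, chart)


def default_wound_scene(seed: int, rng: np.random.Generator | None = None) -> tuple:
    """A clinically plausible wound scene + camera for a given seed.

    Illuminant drawn among the three cabinet lights with correct white
    balance, small random chart rotation, camera noise sd 2 code values.
    """
    rng = rng or np.random.default_rng(seed)
    ill = ("D65", "TL84", "A")[int(rng.integers(3))]
    spec = SceneSpec(
        chart_center=(150.0, 320.0),
        rotation_deg=float(rng.uniform(-4, 4)),
        illuminant=ill,
        wound=WoundSpec(),
        seed=int(rng.integers(2**31 - 1)),
    )
    cam = CameraModel(wb_gains=WB_PRESETS[ill], noise_sd=2.0)
    return spec, cam


def condition_grid(base_scene: SceneSpec | None = None,
                   base_camera: CameraModel | None = None,
                   illuminants: Iterable[str] = ("D65", "TL84", "A"),
                   exposures: Iterable[float] = (-1.0, 0.0, 1.0),
                   white_balance: Iterable[str] = ("correct", "mismatched"),
                   master_seed: int = 0) -> list[dict]:
    """Cartesian grid of acquisition conditions, seeded from ``master_seed``.

    Each cell is a dict with keys ``illuminant, exposure_ev, white_balance,
    normal, scene, camera``; ``normal`` marks proper camera settings (no
    exposure bias, correct white balance).
    """
    base_scene = base_scene or SceneSpec()
    base_camera = base_camera or CameraModel()
    cells = []
    i = 0
    for ill in illuminants:
        for ev in exposures:
            for wb in white_balance:
                gains = (WB_PRESETS[ill] if wb == "correct"
                         else MISMATCHED_WB_GAINS)
                scene = replace(base_scene, illuminant=ill,
                                seed=(master_seed * 1009 + i) % (2**31 - 1))
                camera = replace(base_camera, exposure_ev=float(ev),
                                 wb_gains=gains)
                cells.append({
                    "illuminant": ill,
                    "exposure_ev": float(ev),
                    "white_balance": wb,
                    "normal": ev == 0.0 and wb == "correct",
                    "scene": scene,
                    "camera": camera,
                })
                i += 1
    return cells


def samples_from_ground_truth(image: np.ndarray, gt: GroundTruth):
    """Patch samples taken at the renderer's true windows (detector bypass)."""
    from .detection import PatchSample  # local import to avoid cycle at import time

    img = np.asarray(image, dtype=float)
    out = []
    for idx, (r0, c0, r1, c1) in enumerate(gt.windows(), start=1):
        win = img[r0:r1, c0:c1].reshape(-1, 3)
        out.append(PatchSample(index=idx, mean=win.mean(axis=0), n_pixels=len(win)))
    return out
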