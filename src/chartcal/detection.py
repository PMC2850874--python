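"""Automatic localisation of the 24-patch chart in a photograph.

Strategy: threshold the image for bright, rectangular regions (white-patch
candidates); for each candidate search for the chart's black patch five patch
pitches away along the candidate's principal directions; lay an affine patch
grid between the two; sample every patch; flag channel saturation; and hand
the samples to a caller-supplied calibration quality gate.  Candidates are
iterated deterministically until one passes every gate; if none does the
brightness threshold is relaxed stepwise and the search repeats.

Coordinates are 0-based ``(row, col)`` floats at pixel centres; sampling
windows are half-open integer ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .chart import ChartLayout, ReferenceChart

__all__ = [
    "DetectionConfig",
    "Region",
    "PatchSample",
    "PatchGrid",
    "DetectionResult",
    "find_bright_regions",
    "filter_shapes",
    "find_black_partner",
    "build_patch_grid",
    "sample_patches",
    "check_saturation",
    "detect_chart",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds of the chart detector (defaults in code values)."""

    bright_threshold: int = 230          # min-channel level for "bright"
    bright_threshold_min: int = 140      # relaxation floor when search fails
    bright_threshold_step: int = 30
    delta: float = 3.0                   # saturation margin (codes from 0/255)
    max_saturated_patches: int = 5       # "fewer than 6 of 24"
    min_area_frac: float = 5e-5          # white patch area / image area bounds
    max_area_frac: float = 0.02
    min_fill_ratio: float = 0.85         # rectangularity gate
    sample_window_frac: float = 0.5      # central fraction of each cell sampled
    dark_fraction: float = 0.35          # black patch: max channel <= frac * white level
    partner_size_tol: float = 0.5        # black patch size tolerance vs white
    min_window_pixels: int = 25
    min_diversity: float = 20.0          # mean pairwise distance of colour patches

    def __post_init__(self):
        if not 0 < self.delta < 128:
            raise ValueError("delta must be in (0, 128)")
        if not 0 <= self.bright_threshold <= 255:
            raise ValueError("bright_threshold must be in [0, 255]")
        if not 0 < self.sample_window_frac < 1:
            raise ValueError("sample_window_frac must be in (0, 1)")
        if not 0 < self.min_area_frac < self.max_area_frac < 1:
            raise ValueError("need 0 < min_area_frac < max_area_frac < 1")


@dataclass
class Region:
    """A connected bright region with rectangle-fit geometry."""

    label: int
    bbox: tuple[int, int, int, int]     # (min_row, min_col, max_row, max_col), half-open
    area: int                           # pixel count
    centroid: np.ndarray                # (row, col)
    fill_ratio: float                   # area / min-area-rectangle area
    angle: float                        # principal axis angle, radians
    side_lengths: tuple[float, float]   # min-area rect sides (long, short), px
    axes: np.ndarray                    # (2, 2) unit side directions of the rect


def _min_area_rect(coords: np.ndarray):
    """Min-area bounding rectangle of pixel-centre coordinates.

    Returns (area, (w, h), angle, axes); the footprint adds one pixel per
    side because coords are centres.  Degenerate point sets fall back to the
    axis-aligned box.
    """
    pts = coords.astype(float)
    try:
        hull = pts[ConvexHull(pts).vertices]
    except (QhullError, IndexError):
        hull = None
    if hull is None or len(hull) < 3:
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        w, h = (hi - lo) + 1.0
        return w * h, (w, h), 0.0, np.array([[0.0, 1.0], [1.0, 0.0]])
    best = None
    n = len(hull)
    for i in range(n):
        e = hull[(i + 1) % n] - hull[i]
        norm = np.hypot(*e)
        if norm < 1e-12:
            continue
        u = e / norm
        v = np.array([-u[1], u[0]])
        pu = hull @ u
        pv = hull @ v
        w = pu.max() - pu.min() + 1.0
        h = pv.max() - pv.min() + 1.0
        area = w * h
        if best is None or area < best[0]:
            best = (area, (w, h), float(np.arctan2(u[0], u[1])), np.stack([u, v]))
    return best


def find_bright_regions(image: np.ndarray, cfg: DetectionConfig,
                        threshold: int | None = None) -> list[Region]:
    """Connected components whose minimum channel exceeds the bright threshold."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3 or img.size == 0:
        raise ValueError("expected a non-empty (H, W, 3) 8-bit image")
    t = cfg.bright_threshold if threshold is None else threshold
    mask = img.min(axis=2) >= t
    labels = measure.label(mask, connectivity=2)
    regions = []
    for rp in measure.regionprops(labels):
        area_rect, sides, angle, axes = _min_area_rect(rp.coords)
        regions.append(Region(
            label=rp.label,
            bbox=tuple(rp.bbox),
            area=int(rp.area),
            centroid=np.array(rp.centroid),
            fill_ratio=float(rp.area / area_rect),
            angle=angle,
            side_lengths=(max(sides), min(sides)),
            axes=axes,
        ))
    return regions


def filter_shapes(regions: Sequence[Region], image_shape: tuple[int, int],
                  cfg: DetectionConfig) -> list[Region]:
    """Keep rectangular regions of plausible patch size; order candidates.

    Survivors are sorted by descending fill ratio, ties broken by descending
    area then scanline order of the centroid (deterministic iteration order).
    """
    img_area = image_shape[0] * image_shape[1]
    keep = [
        r for r in regions
        if cfg.min_area_frac * img_area <= r.area <= cfg.max_area_frac * img_area
        and r.fill_ratio >= cfg.min_fill_ratio
    ]
    return sorted(
        keep,
        key=lambda r: (-r.fill_ratio, -r.area, r.centroid[0], r.centroid[1]),
    )


def _window_mean(image: np.ndarray, center: np.ndarray, half: float):
    """Channel means over a half-open square window; None if out of bounds."""
    h, w = image.shape[:2]
    r0 = int(round(center[0] - half))
    r1 = int(round(center[0] + half))
    c0 = int(round(center[1] - half))
    c1 = int(round(center[1] + half))
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w or r1 <= r0 or c1 <= c0:
        return None, 0, (r0, c0, r1, c1)
    win = image[r0:r1, c0:c1].reshape(-1, 3)
    return win.mean(axis=0, dtype=float), win.shape[0], (r0, c0, r1, c1)


def find_black_partner(image: np.ndarray, white: Region, layout: ChartLayout,
                       cfg: DetectionConfig):
    """Search for the chart's black patch near a white-patch candidate.

    The black patch sits ``cols - 1`` patch pitches from the white patch along
    the grayscale row.  Both rectangle side directions (and their negatives)
    of the white candidate are probed; a probe is accepted when the local
    window is uniformly dark relative to the white candidate's brightness.
    Returns ``(black_centroid, direction)`` of the darkest accepted probe, or
    ``(None, None)``.
    """
    img = np.asarray(image, dtype=float)
    side = float(np.mean(white.side_lengths))
    pitch = side * (1.0 + layout.gap_fraction)
    steps = layout.cols - 1
    white_mean, _, _ = _window_mean(img, white.centroid, side * 0.35)
    if white_mean is None:
        return None, None
    dark_ceiling = cfg.dark_fraction * float(white_mean.mean())

    best = None
    for d in (white.axes[0], -white.axes[0], white.axes[1], -white.axes[1]):
        center = white.centroid + steps * pitch * d
        mean, npx, _ = _window_mean(img, center, side * 0.35)
        if mean is None or npx < cfg.min_window_pixels:
            continue
        if mean.max() > dark_ceiling:
            continue
        # refine: centroid of dark pixels in a larger neighbourhood
        ref_mean, _, (r0, c0, r1, c1) = _window_mean(img, center, side * 0.75)
        if ref_mean is not None:
            patchw = img[r0:r1, c0:c1]
            darkmask = patchw.max(axis=2) <= dark_ceiling
            if darkmask.sum() >= cfg.min_window_pixels:
                rr, cc = np.nonzero(darkmask)
                center = np.array([r0 + rr.mean(), c0 + cc.mean()])
        score = float(mean.max())
        if best is None or score < best[0]:
            best = (score, center, d)
    if best is None:
        return None, None
    return best[1], best[2]


@dataclass
class PatchGrid:
    """Affine chart grid: cell centres and integer sampling windows."""

    origin: np.ndarray          # white patch centre, (row, col)
    u: np.ndarray               # + one column step, image px
    v: np.ndarray               # - one row step (towards row 0), image px
    layout: ChartLayout
    window_half: float          # half-size of sampling window, px

    def cell_center(self, row: int, col: int) -> np.ndarray:
        lay = self.layout
        white_r, white_c = lay.cell_of(lay.index_of_white)
        return self.origin + (col - white_c) * self.u + (white_r - row) * self.v

    def centers(self) -> np.ndarray:
        """(n_patches, 2) centres in patch-index order."""
        lay = self.layout
        return np.array([
            self.cell_center(*lay.cell_of(i))
            for i in range(1, lay.n_patches + 1)
        ])

    def windows(self) -> list[tuple[int, int, int, int]]:
        out = []
        for ctr in self.centers():
            r0 = int(round(ctr[0] - self.window_half))
            r1 = int(round(ctr[0] + self.window_half))
            c0 = int(round(ctr[1] - self.window_half))
            c1 = int(round(ctr[1] + self.window_half))
            out.append((r0, c0, r1, c1))
        return out

    def affine(self) -> np.ndarray:
        """2x3 matrix mapping chart cell coords (col, row) -> (row, col) px."""
        white = self.layout.cell_of(self.layout.index_of_white)
        t = self.origin - white[1] * self.u + white[0] * self.v
        return np.column_stack([self.u, -self.v, t])


def build_patch_grid(white_center: np.ndarray, black_center: np.ndarray,
                     side_sign: int, layout: ChartLayout,
                     cfg: DetectionConfig) -> PatchGrid:
    """Grid from the white and black patch centres plus a side hypothesis.

    ``side_sign`` (+1/-1) selects on which side of the white->black axis the
    remaining rows lie; the two signs correspond to a normal versus mirrored
    chart.
    """
    u = (np.asarray(black_center, float) - np.asarray(white_center, float)) / (
        layout.cols - 1
    )
    v = side_sign * np.array([-u[1], u[0]])
    pitch = float(np.hypot(*u))
    patch_side = pitch / (1.0 + layout.gap_fraction)
    half = 0.5 * cfg.sample_window_frac * patch_side
    return PatchGrid(origin=np.asarray(white_center, float), u=u, v=v,
                     layout=layout, window_half=half)


def refine_grid(image: np.ndarray, grid: PatchGrid, cfg: DetectionConfig,
                n_iter: int = 2) -> PatchGrid:
    """Sub-pixel refinement of the patch grid.

    The initial grid comes from the white/black landmark pair, whose black
    end is imprecise (the black patch merges with the chart's dark frame).
    Each iteration re-centres every patch at the centroid of the pixels in
    its cell that match the patch's central colour (the dark divider gaps do
    not match), then refits the affine map to those centroids by least
    squares.  Patches that are themselves frame-dark, clipped by the image
    border or colour-ambiguous are skipped; with fewer than 6 usable patches
    the grid is returned unchanged.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape[:2]
    lay = grid.layout
    white_r, white_c = lay.cell_of(lay.index_of_white)
    for _ in range(n_iter):
        pitch = float(np.hypot(*grid.u))
        patch_side = pitch / (1.0 + lay.gap_fraction)
        half = 0.55 * patch_side
        design, targets = [], []
        for idx in range(1, lay.n_patches + 1):
            r, c = lay.cell_of(idx)
            ctr = grid.cell_center(r, c)
            mean, npx, _ = _window_mean(img, ctr, 0.25 * patch_side)
            if mean is None or npx < cfg.min_window_pixels:
                continue
            if mean.max() < 60:        # blends into the dark chart frame
                continue
            r0, r1 = int(round(ctr[0] - half)), int(round(ctr[0] + half))
            c0, c1 = int(round(ctr[1] - half)), int(round(ctr[1] + half))
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                continue
            win = img[r0:r1, c0:c1]
            mask = np.sqrt(((win - mean) ** 2).sum(-1)) <= 25.0
            if mask.sum() < cfg.min_window_pixels:
                continue
            rr, cc = np.nonzero(mask)
            design.append([c, r, 1.0])
            targets.append([r0 + rr.mean(), c0 + cc.mean()])
        if len(design) < 6:
            return grid
        K, *_ = np.linalg.lstsq(np.array(design), np.array(targets), rcond=None)
        origin = white_c * K[0] + white_r * K[1] + K[2]
        new_pitch = float(np.hypot(*K[0]))
        grid = PatchGrid(
            origin=origin, u=K[0], v=-K[1], layout=lay,
            window_half=0.5 * cfg.sample_window_frac
            * new_pitch / (1.0 + lay.gap_fraction),
        )
    return grid


@dataclass
class PatchSample:
    index: int
    mean: np.ndarray                    # (3,) channel means, device codes
    n_pixels: int
    saturated: np.ndarray = field(default_factory=lambda: np.zeros(3, bool))

    @property
    def proper(self) -> bool:
        return not bool(self.saturated.any())


def sample_patches(image: np.ndarray, grid: PatchGrid,
                   cfg: DetectionConfig) -> list[PatchSample]:
    """Mean device colour of each patch over its central sampling window."""
    img = np.asarray(image, dtype=float)
    samples = []
    for idx, (r0, c0, r1, c1) in enumerate(grid.windows(), start=1):
        h, w = img.shape[:2]
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise SamplingError(f"patch {idx}: window outside image bounds")
        npx = (r1 - r0) * (c1 - c0)
        if npx < cfg.min_window_pixels:
            raise SamplingError(f"patch {idx}: window has {npx} px < "
                                f"{cfg.min_window_pixels}")
        mean = img[r0:r1, c0:c1].reshape(-1, 3).mean(axis=0, dtype=float)
        samples.append(PatchSample(index=idx, mean=mean, n_pixels=npx))
    return samples


class SamplingError(RuntimeError):
    pass


def check_saturation(sample: PatchSample, cfg: DetectionConfig) -> PatchSample:
    """Flag channels whose mean lies within delta of 0 or 255."""
    flags = (sample.mean > 255.0 - cfg.delta) | (sample.mean < cfg.delta)
    sample.saturated = flags
    return sample


def _neutral_monotone(samples: list[PatchSample], layout: ChartLayout,
                      step_tol: float = 2.0, min_drop: float = 20.0) -> bool:
    """True if the grayscale-row sampled brightnesses decrease white -> black.

    Steps may be flat within ``step_tol`` code values (overexposure clips the
    brightest wedge patches to a common level), but none may rise beyond it,
    and the whole row must drop by at least ``min_drop``.
    """
    vals = [float(samples[i - 1].mean.mean()) for i in layout.neutral_row_indices]
    steps_ok = all(b <= a + step_tol for a, b in zip(vals, vals[1:]))
    return steps_ok and (vals[0] - vals[-1]) >= min_drop


def _diversity(samples: list[PatchSample], layout: ChartLayout) -> float:
    """Mean pairwise distance among non-neutral patch means.

    The correct side hypothesis covers 18 distinct colours; the wrong one
    samples the (uniform) background and scores near zero.
    """
    neutral = set(layout.neutral_row_indices)
    m = np.array([s.mean for s in samples if s.index not in neutral])
    d = m[:, None, :] - m[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).mean())


@dataclass
class DetectionResult:
    accepted: bool
    samples: list[PatchSample] = field(default_factory=list)
    grid: PatchGrid | None = None
    white: Region | None = None
    black_center: np.ndarray | None = None
    orientation: int | None = None       # quadrant of the white->black axis (0..3)
    n_saturated: int = 0
    bright_threshold_used: int | None = None
    gate_payload: object = None
    diagnostics: list[str] = field(default_factory=list)

    def to_report(self) -> dict:
        """JSON-serialisable detection report."""
        rep = {
            "accepted": self.accepted,
            "orientation": self.orientation,
            "n_saturated": self.n_saturated,
            "bright_threshold_used": self.bright_threshold_used,
            "diagnostics": list(self.diagnostics),
        }
        if self.grid is not None:
            rep["affine"] = np.asarray(self.grid.affine()).tolist()
        if self.samples:
            rep["samples"] = [
                {
                    "index": s.index,
                    "mean": [round(float(x), 3) for x in s.mean],
                    "n_pixels": s.n_pixels,
                    "saturated": [bool(b) for b in s.saturated],
                    "proper": s.proper,
                }
                for s in self.samples
            ]
        return rep


def _orientation_of(u: np.ndarray) -> int:
    """Quadrant (0..3) of the white->black axis: 0 = +col, 1 = -row, ..."""
    ang = np.arctan2(-u[0], u[1])  # y-up angle of the axis
    return int(np.rint(ang / (np.pi / 2))) % 4


QualityGate = Callable[[list[PatchSample]], tuple[bool, object]]


def detect_chart(image: np.ndarray, chart: ReferenceChart,
                 cfg: DetectionConfig | None = None,
                 quality_gate: QualityGate | None = None) -> DetectionResult:
    """Locate the chart and return samples for the first candidate passing
    every gate (geometry, neutral-row monotonicity, saturation count,
    calibration quality).

    A failed search relaxes the brightness threshold stepwise down to
    ``bright_threshold_min`` before giving up.  Failure returns an
    unaccepted result carrying per-candidate diagnostics, not an exception.
    """
    cfg = cfg or DetectionConfig()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3 or img.size == 0:
        raise ValueError("expected a non-empty (H, W, 3) 8-bit image")
    layout = chart.layout
    diagnostics: list[str] = []

    thresholds = list(range(cfg.bright_threshold, cfg.bright_threshold_min - 1,
                            -cfg.bright_threshold_step))
    for t in thresholds:
        regions = find_bright_regions(img, cfg, threshold=t)
        candidates = filter_shapes(regions, img.shape[:2], cfg)
        for cand in candidates:
            tag = f"t={t} white@({cand.centroid[0]:.0f},{cand.centroid[1]:.0f})"
            black, direction = find_black_partner(img, cand, layout, cfg)
            if black is None:
                diagnostics.append(f"{tag}: no black partner")
                continue
            hyps = []
            for sign in (1, -1):
                grid = build_patch_grid(cand.centroid, black, sign, layout, cfg)
                try:
                    samples = sample_patches(img, grid, cfg)
                except SamplingError as exc:
                    diagnostics.append(f"{tag} side={sign}: {exc}")
                    continue
                if not _neutral_monotone(samples, layout):
                    diagnostics.append(f"{tag} side={sign}: neutral row not monotone")
                    continue
                grid = refine_grid(img, grid, cfg)
                try:
                    samples = sample_patches(img, grid, cfg)
                except SamplingError as exc:
                    diagnostics.append(f"{tag} side={sign}: {exc}")
                    continue
                hyps.append((_diversity(samples, layout), sign, grid, samples))
            # prefer the side with more colour diversity (the actual chart body)
            for div, sign, grid, samples in sorted(hyps, key=lambda h: -h[0]):
                if div < cfg.min_diversity:
                    diagnostics.append(
                        f"{tag} side={sign}: colour diversity {div:.1f} < "
                        f"{cfg.min_diversity} (uniform surroundings)")
                    continue
                samples = [check_saturation(s, cfg) for s in samples]
                n_sat = sum(not s.proper for s in samples)
                if n_sat > cfg.max_saturated_patches:
                    diagnostics.append(
                        f"{tag} side={sign}: {n_sat} saturated patches > "
                        f"{cfg.max_saturated_patches}")
                    continue
                payload = None
                if quality_gate is not None:
                    ok, payload = quality_gate(samples)
                    if not ok:
                        diagnostics.append(f"{tag} side={sign}: quality gate failed")
                        continue
                u = (np.asarray(black) - cand.centroid) / (layout.cols - 1)
                return DetectionResult(
                    accepted=True, samples=samples, grid=grid, white=cand,
                    black_center=np.asarray(black),
                    orientation=_orientation_of(u), n_saturated=n_sat,
                    bright_threshold_used=t, gate_payload=payload,
                    diagnostics=diagnostics,
                )
    diagnostics.append("no candidate passed all gates")
    return DetectionResult(accepted=False, diagnostics=diagnostics)
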