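"""Precision/accuracy statistics for calibrated colour measurements.

Implements the evaluation toolkit used around the calibration pipeline:
pairwise reproducibility (precision) dE_ab sets, split-half accuracy against
the chart's reference values, empirical CDFs, Tukey five-number box-plot
summaries with 1.5*IQR outlier flagging, the Wilcoxon rank-sum test (exact by
enumeration at small n, normal approximation with tie and continuity
corrections otherwise), polygonal ROI colour measurement, and the
rotation-reproducibility protocol (independently re-detecting and
re-calibrating 90/180/270 degree rotations of an image and comparing ROI
means).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import draw

from . import colorimetry as cm
from .calibration import CalibrationConfig, CalibrationError, calibrate_image, \
    fit_calibration, assess_quality
from .chart import ReferenceChart
from .detection import DetectionConfig, PatchSample

__all__ = [
    "DeltaESet",
    "FiveNumberSummary",
    "RankTestResult",
    "ROIMeasurement",
    "pairwise_precision",
    "split_half_accuracy",
    "tukey_summary",
    "wilcoxon_rank_sum",
    "measure_roi",
    "rotate_image",
    "rotate_polygon",
    "rotation_reproducibility",
    "ecdf",
    "ecdf_dominates",
]


@dataclass
class DeltaESet:
    """A labelled collection of dE_ab values.

    ``frame`` has columns ``value`` (dE_ab), ``patch`` (patch index or ROI
    id) and ``pair`` (provenance: image-pair ids or 'vs-reference').
    """

    frame: pd.DataFrame

    @staticmethod
    def from_records(records: list[tuple]) -> "DeltaESet":
        return DeltaESet(pd.DataFrame(records, columns=["value", "patch", "pair"]))

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy()

    def median(self) -> float:
        return float(np.median(self.values))

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def pairwise_precision(labs: np.ndarray,
                       include: np.ndarray | None = None,
                       image_ids: list | None = None) -> DeltaESet:
    """All-pairs dE_ab between repeated measurements of each patch.

    Parameters
    ----------
    labs : (n_images, n_patches, 3) Lab measurements.
    include : optional boolean (n_images, n_patches) mask; a pair counts only
        when the patch is included in both images.
    """
    labs = np.asarray(labs, float)
    if labs.ndim != 3 or labs.shape[0] < 2:
        raise ValueError("need at least 2 measurements per patch")
    n_img, n_patch = labs.shape[:2]
    if include is None:
        include = np.ones((n_img, n_patch), dtype=bool)
    ids = image_ids or list(range(n_img))
    records = []
    for p in range(n_patch):
        for i, j in itertools.combinations(range(n_img), 2):
            if include[i, p] and include[j, p]:
                de = float(cm.delta_e_ab(labs[i, p], labs[j, p]))
                records.append((de, p + 1, f"{ids[i]}|{ids[j]}"))
    return DeltaESet.from_records(records)


def split_half_accuracy(samples: list[PatchSample], chart: ReferenceChart,
                        cfg: CalibrationConfig | None = None):
    """Calibrate on half the patches, evaluate dE to reference on both halves.

    Returns ``(holdout_set, fit_set)``: the held-out half measures accuracy;
    the fit half mirrors the in-sample residual.  Only proper patches enter
    either set.
    """
    cfg = cfg or CalibrationConfig()
    proper = [s for s in samples if s.proper]
    if len(proper) < 12:
        raise CalibrationError(f"need >= 12 proper patches, got {len(proper)}")
    model = fit_calibration(samples, chart, cfg, fit_indices=cfg.fit_half)
    report = assess_quality(model, samples, chart, cfg)
    fit_rec, hold_rec = [], []
    proper_idx = {s.index for s in proper}
    for idx, de in report.de_per_patch.items():
        if idx not in proper_idx:
            continue
        if idx in cfg.fit_half:
            fit_rec.append((de, idx, "vs-reference/fit"))
        else:
            hold_rec.append((de, idx, "vs-reference/holdout"))
    return DeltaESet.from_records(hold_rec), DeltaESet.from_records(fit_rec)


@dataclass
class FiveNumberSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    outliers: np.ndarray = field(default_factory=lambda: np.array([]))

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.minimum, self.q1, self.median, self.q3, self.maximum)


def tukey_summary(values) -> FiveNumberSummary:
    """Five-number summary with median-of-halves quartiles.

    Quartiles are the medians of the lower and upper halves of the sorted
    data, the middle value being excluded from both halves when n is odd.
    Outliers are values beyond 1.5*IQR outside the quartiles.
    """
    v = np.sort(np.asarray(values, float).ravel())
    if v.size == 0:
        raise ValueError("empty input")
    n = v.size
    half = n // 2
    if n == 1:
        q1 = q3 = med = float(v[0])
    else:
        q1 = float(np.median(v[:half]))
        q3 = float(np.median(v[-half:]))
        med = float(np.median(v))
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = v[(v < lo) | (v > hi)]
    return FiveNumberSummary(float(v[0]), q1, med, q3, float(v[-1]), outliers)


@dataclass
class RankTestResult:
    statistic: float          # rank sum of the first sample (midranks)
    p_value: float            # two-sided
    n1: int
    n2: int
    method: str               # "exact" | "normal"


def wilcoxon_rank_sum(a, b, exact_max_n: int = 12) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test on two independent samples.

    Ties receive midranks.  When the combined sample size is at most
    ``exact_max_n`` the null distribution of the rank sum is enumerated over
    all label assignments; otherwise a normal approximation with tie
    correction and a 0.5 continuity correction is used.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    N = n1 + n2
    ranks = stats.rankdata(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())
    mean_w = n1 * (N + 1) / 2.0

    if N <= exact_max_n:
        dev = abs(w - mean_w)
        count = 0
        total = 0
        for combo in itertools.combinations(range(N), n1):
            s = ranks[list(combo)].sum()
            total += 1
            if abs(s - mean_w) >= dev - 1e-12:
                count += 1
        p = count / total
        method = "exact"
    else:
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        var_w = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
        if var_w <= 0:
            p = 1.0
        else:
            z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
            p = 2.0 * stats.norm.sf(max(z, 0.0))
        p = min(p, 1.0)
        method = "normal"
    return RankTestResult(statistic=w, p_value=float(p), n1=n1, n2=n2,
                          method=method)


@dataclass
class ROIMeasurement:
    polygon: np.ndarray       # (k, 2) (row, col) vertices
    mean_lab: np.ndarray      # (3,)
    n_pixels: int


def measure_roi(image: np.ndarray, polygon) -> ROIMeasurement:
    """Mean Lab colour of the pixels enclosed by a polygon in an sRGB image.

    Pixels are converted sRGB -> Lab individually before averaging, so the
    result is the mean in the perceptual space.
    """
    img = np.asarray(image)
    poly = np.asarray(polygon, float)
    rr, cc = draw.polygon(poly[:, 0], poly[:, 1], shape=img.shape[:2])
    if rr.size == 0:
        raise ValueError("polygon does not enclose any pixels of the image")
    labs = cm.srgb8_to_lab(img[rr, cc].astype(float))
    return ROIMeasurement(polygon=poly, mean_lab=labs.mean(axis=0),
                          n_pixels=int(rr.size))


def rotate_image(image: np.ndarray, quarter_turns: int) -> np.ndarray:
    """Rotate by multiples of 90 degrees (counter-clockwise, lossless)."""
    return np.rot90(image, quarter_turns % 4).copy()


def rotate_polygon(polygon: np.ndarray, shape: tuple[int, int],
                   quarter_turns: int) -> np.ndarray:
    """Map polygon vertices through the same lossless rotation.

    ``shape`` is the (H, W) of the *unrotated* image; vertices are (row, col)
    in pixel-centre coordinates.
    """
    poly = np.asarray(polygon, float).copy()
    h, w = shape
    for _ in range(quarter_turns % 4):
        r, c = poly[:, 0].copy(), poly[:, 1].copy()
        poly[:, 0] = (w - 1) - c
        poly[:, 1] = r
        h, w = w, h
    return poly


def rotation_reproducibility(image: np.ndarray, polygon, chart: ReferenceChart,
                             det_cfg: DetectionConfig | None = None,
                             cal_cfg: CalibrationConfig | None = None,
                             scene_id="scene"):
    """Auto-calibrate the image and its three 90-degree rotations
    independently, measure the (correspondingly rotated) ROI in each, and
    return the 6 pairwise dE_ab values.

    Returns ``(DeltaESet, failures)`` where ``failures`` lists the quarter
    turns whose chart detection or calibration failed (those rotations are
    simply absent from the pairwise set).
    """
    img = np.asarray(image)
    measurements = {}
    failures = []
    for k in range(4):
        rot = rotate_image(img, k)
        calibrated, det, _ = calibrate_image(rot, chart, det_cfg, cal_cfg)
        if calibrated is None:
            failures.append(k)
            continue
        poly = rotate_polygon(polygon, img.shape[:2], k)
        measurements[k] = measure_roi(calibrated, poly).mean_lab
    records = []
    for i, j in itertools.combinations(sorted(measurements), 2):
        de = float(cm.delta_e_ab(measurements[i], measurements[j]))
        records.append((de, f"{scene_id}", f"rot{90*i}|rot{90*j}"))
    return DeltaESet.from_records(records), failures


def ecdf(values):
    """Right-continuous empirical CDF: (sorted unique values, P(X <= v))."""
    v = np.asarray(values, float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    xs, counts = np.unique(v, return_counts=True)
    return xs, np.cumsum(counts) / v.size


def ecdf_dominates(better, worse, alpha: float | None = None) -> bool:
    """First-order stochastic dominance of the smaller-is-better sample.

    With ``alpha=None`` (strict) the ECDF of `better` must lie at or above
    the ECDF of `worse` at every pooled value.  With an ``alpha``, empirical
    dominance is asserted in the one-sided Kolmogorov-Smirnov sense: the
    worst violation sup_x(F_worse - F_better) must stay below the one-sided
    KS critical value at that level — i.e. any crossing is indistinguishable
    from sampling noise (a single extreme pair out of thousands cannot veto
    the comparison).
    """
    better = np.sort(np.asarray(better, float).ravel())
    worse = np.sort(np.asarray(worse, float).ravel())
    grid = np.unique(np.concatenate([better, worse]))
    fb = np.searchsorted(better, grid, side="right") / better.size
    fw = np.searchsorted(worse, grid, side="right") / worse.size
    violation = float(np.max(fw - fb))
    if alpha is None:
        return violation <= 0
    n, m = better.size, worse.size
    crit = math.sqrt(-0.5 * math.log(alpha)) * math.sqrt((n + m) / (n * m))
    return violation <= crit


def plot_ecdf(named_sets: dict[str, np.ndarray], path) -> None:
    """ECDF plot of several dE_ab collections (one line each)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, vals in named_sets.items():
        xs, ps = ecdf(vals)
        ax.step(xs, ps, where="post", label=name)
    ax.set_xlabel("dE_ab")
    ax.set_ylabel("cumulative probability")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_box(per_group: dict, path, ylabel: str = "dE_ab") -> None:
    """Box plot (Tukey five-number summary per group, outliers as x)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    labels = list(per_group)
    data = [np.asarray(per_group[k], float) for k in labels]
    ax.boxplot(data, tick_labels=[str(l) for l in labels], whis=1.5,
               flierprops={"marker": "x", "markeredgecolor": "red"})
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
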