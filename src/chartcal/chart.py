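"""The 24-patch reference chart: grid layout and D65 colorimetric values.

The chart is a 4 x 6 checkerboard of matte colour patches; the last row is a
grayscale wedge running from white down to black.  Reference L*a*b* values
(CIE D65, 2 degree observer) are shipped as a plain-text table and are the
single source of truth; sRGB coordinates are derived from them at load time
through :mod:`chartcal.colorimetry` so the two can never drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import colorimetry as cm

__all__ = ["ChartLayout", "PatchReference", "ReferenceChart", "load_reference"]

_NEUTRAL_AB_TOL = 1.0  # |a*|,|b*| ceiling for patches in the grayscale row


@dataclass(frozen=True)
class ChartLayout:
    """Geometric layout of the 24-patch chart.

    Patches are indexed 1..24 in row-major order.  ``gap_fraction`` is the
    width of the black divider between patches as a fraction of patch width.
    """

    rows: int = 4
    cols: int = 6
    patch_aspect: float = 1.0
    gap_fraction: float = 0.125
    neutral_row: int = 3  # 0-based row holding the grayscale wedge

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols

    @property
    def neutral_row_indices(self) -> tuple[int, ...]:
        """1-based indices of the grayscale wedge, white first, black last."""
        start = self.neutral_row * self.cols + 1
        return tuple(range(start, start + self.cols))

    @property
    def index_of_white(self) -> int:
        return self.neutral_row_indices[0]

    @property
    def index_of_black(self) -> int:
        return self.neutral_row_indices[-1]

    def cell_of(self, index: int) -> tuple[int, int]:
        """0-based (row, col) of a 1-based patch index."""
        if not 1 <= index <= self.n_patches:
            raise IndexError(f"patch index {index} out of range 1..{self.n_patches}")
        return divmod(index - 1, self.cols)


@dataclass(frozen=True)
class PatchReference:
    index: int
    name: str
    lab: np.ndarray  # (3,) L*, a*, b* under D65
    srgb: np.ndarray = field(default=None)  # (3,) uint8, derived from lab

    def __post_init__(self):
        if self.srgb is None:
            object.__setattr__(self, "srgb", cm.lab_to_srgb8(self.lab))


class ReferenceChart:
    """The 24 reference patches plus their layout."""

    def __init__(self, layout: ChartLayout, patches: list[PatchReference]):
        if len(patches) != layout.n_patches:
            raise ValueError(
                f"expected {layout.n_patches} patches, got {len(patches)}"
            )
        indices = [p.index for p in patches]
        if sorted(indices) != list(range(1, layout.n_patches + 1)):
            raise ValueError("patch indices must be exactly 1..24, each once")
        self.layout = layout
        self.patches = sorted(patches, key=lambda p: p.index)
        self._validate()

    def _validate(self) -> None:
        lay = self.layout
        neutral = [self.patch(i) for i in lay.neutral_row_indices]
        ab = np.array([p.lab[1:] for p in neutral])
        if np.abs(ab).max() > _NEUTRAL_AB_TOL:
            raise ValueError(
                "neutral-row patches must have |a*|,|b*| <= "
                f"{_NEUTRAL_AB_TOL}; got max {np.abs(ab).max():.3f}"
            )
        lum = self.neutral_luminances()
        if not np.all(np.diff(lum) < 0):
            raise ValueError(
                "neutral-row reference luminances must strictly decrease "
                f"from white to black; got {lum.round(4).tolist()}"
            )

    def patch(self, index: int) -> PatchReference:
        if not 1 <= index <= self.layout.n_patches:
            raise IndexError(
                f"patch index {index} out of range 1..{self.layout.n_patches}"
            )
        return self.patches[index - 1]

    def lab_array(self) -> np.ndarray:
        """(24, 3) reference L*a*b* in index order."""
        return np.array([p.lab for p in self.patches])

    def srgb_array(self) -> np.ndarray:
        """(24, 3) derived 8-bit sRGB in index order."""
        return np.array([p.srgb for p in self.patches])

    def linear_array(self) -> np.ndarray:
        """(24, 3) reference linear sRGB (unclipped) in index order."""
        return cm.lab_to_linear(self.lab_array())

    def neutral_luminances(self) -> np.ndarray:
        """Relative luminance Y (D65 white = 1) of the grayscale wedge."""
        xyz = cm.lab_to_xyz(
            np.array([self.patch(i).lab for i in self.layout.neutral_row_indices])
        )
        return xyz[:, 1]

    def gamut_roundtrip_errors(self) -> np.ndarray:
        """Per-patch dE of Lab -> linear -> 8-bit sRGB -> Lab round trip.

        Flags patches whose reference colour falls outside the sRGB gamut
        (e.g. saturated cyans on some editions of the chart).
        """
        lab = self.lab_array()
        back = cm.srgb8_to_lab(cm.encode_srgb(cm.lab_to_linear(lab)))
        return cm.delta_e_ab(lab, back)


def reference_patch_lab(chart: ReferenceChart, index: int) -> np.ndarray:
    """Stored reference Lab of a 1-based patch index."""
    return chart.patch(index).lab


def load_reference(path: str | Path | None = None,
                   layout: ChartLayout | None = None) -> ReferenceChart:
    """Load a reference chart from a delimited text table.

    The file has one header line and 24 data rows ``index,name,L,a,b``
    (comma or whitespace separated; ``#`` lines are comments).  When *path*
    is ``None`` the packaged chart data file is used.
    """
    layout = layout or ChartLayout()
    if path is None:
        text = (
            resources.files("chartcal").joinpath("data/colorchecker24_d65.csv")
            .read_text()
        )
        source = "<packaged colorchecker24_d65.csv>"
    else:
        text = Path(path).read_text()
        source = str(path)

    patches: list[PatchReference] = []
    seen: set[int] = set()
    header_skipped = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_skipped:
            header_skipped = True
            continue
        fields = [f for f in line.replace(",", " ").split() if f]
        if len(fields) != 5:
            raise ValueError(f"{source}:{lineno}: expected 5 fields, got {len(fields)}")
        try:
            idx = int(fields[0])
            lab = np.array([float(x) for x in fields[2:5]])
        except ValueError as exc:
            raise ValueError(f"{source}:{lineno}: unparseable row: {raw!r}") from exc
        if idx in seen:
            raise ValueError(f"{source}:{lineno}: duplicate patch index {idx}")
        seen.add(idx)
        patches.append(PatchReference(index=idx, name=fields[1], lab=lab))

    if len(patches) != layout.n_patches:
        raise ValueError(
            f"{source}: expected {layout.n_patches} data rows, got {len(patches)}"
        )
    return ReferenceChart(layout, patches)
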