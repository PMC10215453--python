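"""Balloon-guided ROI boxes on resliced, vertically rotated images.

Three nested vertical rectangles are placed over the Eustachian-tube lumen
(nasopharyngeal end at the top of the image):

* **small** — spans the balloon's full-diameter cylindrical segment; its
  short (horizontal) sides cross the two radiopaque marker bands, its
  width covers the inflated balloon body.
* **longest** — the small box extended toward the torus tip (up) and the
  balloon tip (down) by one equal pixel distance, stopping before it would
  include bone or the nasopharyngeal air column.
* **long** — the longest box shrunk by exactly 5 pixels at each end.

All three share their column extent.  Bounds are 0-based inclusive pixel
indices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "RoiBox",
    "build_small_roi",
    "build_longest_roi",
    "build_long_roi",
    "default_lumen_halfwidth_px",
    "roi_to_json",
    "roi_from_json",
]

LONG_BOX_TRIM_PX = 5  # the long box retracts this many pixels per end


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned box with inclusive 0-based pixel bounds."""

    kind: str  # "small" | "longest" | "long"
    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.kind not in ("small", "longest", "long"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError("ROI bounds must satisfy min <= max")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min + 1

    @property
    def width(self) -> int:
        return self.col_max - self.col_min + 1

    @property
    def area(self) -> int:
        return self.height * self.width


def default_lumen_halfwidth_px(pixel_spacing_mm: float, balloon_max_diameter_mm: float = 7.0) -> int:
    """Half-width of the small box: half the inflated balloon diameter, in px.

    ceil(3.5 mm / pixel spacing) by default, so the box covers the balloon
    body with margin at any in-plane resolution.
    """
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel spacing must be > 0")
    return math.ceil((balloon_max_diameter_mm / 2.0) / pixel_spacing_mm)


def build_small_roi(marker_a_2d, marker_b_2d, lumen_halfwidth_px: int) -> RoiBox:
    """Small box between the two radiopaque marker bands.

    Markers must be near-vertical (column difference <= 2 px) — i.e. the
    image has been rotated lumen-vertical first.  Rows span the marker
    rows; columns span the markers' mean column +- ``lumen_halfwidth_px``.
    """
    a = np.asarray(marker_a_2d, dtype=float)
    b = np.asarray(marker_b_2d, dtype=float)
    if np.allclose(a, b):
        raise ValueError("markers must be distinct")
    if abs(a[1] - b[1]) > 2.0:
        raise ValueError("rotate first")
    if lumen_halfwidth_px < 0:
        raise ValueError("halfwidth must be >= 0")
    r_lo, r_hi = sorted((int(round(a[0])), int(round(b[0]))))
    c_mid = int(round((a[1] + b[1]) / 2.0))
    return RoiBox("small", r_lo, r_hi, c_mid - lumen_halfwidth_px, c_mid + lumen_halfwidth_px)


def _max_clear_extension(small: RoiBox, mask: np.ndarray | None, d_limit: int) -> int:
    """Largest d <= d_limit so that extending the box by d rows on both ends
    keeps it clear of ``mask`` within the box columns (row-by-row scan)."""
    if mask is None:
        return d_limit
    mask = np.asarray(mask, dtype=bool)
    cols = slice(small.col_min, small.col_max + 1)
    if mask[small.row_min : small.row_max + 1, cols].any():
        return 0  # the starting box already overlaps the exclusion region
    for d in range(1, d_limit + 1):
        top = small.row_min - d
        bot = small.row_max + d
        hit = False
        if 0 <= top < mask.shape[0] and mask[top, cols].any():
            hit = True
        if 0 <= bot < mask.shape[0] and mask[bot, cols].any():
            hit = True
        if hit:
            return d - 1
    return d_limit


def build_longest_roi(
    small: RoiBox,
    torus_row: int,
    balloon_tip_row: int,
    bone_mask: np.ndarray | None = None,
    np_air_mask: np.ndarray | None = None,
) -> RoiBox:
    """Extend the small box by an equal distance toward torus and balloon tip.

    The extension distance is ``d = min(row_min - torus_row,
    balloon_tip_row - row_max)``, further capped so the grown box never
    overlaps the bone mask or the nasopharyngeal air column mask.  Columns
    are unchanged.  Raises ``ValueError("no room to extend")`` if d <= 0.
    """
    if small.kind != "small":
        raise ValueError("longest box must grow from the small box")
    d_limit = min(small.row_min - int(torus_row), int(balloon_tip_row) - small.row_max)
    if d_limit <= 0:
        raise ValueError("no room to extend")
    d = d_limit
    for mask in (bone_mask, np_air_mask):
        d = _max_clear_extension(small, mask, d)
    if d <= 0:
        raise ValueError("no room to extend")
    return RoiBox("longest", small.row_min - d, small.row_max + d, small.col_min, small.col_max)


def build_long_roi(longest: RoiBox) -> RoiBox:
    """Shrink the longest box by exactly 5 px at each vertical end."""
    if longest.kind != "longest":
        raise ValueError("long box must shrink the longest box")
    if longest.height <= 2 * LONG_BOX_TRIM_PX:
        raise ValueError("longest box too short to trim")
    return RoiBox(
        "long",
        longest.row_min + LONG_BOX_TRIM_PX,
        longest.row_max - LONG_BOX_TRIM_PX,
        longest.col_min,
        longest.col_max,
    )


def roi_to_json(rois: dict[str, RoiBox]) -> str:
    return json.dumps({k: asdict(v) for k, v in rois.items()}, indent=2)


def roi_from_json(text: str) -> dict[str, RoiBox]:
    raw = json.loads(text)
    return {k: RoiBox(**v) for k, v in raw.items()}
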