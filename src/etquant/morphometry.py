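"""Lumen width and length measurements on resliced center-axis images.

Widths are taken at three lumen levels — nasopharyngeal opening,
mid-cartilaginous, and the posterior (isthmus) end — as the length of the
maximal contiguous run of air-classified pixels along the level's image
row, seeded from a column known to lie inside the lumen (the center column
of the longest ROI, which acts as a constant locator across ears and
states).  Lengths are straight-line pixel distances between the torus tip,
the widest balloon level, and the balloon tip.

Pixel values convert to mm by multiplying with the in-plane pixel spacing;
spacing is always an explicit input, never assumed from any particular
scanner geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .densitometry import DensityRanges
from .volume import round_half_up

__all__ = [
    "Morphometrics",
    "measure_widths",
    "measure_distances",
    "px_to_mm",
    "air_run_length",
]


@dataclass
class Morphometrics:
    """Per-ear width and distance measurements in pixels (mm via spacing)."""

    width_np: float
    width_mid: float
    width_isthmus: float
    distance_total: float
    distance_torus_to_widest: float
    distance_widest_to_tip: float
    pixel_spacing: float  # mm per pixel

    def widths_mm(self) -> tuple[float, float, float]:
        return tuple(
            px_to_mm(w, self.pixel_spacing)
            for w in (self.width_np, self.width_mid, self.width_isthmus)
        )

    def distances_mm(self) -> tuple[float, float, float]:
        return tuple(
            px_to_mm(d, self.pixel_spacing)
            for d in (
                self.distance_total,
                self.distance_torus_to_widest,
                self.distance_widest_to_tip,
            )
        )


def air_run_length(row_values, seed_col: int, lo: int, hi: int) -> int:
    """Length of the maximal contiguous run of values in [lo, hi] containing
    ``seed_col``; 0 if the seed pixel itself is not in range."""
    vals = round_half_up(np.asarray(row_values, dtype=float)).astype(int)
    if not (0 <= seed_col < vals.size):
        raise ValueError("seed column outside the image")
    in_range = (vals >= lo) & (vals <= hi)
    if not in_range[seed_col]:
        return 0
    left = seed_col
    while left > 0 and in_range[left - 1]:
        left -= 1
    right = seed_col
    while right < vals.size - 1 and in_range[right + 1]:
        right += 1
    return right - left + 1


def measure_widths(
    image,
    levels: dict[str, int],
    ranges: DensityRanges,
    seed_col: int,
    mode: str = "partial",
) -> tuple[int, int, int]:
    """Lumen widths (px) at the three measurement levels of a vertical image.

    ``levels`` maps ``np_row`` / ``mid_row`` / ``isthmus_row`` to image rows.
    A closed lumen (no air at the seed) measures 0.
    """
    img = np.asarray(image)
    lo, hi = ranges.interval(mode)
    widths = []
    for key in ("np_row", "mid_row", "isthmus_row"):
        row = int(levels[key])
        if not (0 <= row < img.shape[0]):
            raise ValueError(f"{key}={row} outside the image")
        widths.append(air_run_length(img[row], seed_col, lo, hi))
    return tuple(widths)


def measure_distances(torus_tip_2d, widest_2d, balloon_tip_2d) -> tuple[float, float, float]:
    """Straight-line pixel distances between the three balloon/lumen anchors.

    Returns (total torus->tip, torus->widest, widest->tip).  The total is an
    independent measurement between its own endpoints, not the sum of the
    two parts (the parts need not be collinear).
    """
    torus = np.asarray(torus_tip_2d, dtype=float)
    widest = np.asarray(widest_2d, dtype=float)
    tip = np.asarray(balloon_tip_2d, dtype=float)
    for a, b in ((torus, widest), (widest, tip), (torus, tip)):
        if np.allclose(a, b):
            raise ValueError("anchor points must be distinct")
    d1 = float(np.linalg.norm(tip - torus))
    d2 = float(np.linalg.norm(widest - torus))
    d3 = float(np.linalg.norm(tip - widest))
    return d1, d2, d3


def px_to_mm(value_px: float, pixel_spacing: float) -> float:
    """Convert a pixel measurement to mm using the in-plane pixel spacing."""
    if pixel_spacing <= 0:
        raise ValueError("pixel spacing must be > 0")
    return float(value_px) * float(pixel_spacing)
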