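"""Gray-value densitometry: calibration, ROI histograms, air-pixel counts.

Dilation of the Eustachian tube is quantified as the change in the number
of air-classified pixels inside the ROI boxes across the slice stack.
Air, soft-tissue and bone gray-value ranges are calibrated from reference
regions (nasopharyngeal air, surrounding tissue, petrous bone).  Two air
ranges are carried throughout:

* ``strict`` — the range observed in pure air references (typically 0-16
  on 8-bit images);
* ``partial`` — the strict range widened to a partial-volume ceiling
  (default 31): voxels on the lumen wall average air with tissue and land
  in a tail above the pure-air maximum.

Both counts are first-class outputs; the partial-mode count is the
headline dilation measure.  All range bounds are inclusive integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import RoiBox
from .volume import round_half_up

__all__ = [
    "DensityRanges",
    "HistogramResult",
    "calibrate_ranges",
    "roi_histogram",
    "air_pixels",
    "percent_increase",
    "mean_gray_profile",
    "DEFAULT_RANGES",
    "PARTIAL_VOLUME_CEILING",
]

#: default ceiling of the partial-volume air tail (inclusive gray value)
PARTIAL_VOLUME_CEILING = 31

#: fraction of a reference sample a histogram bin must hold to survive trimming
CALIBRATION_TRIM_FRACTION = 0.001


@dataclass(frozen=True)
class DensityRanges:
    """Calibrated inclusive gray-value intervals for air, tissue and bone."""

    air_strict: tuple[int, int]
    air_partial: tuple[int, int]
    tissue: tuple[int, int]
    bone: tuple[int, int]

    def __post_init__(self) -> None:
        for name in ("air_strict", "air_partial", "tissue", "bone"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")
        if not (self.air_partial[0] <= self.air_strict[0] and self.air_strict[1] <= self.air_partial[1]):
            raise ValueError("strict air range must lie within the partial range")
        if not (self.air_partial[1] < self.tissue[0] <= self.tissue[1] < self.bone[0]):
            raise ValueError("ranges must be ordered air < tissue < bone without overlap")

    def interval(self, mode: str) -> tuple[int, int]:
        if mode == "strict":
            return self.air_strict
        if mode == "partial":
            return self.air_partial
        raise ValueError(f"unknown air mode {mode!r}")


#: the calibration obtained on the reference cadaver material; used when no
#: per-scan reference regions are supplied
DEFAULT_RANGES = DensityRanges(
    air_strict=(0, 16),
    air_partial=(0, PARTIAL_VOLUME_CEILING),
    tissue=(42, 88),
    bone=(214, 255),
)


@dataclass
class HistogramResult:
    """256-bin gray-value histogram of one ROI on one slice."""

    counts: np.ndarray
    roi: RoiBox
    slice_offset: float  # mm

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (256,):
            raise ValueError("histogram must have 256 bins")
        if int(self.counts.sum()) != self.roi.area:
            raise ValueError("histogram must conserve ROI area")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"gray_value": np.arange(256), "count": self.counts}).to_csv(
            path, index=False
        )


def _as_gray8(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    g = round_half_up(arr)
    if g.min() < 0 or g.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    return g.astype(np.int64)


def _trimmed_min_max(sample: np.ndarray) -> tuple[int, int]:
    counts = np.bincount(sample, minlength=256)
    threshold = CALIBRATION_TRIM_FRACTION * sample.size
    kept = np.nonzero(counts >= max(threshold, 1))[0]
    if kept.size == 0:  # every bin below threshold: fall back to raw extremes
        kept = np.nonzero(counts)[0]
    return int(kept.min()), int(kept.max())


def calibrate_ranges(
    air_ref, tissue_ref, bone_ref, partial_ceiling: int = PARTIAL_VOLUME_CEILING
) -> DensityRanges:
    """Derive density ranges from reference-region pixel samples.

    Each range is the [min, max] of its sample after discarding gray-value
    bins holding under 0.1% of that sample (raw extremes are fragile under
    noise; trimming does not move the bounds of clean samples).  The
    partial air range runs from the air minimum up to ``partial_ceiling``.

    Raises ``ValueError("reference regions not separable")`` when the
    trimmed ranges overlap or are out of order.
    """
    samples = []
    for name, ref in (("air", air_ref), ("tissue", tissue_ref), ("bone", bone_ref)):
        arr = _as_gray8(np.ravel(ref))
        if arr.size == 0:
            raise ValueError(f"{name} reference sample is empty")
        samples.append(arr)
    air = _trimmed_min_max(samples[0])
    tissue = _trimmed_min_max(samples[1])
    bone = _trimmed_min_max(samples[2])
    partial = (air[0], max(int(partial_ceiling), air[1]))
    try:
        return DensityRanges(air, partial, tissue, bone)
    except ValueError as exc:
        raise ValueError("reference regions not separable") from exc


def roi_histogram(image, roi: RoiBox, slice_offset: float = 0.0) -> HistogramResult:
    """Exact 256-bin histogram of the pixels inside an inclusive ROI box."""
    img = np.asarray(image)
    if roi.row_min < 0 or roi.col_min < 0 or roi.row_max >= img.shape[0] or roi.col_max >= img.shape[1]:
        raise ValueError("ROI box out of image bounds")
    patch = _as_gray8(img[roi.row_min : roi.row_max + 1, roi.col_min : roi.col_max + 1])
    counts = np.bincount(patch.ravel(), minlength=256)
    return HistogramResult(counts, roi, slice_offset)


def air_pixels(stack, rois, ranges: DensityRanges, mode: str = "partial") -> int:
    """Total air-classified pixels over all ROIs of a slice stack.

    ``rois`` holds one box per stack image; the count sums, over slices,
    the histogram mass inside the inclusive air interval of ``mode``.
    """
    if len(rois) != len(stack.images):
        raise ValueError("need exactly one ROI per slice")
    lo, hi = ranges.interval(mode)
    total = 0
    for img, roi, off in zip(stack.images, rois, stack.offsets):
        counts = roi_histogram(img, roi, off).counts
        total += int(counts[lo : hi + 1].sum())
    return total


def percent_increase(pre_count: float, post_count: float) -> float:
    """Relative air-count change post vs pre, in percent.

    Per-ear report tables round this half-up to the nearest integer; the
    raw value is returned here.
    """
    if pre_count <= 0:
        raise ValueError("undefined baseline")
    return 100.0 * (post_count - pre_count) / pre_count


def mean_gray_profile(stack, rois) -> list[float]:
    """Per-slice mean ROI gray value, ordered by slice offset.

    Falling means after dilation reflect the growing share of dark air
    pixels in the ROI.
    """
    if len(rois) != len(stack.images):
        raise ValueError("need exactly one ROI per slice")
    means = []
    for img, roi in zip(stack.images, rois):
        img = np.asarray(img)
        if roi.row_max >= img.shape[0] or roi.col_max >= img.shape[1]:
            raise ValueError("ROI box out of image bounds")
        patch = _as_gray8(img[roi.row_min : roi.row_max + 1, roi.col_min : roi.col_max + 1])
        means.append(float(patch.mean()))
    return means
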