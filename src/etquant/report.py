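"""End-to-end pipeline orchestration and per-ear report aggregation.

``run_pipeline`` drives the whole measurement chain for a set of phantom
ears: generate the volumes, build the landmark plane, extract matched
pre/post slice stacks, rotate them lumen-vertical, construct the three ROI
boxes, calibrate density ranges, count air pixels (strict and partial),
and measure widths and distances.  Results aggregate into a
:class:`DilationReport` whose summary rows are the column means and sample
standard deviations (n-1 denominator, the convention that reproduces the
reference dataset's printed dispersions).

Percent columns in per-ear tables are reported rounded half-up to
integers; summary statistics are computed on the rounded per-ear values
and rounded only at display time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from . import reference_tables
from .densitometry import (
    DensityRanges,
    DEFAULT_RANGES,
    air_pixels,
    calibrate_ranges,
    mean_gray_profile,
    percent_increase,
)
from .morphometry import measure_distances, measure_widths
from .phantom import (
    GroundTruth,
    PhantomSpec,
    dilation_factor_for_air_increase,
    generate_phantom,
)
from .reslice import (
    PlaneFrame,
    SliceStack,
    extract_stack,
    plane_from_landmarks,
    plane_point_to_pixel,
    rotate_point_2d,
    rotate_to_vertical,
)
from .roi import (
    RoiBox,
    build_long_roi,
    build_longest_roi,
    build_small_roi,
    default_lumen_halfwidth_px,
)
from .volume import Volume, round_half_up

__all__ = [
    "EarRecord",
    "DilationReport",
    "PipelineConfig",
    "summarize",
    "run_pipeline",
    "analyze_ear",
    "reproduce_reference_tables",
    "resliced_mask_count",
    "equivalent_mask_threshold",
]

log = logging.getLogger("etquant")


class _stage:
    """Attach the failing stage's name to pipeline exceptions."""

    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self) -> None:
        log.debug("stage %s", self.name)

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc is not None and not getattr(exc, "_staged", False):
            exc._staged = True
            exc.args = (f"[{self.name}] {exc}",) + exc.args[1:]
        return None


ROI_KINDS = ("small", "longest", "long")
#: axial offset (mm past the torus) at which the nasopharyngeal-opening
#: width is read; the exact orifice row sits on the funnel boundary
NP_LEVEL_INSET_MM = 1.0


def summarize(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator).

    The SD requires at least two values; a single value yields SD = nan.
    Rounding to a table's printed precision happens at report time only.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty list")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else float("nan")
    return mean, sd


# ---------------------------------------------------------------------------
# Report containers
# ---------------------------------------------------------------------------


@dataclass
class EarRecord:
    """All measurements for one ear (one pre/post phantom pair)."""

    ear_id: str
    air_counts_pre: dict[str, dict[str, int]]  # mode -> roi kind -> count
    air_counts_post: dict[str, dict[str, int]]
    percent_increase: dict[str, dict[str, float]]  # mode -> roi kind -> raw %
    widths_pre_px: tuple[float, float, float]
    widths_post_px: tuple[float, float, float]
    width_increase_pct: tuple[float, float, float]
    distances_px: tuple[float, float, float]
    pixel_spacing_mm: float
    density_ranges: DensityRanges
    ground_truth_air_increase_pct: float | None = None
    ground_truth_mid_width_ratio: float | None = None

    def rounded_percent(self, mode: str = "partial") -> dict[str, int]:
        """Per-ear air-increase column entries, rounded half-up to integers."""
        return {
            kind: int(round_half_up(self.percent_increase[mode][kind]))
            for kind in ROI_KINDS
        }


@dataclass
class DilationReport:
    """Per-ear records plus column summaries (mean, sample SD)."""

    ears: list[EarRecord]
    air_mode: str = "partial"
    summary: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary and self.ears:
            self.summary = self._compute_summary()

    def _compute_summary(self) -> dict[str, tuple[float, float]]:
        out: dict[str, tuple[float, float]] = {}
        for kind in ROI_KINDS:
            col = [e.rounded_percent(self.air_mode)[kind] for e in self.ears]
            out[f"air_increase_{kind}_pct"] = summarize(col)
        for i, name in enumerate(("width_np", "width_mid", "width_isthmus")):
            out[f"{name}_increase_pct"] = summarize(
                [e.width_increase_pct[i] for e in self.ears]
            )
        for i, name in enumerate(
            ("distance_total", "distance_torus_to_widest", "distance_widest_to_tip")
        ):
            out[f"{name}_px"] = summarize([e.distances_px[i] for e in self.ears])
        return out

    # -- lossless serialization -------------------------------------------

    def to_json(self) -> str:
        def encode(rec: EarRecord) -> dict:
            d = asdict(rec)
            d["density_ranges"] = asdict(rec.density_ranges)
            return d

        return json.dumps(
            {
                "air_mode": self.air_mode,
                "ears": [encode(e) for e in self.ears],
                "summary": {k: list(v) for k, v in self.summary.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DilationReport":
        raw = json.loads(text)
        ears = []
        for d in raw["ears"]:
            d = dict(d)
            d["density_ranges"] = DensityRanges(
                **{k: tuple(v) for k, v in d["density_ranges"].items()}
            )
            for key in ("widths_pre_px", "widths_post_px", "width_increase_pct", "distances_px"):
                d[key] = tuple(d[key])
            ears.append(EarRecord(**d))
        return cls(
            ears,
            raw["air_mode"],
            {k: tuple(v) for k, v in raw["summary"].items()},
        )

    def to_csv(self, path) -> None:
        """Write the three per-ear tables and the summary rows as CSV."""
        import pandas as pd

        rows = []
        for e in self.ears:
            pct = e.rounded_percent(self.air_mode)
            rows.append(
                {
                    "ear_id": e.ear_id,
                    **{f"air_increase_{k}_pct": pct[k] for k in ROI_KINDS},
                    "width_np_increase_pct": round(e.width_increase_pct[0], 1),
                    "width_mid_increase_pct": round(e.width_increase_pct[1], 1),
                    "width_isthmus_increase_pct": round(e.width_increase_pct[2], 1),
                    "distance_total_px": round(e.distances_px[0], 2),
                    "distance_torus_to_widest_px": round(e.distances_px[1], 2),
                    "distance_widest_to_tip_px": round(e.distances_px[2], 2),
                }
            )
        df = pd.DataFrame(rows)
        mean_row = {"ear_id": "mean"}
        sd_row = {"ear_id": "sd"}
        for col, (m, s) in self.summary.items():
            key = col if col in df.columns else None
            if key:
                mean_row[key] = m
                sd_row[key] = s
        df = pd.concat([df, pd.DataFrame([mean_row, sd_row])], ignore_index=True)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Run configuration: one phantom spec per ear plus analysis settings."""

    ears: dict[str, PhantomSpec]
    air_mode: str = "partial"
    half_count: int = 12
    size_px: tuple[int, int] = (160, 64)
    calibrate_from_references: bool = True
    qc_dir: Path | None = None

    @classmethod
    def from_target_increases(
        cls,
        target_increases_pct: dict[str, float],
        base: PhantomSpec | None = None,
        seed: int = 0,
        region: str = "lumen",
        **kwargs,
    ) -> "PipelineConfig":
        """Build a config whose ears are tuned to given true air increases.

        ``region="lumen"`` tunes the whole-lumen increase (compare with the
        longest box); ``region="cylinder"`` tunes the increase over the
        balloon's cylindrical span (compare with the small box).
        """
        base = base if base is not None else PhantomSpec()
        ears = {}
        for i, (ear_id, target) in enumerate(target_increases_pct.items()):
            spec = dilation_factor_for_air_increase(base, target, region)
            ears[ear_id] = replace(spec, seed=int(seed) * 1009 + i)
        return cls(ears=ears, **kwargs)


def equivalent_mask_threshold(
    air_bound: int, air_mean: float, tissue_mean: float
) -> float:
    """Air-fraction level equivalent to an intensity classification bound.

    In a two-material (air/tissue) region the intensity is affine in the
    air fraction m: value = tissue - m * (tissue - air).  A pixel rounds
    into the air class (value <= bound) exactly when
    m > (tissue - bound - 0.5) / (tissue - air); reslicing commutes with
    the affine map, so thresholding the resliced ground-truth mask at this
    level reproduces the intensity-route classification.
    """
    if tissue_mean <= air_mean:
        raise ValueError("tissue mean must exceed air mean")
    return (tissue_mean - (air_bound + 0.5)) / (tissue_mean - air_mean)


def _stack_mask_count(mask_stack: SliceStack, rois, threshold: float) -> int:
    total = 0
    for img, roi in zip(mask_stack.images, rois):
        patch = img[roi.row_min : roi.row_max + 1, roi.col_min : roi.col_max + 1]
        total += int((patch > threshold).sum())
    return total


def resliced_mask_count(
    mask: np.ndarray,
    spec: PhantomSpec,
    frame: PlaneFrame,
    rois,
    half_count: int,
    size_px,
    threshold: float = 0.5,
    lumen_axis_2d=None,
) -> int:
    """Ground-truth voxel-mask count inside the ROIs, in resliced space.

    The binary mask is resliced (and optionally rotated) with the same
    trilinear scheme as the intensity volume, then counted above
    ``threshold``.  With the threshold from
    :func:`equivalent_mask_threshold` this is the independent mask-space
    oracle for the pipeline's intensity-route air counts.
    """
    vol = Volume(mask.astype(float) * 255.0, spec.spacing, "gray8")
    stack = extract_stack(vol, frame, half_count=half_count, size_px=size_px)
    if lumen_axis_2d is not None:
        stack, _ = rotate_to_vertical(stack, lumen_axis_2d)
    rescaled = SliceStack(
        [im / 255.0 for im in stack.images], stack.offsets, stack.pixel_spacing
    )
    return _stack_mask_count(rescaled, rois, threshold)


def _qc_overlay(image: np.ndarray, rois: dict[str, RoiBox], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(4, 8))
    ax.imshow(image, cmap="gray", vmin=0, vmax=255)
    colors = {"small": "tab:red", "longest": "tab:cyan", "long": "tab:orange"}
    for kind, roi in rois.items():
        ax.add_patch(
            Rectangle(
                (roi.col_min - 0.5, roi.row_min - 0.5),
                roi.width,
                roi.height,
                fill=False,
                edgecolor=colors[kind],
                linewidth=1.2,
                label=kind,
            )
        )
    ax.legend(loc="lower right", fontsize=7)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


@dataclass
class EarAnalysis:
    """Intermediate per-ear pipeline products (useful for QC and tests)."""

    record: EarRecord
    frame: PlaneFrame
    rois: dict[str, RoiBox]
    stack_pre: SliceStack
    stack_post: SliceStack
    rotation_deg: float
    ground_truth: GroundTruth
    anchors_2d: dict[str, np.ndarray]
    level_rows: dict[str, int]
    mean_profile_pre: list[float]
    mean_profile_post: list[float]


def analyze_ear(
    ear_id: str,
    spec: PhantomSpec,
    config: PipelineConfig,
) -> EarAnalysis:
    """Run the full measurement chain for one phantom ear."""
    log.info("ear %s: generating phantom (dilation factor %.3f)", ear_id, spec.dilation_factor)
    with _stage("phantom"):
        vol_pre, _vol_during, vol_post, gt = generate_phantom(spec)
    spacing = np.asarray(spec.spacing)

    with _stage("reslice"):
        frame = plane_from_landmarks(gt.landmarks, spec.spacing)
        size_px = config.size_px
        px = float(min(spec.spacing[1], spec.spacing[2]))

        stack_pre = extract_stack(vol_pre, frame, config.half_count, size_px)
        stack_post = extract_stack(vol_post, frame, config.half_count, size_px)

    def project(voxel_point) -> np.ndarray:
        return plane_point_to_pixel(frame, np.asarray(voxel_point) * spacing, size_px, px)

    torus_2d = project(gt.landmarks.torus_tip)
    tip_2d = project(gt.landmarks.balloon_tip)
    axis_2d = tip_2d - torus_2d
    stack_pre, angle = rotate_to_vertical(stack_pre, axis_2d)
    stack_post, _ = rotate_to_vertical(stack_post, axis_2d)

    anchors = {
        "torus": rotate_point_2d(torus_2d, angle, size_px),
        "tip": rotate_point_2d(tip_2d, angle, size_px),
        "widest": rotate_point_2d(project(gt.widest_point), angle, size_px),
        "marker_a": rotate_point_2d(project(gt.landmarks.marker_a), angle, size_px),
        "marker_b": rotate_point_2d(project(gt.landmarks.marker_b), angle, size_px),
    }

    # density calibration from the phantom's reference regions (pre volume)
    if config.calibrate_from_references:
        refs = gt.reference_regions
        ranges = calibrate_ranges(
            vol_pre.voxels[refs["air"]],
            vol_pre.voxels[refs["tissue"]],
            vol_pre.voxels[refs["bone"]],
        )
    else:
        ranges = DEFAULT_RANGES

    # ROI construction on the rotated center-image geometry; the ground
    # truth bone / nasopharyngeal-air masks provide the exclusion regions
    halfwidth = default_lumen_halfwidth_px(px, spec.balloon.max_diameter_mm)
    small = build_small_roi(anchors["marker_a"], anchors["marker_b"], halfwidth)

    def center_mask(mask: np.ndarray) -> np.ndarray:
        vol = Volume(mask.astype(float) * 255.0, spec.spacing, "gray8")
        st = extract_stack(vol, frame, 0, size_px)
        st, _ = rotate_to_vertical(st, axis_2d)
        return st.center >= 127.5

    longest = build_longest_roi(
        small,
        int(round_half_up(anchors["torus"][0])),
        int(round_half_up(anchors["tip"][0])),
        bone_mask=center_mask(gt.bone_mask),
        np_air_mask=center_mask(gt.np_air_mask),
    )
    long_box = build_long_roi(longest)
    rois = {"small": small, "longest": longest, "long": long_box}

    n_slices = len(stack_pre)
    counts_pre = {m: {} for m in ("strict", "partial")}
    counts_post = {m: {} for m in ("strict", "partial")}
    pct = {m: {} for m in ("strict", "partial")}
    for mode in ("strict", "partial"):
        for kind, roi in rois.items():
            per_slice = [roi] * n_slices
            pre_n = air_pixels(stack_pre, per_slice, ranges, mode)
            post_n = air_pixels(stack_post, per_slice, ranges, mode)
            counts_pre[mode][kind] = pre_n
            counts_post[mode][kind] = post_n
            pct[mode][kind] = percent_increase(pre_n, post_n)

    # morphometry on the rotated center images
    t_np = NP_LEVEL_INSET_MM
    level_points = {
        "np_row": spec.axis_point(t_np),
        "mid_row": spec.axis_point(spec.mid_level_t),
        "isthmus_row": spec.axis_point(spec.junction_t),
    }
    level_rows = {
        key: int(round_half_up(rotate_point_2d(
            plane_point_to_pixel(frame, p, size_px, px), angle, size_px
        )[0]))
        for key, p in level_points.items()
    }
    seed_col = int(round_half_up((longest.col_min + longest.col_max) / 2.0))
    w_pre = measure_widths(stack_pre.center, level_rows, ranges, seed_col, config.air_mode)
    w_post = measure_widths(stack_post.center, level_rows, ranges, seed_col, config.air_mode)
    width_pct = tuple(
        percent_increase(a, b) if a > 0 else float("nan") for a, b in zip(w_pre, w_post)
    )
    distances = measure_distances(anchors["torus"], anchors["widest"], anchors["tip"])

    small_per_slice = [small] * n_slices
    record = EarRecord(
        ear_id=ear_id,
        air_counts_pre=counts_pre,
        air_counts_post=counts_post,
        percent_increase=pct,
        widths_pre_px=tuple(float(w) for w in w_pre),
        widths_post_px=tuple(float(w) for w in w_post),
        width_increase_pct=tuple(float(w) for w in width_pct),
        distances_px=tuple(float(d) for d in distances),
        pixel_spacing_mm=px,
        density_ranges=ranges,
        ground_truth_air_increase_pct=gt.percent_air_increase(),
        ground_truth_mid_width_ratio=gt.widths_post_px[1] / gt.widths_pre_px[1],
    )
    return EarAnalysis(
        record=record,
        frame=frame,
        rois=rois,
        stack_pre=stack_pre,
        stack_post=stack_post,
        rotation_deg=angle,
        ground_truth=gt,
        anchors_2d=anchors,
        level_rows=level_rows,
        mean_profile_pre=mean_gray_profile(stack_pre, small_per_slice),
        mean_profile_post=mean_gray_profile(stack_post, small_per_slice),
    )


def run_pipeline(config: PipelineConfig) -> DilationReport:
    """Execute the pipeline for every configured ear and aggregate."""
    records = []
    for ear_id, spec in config.ears.items():
        try:
            analysis = analyze_ear(ear_id, spec, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at ear {ear_id!r}: {exc}") from exc
        records.append(analysis.record)
        if config.qc_dir is not None:
            qc_dir = Path(config.qc_dir)
            qc_dir.mkdir(parents=True, exist_ok=True)
            for state, stack in (("pre", analysis.stack_pre), ("post", analysis.stack_post)):
                _qc_overlay(
                    np.clip(round_half_up(stack.center), 0, 255),
                    analysis.rois,
                    qc_dir / f"{ear_id}_{state}_rois.png",
                )
    return DilationReport(records, air_mode=config.air_mode)


# ---------------------------------------------------------------------------
# Reference-table reproduction
# ---------------------------------------------------------------------------


def reproduce_reference_tables() -> dict[str, dict[str, float]]:
    """Summaries (mean, sample SD) of the built-in per-ear reference data.

    Air-increase column means are computed on the per-ear integer entries
    and printed as integers; width increases use one decimal; distances
    two decimals.  SDs are sample SDs.
    """
    out: dict[str, dict[str, float]] = {}
    for kind, col in reference_tables.AIR_INCREASE_PCT.items():
        mean, sd = summarize(col)
        out[f"air_increase_{kind}"] = {
            "mean": float(round_half_up(mean)),
            "sd": round(sd, 1),
        }
    for name, col in reference_tables.WIDTH_INCREASE_PCT.items():
        mean, sd = summarize(col)
        out[f"{name}_increase"] = {"mean": round(mean, 1), "sd": round(sd, 1)}
    for name, col in reference_tables.DISTANCES_PX.items():
        mean, sd = summarize(col)
        out[name] = {"mean": round(mean, 2), "sd": round(sd, 1)}
    return out
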