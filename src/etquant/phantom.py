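"""Parametric synthetic head phantom for Eustachian-tube dilation studies.

The phantom emulates the structures the analysis pipeline relies on, in a
head-like spatial arrangement but without anatomical detail:

* a tapering Eustachian-tube lumen rendered as an oblique elliptical tube
  running from a nasopharyngeal air funnel to a petrous-bone-like block,
  in pre-, during- and post-dilation states;
* an inflated balloon (16 mm long, 7 mm max / 3 mm min diameter) with two
  radiopaque marker bands at the ends of its full-diameter cylindrical
  segment, present in the during state;
* reference regions of pure air, soft tissue and bone for density-range
  calibration.

All three states share one geometry, so landmark-matched pre/post
reslicing is exact by construction.  Partial-volume averaging at tissue
boundaries is simulated by supersampled rendering followed by block
averaging; Gaussian noise is added afterwards.  Every random choice is
driven by the mandatory seed, making volumes bit-reproducible.

The lumen axis parameter ``t`` (mm) runs from the torus tip (t = 0) to the
posterior lumen end (t = lumen length), where the balloon tip sits.  The
cartilaginous/bony junction lies at ``cartilaginous_fraction * length``;
the balloon's cylindrical segment ends there, and its distal cone spans
the bony portion to the tip — so the torus->widest and widest->tip
distances are the cartilaginous and bony lengths respectively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .reslice import LandmarkSet
from .volume import Volume, write_dicom_series

__all__ = [
    "BalloonSpec",
    "PhantomIntensities",
    "PhantomSpec",
    "GroundTruth",
    "compute_ground_truth",
    "generate_phantom",
    "write_phantom_series",
    "write_ground_truth",
    "load_ground_truth",
    "true_air_increase_percent",
    "dilation_factor_for_air_increase",
]


@dataclass(frozen=True)
class BalloonSpec:
    """Dilation balloon geometry (catheter datasheet values)."""

    length_mm: float = 16.0
    max_diameter_mm: float = 7.0
    min_diameter_mm: float = 3.0
    proximal_cone_mm: float = 2.0  # taper length at the nasopharyngeal end
    marker_band_mm: float = 0.8  # axial thickness of each radiopaque band


@dataclass(frozen=True)
class PhantomIntensities:
    """Mean 8-bit gray values per material.

    Defaults sit inside the calibrated reference ranges (air <= 16, tissue
    42-88, bone 214-255) so default densitometry classifies the phantom
    correctly.  The balloon wall has no in-vivo reference statistics and
    is a free parameter between tissue and bone.
    """

    air: float = 5.0
    tissue: float = 64.0
    bone: float = 235.0
    balloon: float = 120.0
    marker: float = 245.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of one phantom ear.

    ``dilation_factor`` multiplies the mid-cartilaginous lumen width post
    vs pre.  The nasopharyngeal-opening and isthmus levels receive a fixed
    share of the mid-level excess (factor ``1 + share * (f - 1)``), which
    concentrates dilation at mid-lumen the way the balloon's cylindrical
    segment does; ``dilation_factor = 1`` therefore leaves the whole
    geometry unchanged.
    """

    shape: tuple[int, int, int] = (52, 160, 64)
    spacing: tuple[float, float, float] = (0.625, 0.3125, 0.3125)
    lumen_length_mm: float = 25.0
    cartilaginous_fraction: float = 0.6
    lumen_width_pre_mm: tuple[float, float, float] = (3.5, 3.0, 2.0)  # NP, mid, isthmus
    dilation_factor: float = 1.72
    np_dilation_share: float = 0.11
    isthmus_dilation_share: float = 0.53
    lumen_aspect: float = 1.0  # out-of-plane/in-plane half-axis ratio
    balloon: BalloonSpec = field(default_factory=BalloonSpec)
    intensities: PhantomIntensities = field(default_factory=PhantomIntensities)
    noise_sd: float = 5.0
    partial_volume: int = 3  # supersampling factor per axis
    seed: int = 0

    # world-frame placement of the lumen axis; fixed for the default shape
    axis_origin_mm: tuple[float, float, float] = (8.0, 10.0, 9.0)
    axis_direction: tuple[float, float, float] = (0.35, 0.93, 0.10)  # (z, y, x)

    def __post_init__(self) -> None:
        if self.dilation_factor < 1:
            raise ValueError("dilation_factor must be >= 1")
        if not (0 <= self.np_dilation_share <= 1 and 0 <= self.isthmus_dilation_share <= 1):
            raise ValueError("dilation shares must lie in [0, 1]")
        if any(w <= 0 for w in self.lumen_width_pre_mm):
            raise ValueError("lumen widths must be > 0")
        if not 0 < self.cartilaginous_fraction < 1:
            raise ValueError("cartilaginous_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.partial_volume < 1:
            raise ValueError("partial_volume supersampling factor must be >= 1")
        if self.lumen_aspect <= 0:
            raise ValueError("lumen_aspect must be > 0")

    # ---- derived axis geometry -------------------------------------------

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(origin, u, v, n): lumen-plane frame in world mm, v along the axis."""
        origin = np.asarray(self.axis_origin_mm, dtype=float)
        v = np.asarray(self.axis_direction, dtype=float)
        v = v / np.linalg.norm(v)
        x_hat = np.array([0.0, 0.0, 1.0])
        u = x_hat - (x_hat @ v) * v
        u = u / np.linalg.norm(u)
        n = np.cross(u, v)
        n = n / np.linalg.norm(n)
        return origin, u, v, n

    def axis_point(self, t_mm: float) -> np.ndarray:
        origin, _, v, _ = self.frame()
        return origin + t_mm * v

    @property
    def junction_t(self) -> float:
        """Axial position of the cartilaginous/bony junction (= widest balloon level)."""
        return self.cartilaginous_fraction * self.lumen_length_mm

    def marker_ts(self) -> tuple[float, float]:
        """Axial positions of the two radiopaque bands (cylindrical segment ends)."""
        distal_cone = self.lumen_length_mm - self.junction_t
        cyl = self.balloon.length_mm - self.balloon.proximal_cone_mm - distal_cone
        if cyl < 1.0:
            raise ValueError("balloon cylindrical segment shorter than 1 mm; "
                             "incompatible balloon/lumen geometry")
        return self.junction_t - cyl, self.junction_t

    @property
    def mid_level_t(self) -> float:
        """Mid-balloon level: center of the cylindrical segment."""
        a, b = self.marker_ts()
        return 0.5 * (a + b)

    def width_knots(self, state: str) -> tuple[np.ndarray, np.ndarray]:
        """(t positions, widths in mm) of the three-knot taper for a state."""
        ts = np.array([0.0, self.mid_level_t, self.junction_t])
        widths = np.asarray(self.lumen_width_pre_mm, dtype=float)
        if state in ("post", "during"):
            excess = self.dilation_factor - 1.0
            factors = 1.0 + excess * np.array(
                [self.np_dilation_share, 1.0, self.isthmus_dilation_share]
            )
            widths = widths * factors
        elif state != "pre":
            raise ValueError(f"unknown state {state!r}")
        return ts, widths

    def lumen_width_at(self, t, state: str) -> np.ndarray:
        """Lumen width (mm) along the axis: linear taper between the knots,
        constant through the bony portion."""
        ts, widths = self.width_knots(state)
        t = np.asarray(t, dtype=float)
        return np.interp(t, ts, widths, left=widths[0], right=widths[-1])


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything the phantom knows that a cadaver scan would not reveal."""

    landmarks: LandmarkSet  # voxel coordinates, incl. torus/tip/markers
    widest_point: tuple[float, float, float]  # voxel coords of the widest balloon level
    lumen_mask_pre: np.ndarray
    lumen_mask_post: np.ndarray
    bone_mask: np.ndarray
    np_air_mask: np.ndarray
    air_count_pre: int
    air_count_post: int
    air_count_pre_cylinder: int
    air_count_post_cylinder: int
    widths_pre_mm: tuple[float, float, float]
    widths_post_mm: tuple[float, float, float]
    widths_pre_px: tuple[float, float, float]
    widths_post_px: tuple[float, float, float]
    distances_mm: tuple[float, float, float]  # total, torus->widest, widest->tip
    distances_px: tuple[float, float, float]
    reference_regions: dict[str, tuple[slice, slice, slice]]  # air/tissue/bone index boxes
    pixel_spacing_mm: float  # isotropic in-plane spacing the px values refer to

    def percent_air_increase(self, region: str = "lumen") -> float:
        """True air-count increase, over the whole lumen or the
        marker-to-marker cylinder span the small ROI measures."""
        if region == "lumen":
            pre, post = self.air_count_pre, self.air_count_post
        elif region == "cylinder":
            pre, post = self.air_count_pre_cylinder, self.air_count_post_cylinder
        else:
            raise ValueError(f"unknown region {region!r}")
        return 100.0 * (post - pre) / pre


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

NP_FUNNEL_LENGTH_MM = 8.0
NP_FUNNEL_RADIUS_MM = (2.0, 5.0)  # at the torus, at the funnel mouth
BONE_GAP_MM = 1.0  # tissue gap between lumen end and the bone block
BONE_LENGTH_MM = 10.0
BONE_HALF_U_MM = 10.0
BONE_HALF_N_MM = 6.0
MARKER_RADIAL_EXTRA_MM = 0.3


def _balloon_radius(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    """Balloon outer radius along the axis (mm); 0 outside the balloon."""
    tip = spec.lumen_length_mm
    start = tip - spec.balloon.length_mm
    cyl_lo, cyl_hi = spec.marker_ts()
    r_max = spec.balloon.max_diameter_mm / 2.0
    r_min = spec.balloon.min_diameter_mm / 2.0
    t = np.asarray(t, dtype=float)
    r = np.zeros_like(t)
    prox = (t >= start) & (t < cyl_lo)
    cone_len = cyl_lo - start
    if cone_len > 0:
        r[prox] = r_min + (r_max - r_min) * (t[prox] - start) / cone_len
    cyl = (t >= cyl_lo) & (t <= cyl_hi)
    r[cyl] = r_max
    dist = (t > cyl_hi) & (t <= tip)
    dcone = tip - cyl_hi
    if dcone > 0:
        r[dist] = r_max - (r_max - r_min) * (t[dist] - cyl_hi) / dcone
    return r


def _material_maps(spec: PhantomSpec, points: np.ndarray, state: str) -> np.ndarray:
    """Gray value of the phantom material at each world point (no noise)."""
    origin, u, v, n = spec.frame()
    d = points - origin
    t = d @ v
    du = d @ u
    dn = d @ n
    inten = spec.intensities
    out = np.full(t.shape, float(inten.tissue))

    # lumen air (state-dependent taper)
    half_u = spec.lumen_width_at(t, "post" if state == "during" else state) / 2.0
    half_n = half_u * spec.lumen_aspect
    in_lumen = (t >= 0) & (t <= spec.lumen_length_mm) & (
        (du / np.maximum(half_u, 1e-9)) ** 2 + (dn / np.maximum(half_n, 1e-9)) ** 2 <= 1.0
    )
    out[in_lumen] = inten.air

    # nasopharyngeal air funnel beyond the torus
    r0, r1 = NP_FUNNEL_RADIUS_MM
    frac = np.clip(-t / NP_FUNNEL_LENGTH_MM, 0.0, 1.0)
    funnel_r = r0 + (r1 - r0) * frac
    in_np = (t < 0) & (t >= -NP_FUNNEL_LENGTH_MM) & (du**2 + dn**2 <= funnel_r**2)
    out[in_np] = inten.air

    # petrous-bone-like block past the posterior lumen end
    t_bone0 = spec.lumen_length_mm + BONE_GAP_MM
    in_bone = (
        (t >= t_bone0)
        & (t <= t_bone0 + BONE_LENGTH_MM)
        & (np.abs(du) <= BONE_HALF_U_MM)
        & (np.abs(dn) <= BONE_HALF_N_MM)
    )
    out[in_bone] = inten.bone

    if state == "during":
        rho2 = du**2 + dn**2
        br = _balloon_radius(spec, t)
        in_balloon = (br > 0) & (rho2 <= br**2)
        out[in_balloon] = inten.balloon
        half_band = spec.balloon.marker_band_mm / 2.0
        for tm in spec.marker_ts():
            band = (np.abs(t - tm) <= half_band) & (
                rho2 <= (_balloon_radius(spec, np.asarray([tm]))[0] + MARKER_RADIAL_EXTRA_MM) ** 2
            )
            out[band] = inten.marker
    return out


def _render_state(spec: PhantomSpec, state: str, rng: np.random.Generator) -> np.ndarray:
    """Render one state: supersample, block-average, add noise, quantize."""
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    s = spec.partial_volume
    sub = (np.arange(s) + 0.5) / s - 0.5
    ys = (np.arange(ny)[:, None] + sub[None, :]).ravel() * dy
    xs = (np.arange(nx)[:, None] + sub[None, :]).ravel() * dx
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    vol = np.empty(spec.shape, dtype=float)
    for i in range(nz):
        acc = np.zeros((ny * s, nx * s))
        for j in range(s):
            z = (i + sub[j]) * dz
            pts = np.stack([np.full(yy.shape, z), yy, xx], axis=-1)
            acc += _material_maps(spec, pts, state)
        sup = acc / s
        # block mean over the s x s in-plane subgrid
        vol[i] = sup.reshape(ny, s, nx, s).mean(axis=(1, 3))
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    return np.clip(np.floor(vol + 0.5), 0, 255).astype(np.uint8)


def _voxel_center_points(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    zz, yy, xx = np.meshgrid(
        np.arange(nz) * dz, np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij"
    )
    return np.stack([zz, yy, xx], axis=-1)


def _masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Voxel-center membership masks (supersampling-independent)."""
    pts = _voxel_center_points(spec)
    origin, u, v, n = spec.frame()
    d = pts - origin
    t = d @ v
    du = d @ u
    dn = d @ n
    out = {}
    for state in ("pre", "post"):
        half_u = spec.lumen_width_at(t, state) / 2.0
        half_n = half_u * spec.lumen_aspect
        out[f"lumen_{state}"] = (
            (t >= 0)
            & (t <= spec.lumen_length_mm)
            & ((du / np.maximum(half_u, 1e-9)) ** 2 + (dn / np.maximum(half_n, 1e-9)) ** 2 <= 1.0)
        )
    t_a, t_b = spec.marker_ts()
    in_cyl = (t >= t_a) & (t <= t_b)
    for state in ("pre", "post"):
        out[f"lumen_{state}_cylinder"] = out[f"lumen_{state}"] & in_cyl
    r0, r1 = NP_FUNNEL_RADIUS_MM
    frac = np.clip(-t / NP_FUNNEL_LENGTH_MM, 0.0, 1.0)
    funnel_r = r0 + (r1 - r0) * frac
    out["np_air"] = (t < 0) & (t >= -NP_FUNNEL_LENGTH_MM) & (du**2 + dn**2 <= funnel_r**2)
    t_bone0 = spec.lumen_length_mm + BONE_GAP_MM
    out["bone"] = (
        (t >= t_bone0)
        & (t <= t_bone0 + BONE_LENGTH_MM)
        & (np.abs(du) <= BONE_HALF_U_MM)
        & (np.abs(dn) <= BONE_HALF_N_MM)
    )
    return out


def _check_bounds(spec: PhantomSpec) -> None:
    """Reject lumens that poke out of the volume."""
    extent = (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing)
    _, u, _, n = spec.frame()
    half_max = float(np.max(spec.lumen_width_at(
        np.linspace(0, spec.lumen_length_mm, 64), "post")) / 2.0)
    half_max = half_max * max(1.0, spec.lumen_aspect)
    for t in (0.0, spec.junction_t, spec.lumen_length_mm):
        p = spec.axis_point(t)
        for off in (u * half_max, -u * half_max, n * half_max, -n * half_max):
            q = p + off
            if np.any(q < 0) or np.any(q > extent):
                raise ValueError("lumen exceeds volume bounds")


def _reference_regions(spec: PhantomSpec) -> dict[str, tuple[slice, slice, slice]]:
    """Small voxel boxes guaranteed to sample pure air / tissue / bone."""
    _, u, _, n = spec.frame()
    centers = {
        "air": spec.axis_point(-5.0),
        "tissue": spec.axis_point(5.0) + 4.0 * n,
        "bone": spec.axis_point(spec.lumen_length_mm + BONE_GAP_MM + BONE_LENGTH_MM / 2.0),
    }
    half_mm = (1.0, 1.5, 1.5)
    regions = {}
    for name, c in centers.items():
        idx = c / np.asarray(spec.spacing)
        box = []
        for axis in range(3):
            h = max(1, int(round(half_mm[axis] / spec.spacing[axis])))
            lo = int(round(idx[axis])) - h
            hi = int(round(idx[axis])) + h + 1
            lo = max(lo, 0)
            hi = min(hi, spec.shape[axis])
            box.append(slice(lo, hi))
        regions[name] = tuple(box)
    return regions


def compute_ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Ground truth for a spec without rendering any volumes (fast path)."""
    _check_bounds(spec)
    return _ground_truth(spec, _masks(spec))


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, Volume, Volume, GroundTruth]:
    """Render the pre-, during- and post-dilation volumes plus ground truth.

    Deterministic given ``spec.seed``: two calls return bit-identical
    volumes.  Raises if the (post-dilation) lumen would leave the volume.
    """
    _check_bounds(spec)
    vols = {}
    for idx, state in enumerate(("pre", "during", "post")):
        rng = np.random.default_rng([int(spec.seed), idx])
        vols[state] = Volume(_render_state(spec, state, rng), spec.spacing, "gray8")
    gt = _ground_truth(spec, _masks(spec))
    return vols["pre"], vols["during"], vols["post"], gt


def _ground_truth(spec: PhantomSpec, masks: dict[str, np.ndarray]) -> GroundTruth:
    spacing = np.asarray(spec.spacing)
    t_a, t_b = spec.marker_ts()

    def vox(p_mm: np.ndarray) -> tuple[float, float, float]:
        return tuple(float(x) for x in (p_mm / spacing))

    origin, u, v, n = spec.frame()
    landmarks = LandmarkSet(
        medial_pterygoid_plate=vox(spec.axis_point(2.0) - 6.0 * u),
        opposite_pterygoid_plate=vox(spec.axis_point(2.0) + 6.0 * u),
        sphenoid_spine=vox(spec.axis_point(32.0)),
        torus_tip=vox(spec.axis_point(0.0)),
        balloon_tip=vox(spec.axis_point(spec.lumen_length_mm)),
        marker_a=vox(spec.axis_point(t_a)),
        marker_b=vox(spec.axis_point(t_b)),
    )

    px = float(min(spec.spacing[1], spec.spacing[2]))  # reslice pixel spacing
    _, w_pre = spec.width_knots("pre")
    _, w_post = spec.width_knots("post")
    L = spec.lumen_length_mm
    d_mm = (L, spec.junction_t, L - spec.junction_t)
    gt = GroundTruth(
        landmarks=landmarks,
        widest_point=vox(spec.axis_point(spec.junction_t)),
        lumen_mask_pre=masks["lumen_pre"],
        lumen_mask_post=masks["lumen_post"],
        bone_mask=masks["bone"],
        np_air_mask=masks["np_air"],
        air_count_pre=int(masks["lumen_pre"].sum()),
        air_count_post=int(masks["lumen_post"].sum()),
        air_count_pre_cylinder=int(masks["lumen_pre_cylinder"].sum()),
        air_count_post_cylinder=int(masks["lumen_post_cylinder"].sum()),
        widths_pre_mm=tuple(float(w) for w in w_pre),
        widths_post_mm=tuple(float(w) for w in w_post),
        widths_pre_px=tuple(float(w / px) for w in w_pre),
        widths_post_px=tuple(float(w / px) for w in w_post),
        distances_mm=tuple(float(d) for d in d_mm),
        distances_px=tuple(float(d / px) for d in d_mm),
        reference_regions=_reference_regions(spec),
        pixel_spacing_mm=px,
    )
    return gt


# ---------------------------------------------------------------------------
# Analytic air-volume model (for choosing dilation factors)
# ---------------------------------------------------------------------------


def _region_bounds(spec: PhantomSpec, region: str) -> tuple[float, float]:
    """Axial bounds of an analysis region: the whole lumen, or the balloon's
    cylindrical (marker-to-marker) span the small ROI covers."""
    if region == "lumen":
        return 0.0, spec.lumen_length_mm
    if region == "cylinder":
        return spec.marker_ts()
    raise ValueError(f"unknown region {region!r}")


def _profile_area_integral(spec: PhantomSpec, state: str, t_lo: float, t_hi: float) -> float:
    """Integral of the lumen cross-section area over [t_lo, t_hi] (mm^3)."""
    half = lambda t: spec.lumen_width_at(t, state) / 2.0  # piecewise linear
    ts, _ = spec.width_knots(state)
    knots = sorted({t_lo, t_hi, *[t for t in ts if t_lo < t < t_hi]})
    total = 0.0
    for t0, t1 in zip(knots, knots[1:]):
        a, b = float(half(t0)), float(half(t1))
        total += (t1 - t0) * (a * a + a * b + b * b) / 3.0
    return float(np.pi * spec.lumen_aspect * total)


def true_air_increase_percent(spec: PhantomSpec, region: str = "lumen") -> float:
    """Analytic relative air-volume increase post vs pre, in percent.

    ``region="lumen"`` integrates the whole tube; ``region="cylinder"``
    only the marker-to-marker span the small ROI measures (dilation is
    concentrated there, so its regional increase exceeds the global one).
    """
    t_lo, t_hi = _region_bounds(spec, region)
    pre = _profile_area_integral(spec, "pre", t_lo, t_hi)
    post = _profile_area_integral(spec, "post", t_lo, t_hi)
    return 100.0 * (post - pre) / pre


def dilation_factor_for_air_increase(
    spec: PhantomSpec, target_percent: float, region: str = "lumen"
) -> PhantomSpec:
    """Return a spec whose mid-lumen dilation factor yields the target
    analytic air-volume increase in ``region`` (end-level shares fixed)."""
    if target_percent < 0:
        raise ValueError("target increase must be >= 0")
    if target_percent == 0:
        return replace(spec, dilation_factor=1.0)

    def gap(f: float) -> float:
        return (
            true_air_increase_percent(replace(spec, dilation_factor=f), region)
            - target_percent
        )

    f = brentq(gap, 1.0, 8.0, xtol=1e-10)
    return replace(spec, dilation_factor=f)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_phantom_series(v: Volume, directory) -> list[Path]:
    """Write one phantom state as a DICOM series readable by volume I/O."""
    return write_dicom_series(v, directory)


def write_ground_truth(gt: GroundTruth, basepath) -> None:
    """Persist ground truth: JSON scalars/coordinates + .npy masks."""
    basepath = Path(basepath)
    np.save(basepath.with_suffix(".masks.npy"), np.stack([
        gt.lumen_mask_pre, gt.lumen_mask_post, gt.bone_mask, gt.np_air_mask
    ]))
    lm = gt.landmarks
    payload = {
        "coordinate_convention": "zyx0",
        "landmarks": {
            name: list(getattr(lm, name))
            for name in (
                "medial_pterygoid_plate", "opposite_pterygoid_plate", "sphenoid_spine",
                "torus_tip", "balloon_tip", "marker_a", "marker_b",
            )
            if getattr(lm, name) is not None
        },
        "widest_point": list(gt.widest_point),
        "air_count_pre": gt.air_count_pre,
        "air_count_post": gt.air_count_post,
        "air_count_pre_cylinder": gt.air_count_pre_cylinder,
        "air_count_post_cylinder": gt.air_count_post_cylinder,
        "widths_pre_mm": list(gt.widths_pre_mm),
        "widths_post_mm": list(gt.widths_post_mm),
        "widths_pre_px": list(gt.widths_pre_px),
        "widths_post_px": list(gt.widths_post_px),
        "distances_mm": list(gt.distances_mm),
        "distances_px": list(gt.distances_px),
        "pixel_spacing_mm": gt.pixel_spacing_mm,
        "reference_regions": {
            k: [[s.start, s.stop] for s in v] for k, v in gt.reference_regions.items()
        },
    }
    basepath.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def load_ground_truth(basepath) -> GroundTruth:
    basepath = Path(basepath)
    data = json.loads(basepath.with_suffix(".json").read_text())
    masks = np.load(basepath.with_suffix(".masks.npy"))
    lm = LandmarkSet(**{k: tuple(v) for k, v in data["landmarks"].items()})
    return GroundTruth(
        landmarks=lm,
        widest_point=tuple(data["widest_point"]),
        lumen_mask_pre=masks[0].astype(bool),
        lumen_mask_post=masks[1].astype(bool),
        bone_mask=masks[2].astype(bool),
        np_air_mask=masks[3].astype(bool),
        air_count_pre=int(data["air_count_pre"]),
        air_count_post=int(data["air_count_post"]),
        air_count_pre_cylinder=int(data["air_count_pre_cylinder"]),
        air_count_post_cylinder=int(data["air_count_post_cylinder"]),
        widths_pre_mm=tuple(data["widths_pre_mm"]),
        widths_post_mm=tuple(data["widths_post_mm"]),
        widths_pre_px=tuple(data["widths_pre_px"]),
        widths_post_px=tuple(data["widths_post_px"]),
        distances_mm=tuple(data["distances_mm"]),
        distances_px=tuple(data["distances_px"]),
        reference_regions={
            k: tuple(slice(a, b) for a, b in v) for k, v in data["reference_regions"].items()
        },
        pixel_spacing_mm=float(data["pixel_spacing_mm"]),
    )
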