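"""Landmark-defined oblique reslicing of a CT volume.

The Eustachian-tube longitudinal axis does not lie in the axial acquisition
plane.  The viewing plane is anchored on three bony landmarks — the medial
pterygoid plate, the contralateral pterygoid plate / hamulus, and the
sphenoid spine — which, in a well-annotated scan, are coplanar with the
tube's long axis.  From that plane the package extracts the center image
plus a configurable number of parallel images toward cranial and caudal
(default 12 each, 25 in total), then rotates them by a single common angle
so the lumen runs vertically with the nasopharyngeal end at the top.

All plane geometry is done in world mm coordinates; landmark files carry
0-based voxel indices in (slice, row, col) order and must declare that
convention explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "LandmarkSet",
    "PlaneFrame",
    "SliceStack",
    "plane_from_landmarks",
    "extract_stack",
    "rotate_to_vertical",
    "rotate_point_2d",
    "plane_point_to_pixel",
    "load_landmarks",
    "save_landmarks",
]

#: landmark triangles with area below this are treated as annotation errors
MIN_TRIANGLE_AREA_MM2 = 1.0

COORDINATE_CONVENTION = "zyx0"  # 0-based (slice, row, col) voxel-center indices


@dataclass
class LandmarkSet:
    """Named anatomical points in 0-based voxel coordinates (z, y, x).

    The three plane landmarks are mandatory; balloon-derived points
    (catheter tip, torus tip, radiopaque markers) are optional and, when
    present, orient the in-plane vertical axis along the lumen.
    """

    medial_pterygoid_plate: tuple[float, float, float]
    opposite_pterygoid_plate: tuple[float, float, float]
    sphenoid_spine: tuple[float, float, float]
    balloon_tip: tuple[float, float, float] | None = None
    torus_tip: tuple[float, float, float] | None = None
    marker_a: tuple[float, float, float] | None = None
    marker_b: tuple[float, float, float] | None = None

    def plane_points(self) -> list[np.ndarray]:
        return [
            np.asarray(self.medial_pterygoid_plate, dtype=float),
            np.asarray(self.opposite_pterygoid_plate, dtype=float),
            np.asarray(self.sphenoid_spine, dtype=float),
        ]


@dataclass
class PlaneFrame:
    """Orthonormal frame of the reslicing plane, in world mm coordinates.

    ``in_plane_v`` is the image "down" direction (rows), chosen along the
    lumen axis from torus toward balloon tip so the nasopharyngeal end sits
    at the top of extracted images; ``in_plane_u`` is the image "right"
    direction (columns); ``normal`` steps through the stack.
    """

    origin: np.ndarray  # mm (z, y, x)
    in_plane_u: np.ndarray
    in_plane_v: np.ndarray
    normal: np.ndarray
    slice_step: float = 0.625  # mm

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.in_plane_u = np.asarray(self.in_plane_u, dtype=float)
        self.in_plane_v = np.asarray(self.in_plane_v, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        for vec in (self.in_plane_u, self.in_plane_v, self.normal):
            if abs(np.linalg.norm(vec) - 1.0) > 1e-9:
                raise ValueError("frame directions must be unit vectors")
        for a, b in ((self.in_plane_u, self.in_plane_v),
                     (self.in_plane_u, self.normal),
                     (self.in_plane_v, self.normal)):
            if abs(float(a @ b)) > 1e-9:
                raise ValueError("frame directions must be orthogonal")
        if self.slice_step <= 0:
            raise ValueError("slice_step must be > 0")


@dataclass
class SliceStack:
    """An ordered stack of resliced 2D images with signed mm offsets.

    Offsets are strictly increasing, symmetric about 0, with the center
    image at offset 0.  Pixel values are kept continuous (float) internally
    and only quantized to integers at histogram/export time, avoiding a
    second quantization on top of the acquisition one.
    """

    images: list[np.ndarray]
    offsets: np.ndarray  # mm, signed
    pixel_spacing: tuple[float, float]  # (row, col) mm

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if len(self.images) != len(self.offsets):
            raise ValueError("one offset per image required")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError("stack images must share one shape")
        if len(self.offsets) and not np.all(np.diff(self.offsets) > 0):
            raise ValueError("offsets must be strictly increasing")
        if len(self.offsets) and np.abs(self.offsets + self.offsets[::-1]).max() > 1e-9:
            raise ValueError("offsets must be symmetric about 0")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def center(self) -> np.ndarray:
        return self.images[len(self.images) // 2]


def _unit(vec: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(vec)
    if n == 0:
        raise ValueError("zero-length direction")
    return vec / n


def plane_from_landmarks(lm: LandmarkSet, spacing, slice_step: float | None = None) -> PlaneFrame:
    """Build the reslicing frame from the three bony landmarks.

    The plane contains all three landmarks; its origin is their centroid.
    The in-plane vertical ``v`` follows the projected lumen axis (torus ->
    balloon tip) when those points are annotated, otherwise the longest
    triangle edge.  The normal's sign is fixed cranial-positive so the
    frame does not depend on landmark ordering.

    Raises ``ValueError("degenerate plane")`` when the landmark triangle
    has area below 1 mm^2 (sub-millimeter triangles are annotation errors
    at CT resolution).
    """
    spacing = np.asarray(spacing, dtype=float)
    pts = [p * spacing for p in lm.plane_points()]
    cross = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    area = 0.5 * np.linalg.norm(cross)
    if area <= MIN_TRIANGLE_AREA_MM2:
        raise ValueError("degenerate plane")
    normal = _unit(cross)
    # cranial-positive: slice index grows cranial->caudal, so cranial is -z
    if normal[0] > 0 or (normal[0] == 0 and (normal[1] < 0 or (normal[1] == 0 and normal[2] < 0))):
        normal = -normal
    origin = np.mean(pts, axis=0)

    if lm.torus_tip is not None and lm.balloon_tip is not None:
        axis = (np.asarray(lm.balloon_tip, float) - np.asarray(lm.torus_tip, float)) * spacing
    else:
        edges = [pts[1] - pts[0], pts[2] - pts[1], pts[0] - pts[2]]
        lengths = [np.linalg.norm(e) for e in edges]
        axis = edges[int(np.argmax(lengths))]
        # orientation-stable tie-break: point the axis into a fixed half-space
        if axis[0] < 0 or (axis[0] == 0 and (axis[1] < 0 or (axis[1] == 0 and axis[2] < 0))):
            axis = -axis
    v = axis - (axis @ normal) * normal
    v = _unit(v)
    u = _unit(np.cross(v, normal))
    step = float(slice_step) if slice_step is not None else float(spacing[0])
    return PlaneFrame(origin, u, v, normal, step)


def extract_stack(
    v: Volume,
    frame: PlaneFrame,
    half_count: int = 12,
    size_px: tuple[int, int] = (160, 96),
    pixel_spacing: float | None = None,
) -> SliceStack:
    """Sample ``2*half_count + 1`` parallel images through the volume.

    Images are sampled by trilinear interpolation on the plane grid
    ``origin + (r - (R-1)/2) s v + (c - (C-1)/2) s u + k*step*n`` with
    isotropic in-plane pixel size ``s`` (default: min of native row/col
    spacing, preventing direction-dependent width bias).  Samples outside
    the volume read as 0.
    """
    if half_count < 0:
        raise ValueError("half_count must be >= 0")
    rows, cols = int(size_px[0]), int(size_px[1])
    s = float(pixel_spacing) if pixel_spacing else float(min(v.spacing[1], v.spacing[2]))
    r_idx = (np.arange(rows) - (rows - 1) / 2.0) * s
    c_idx = (np.arange(cols) - (cols - 1) / 2.0) * s
    rr, cc = np.meshgrid(r_idx, c_idx, indexing="ij")
    base = (
        frame.origin[None, None, :]
        + rr[..., None] * frame.in_plane_v[None, None, :]
        + cc[..., None] * frame.in_plane_u[None, None, :]
    )
    spacing = np.asarray(v.spacing)
    origin = np.asarray(v.origin)
    voxels = np.asarray(v.voxels, dtype=float)
    images, offsets = [], []
    for k in range(-half_count, half_count + 1):
        pts = base + (k * frame.slice_step) * frame.normal[None, None, :]
        idx = (pts - origin) / spacing  # (rows, cols, 3) in (z, y, x) index space
        img = ndimage.map_coordinates(
            voxels, [idx[..., 0], idx[..., 1], idx[..., 2]], order=1, mode="constant", cval=0.0
        )
        images.append(img)
        offsets.append(k * frame.slice_step)
    return SliceStack(images, np.asarray(offsets), (s, s))


def rotate_to_vertical(stack: SliceStack, lumen_axis_2d) -> tuple[SliceStack, float]:
    """Rotate every image by one common angle so the lumen runs vertically.

    ``lumen_axis_2d`` is the in-image (d_row, d_col) direction of the lumen
    pointing from the nasopharyngeal end toward the balloon tip; it is
    mapped onto +rows (downward), which puts the nasopharynx at the top.
    Returns the rotated stack and the applied angle in degrees
    (counter-clockwise in image axes).
    """
    axis = np.asarray(lumen_axis_2d, dtype=float)
    if np.linalg.norm(axis) == 0:
        raise ValueError("lumen axis must be a nonzero vector")
    # angle of the axis relative to +row direction
    angle_deg = float(np.degrees(np.arctan2(axis[1], axis[0])))
    rotated = [
        ndimage.rotate(im, angle_deg, reshape=False, order=1, mode="constant", cval=0.0)
        for im in stack.images
    ]
    return SliceStack(rotated, stack.offsets, stack.pixel_spacing), angle_deg


def rotate_point_2d(point_rc, angle_deg: float, shape) -> np.ndarray:
    """Map a (row, col) point through the rotation applied by rotate_to_vertical."""
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    p = np.asarray(point_rc, dtype=float) - center
    # scipy rotates image content by +angle (ccw in array axes); the matching
    # point map is the rotation of coordinates by -angle
    a = np.radians(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return rot @ p + center


def plane_point_to_pixel(frame: PlaneFrame, point_mm, size_px, pixel_spacing) -> np.ndarray:
    """Project a world point into (row, col) pixel coordinates of the center image."""
    d = np.asarray(point_mm, dtype=float) - frame.origin
    r = float(d @ frame.in_plane_v) / pixel_spacing + (size_px[0] - 1) / 2.0
    c = float(d @ frame.in_plane_u) / pixel_spacing + (size_px[1] - 1) / 2.0
    return np.array([r, c])


# ---------------------------------------------------------------------------
# Landmark file I/O
# ---------------------------------------------------------------------------

_REQUIRED = ("medial_pterygoid_plate", "opposite_pterygoid_plate", "sphenoid_spine")
_OPTIONAL = ("balloon_tip", "torus_tip", "marker_a", "marker_b")


def load_landmarks(path) -> LandmarkSet:
    """Load a landmark JSON file; refuses files without a declared convention."""
    data = json.loads(Path(path).read_text())
    conv = data.get("coordinate_convention")
    if conv != COORDINATE_CONVENTION:
        raise ValueError(
            f"landmark file must declare coordinate_convention={COORDINATE_CONVENTION!r}"
        )
    kwargs = {}
    for name in _REQUIRED:
        if name not in data:
            raise ValueError(f"missing landmark {name!r}")
        kwargs[name] = tuple(float(x) for x in data[name])
    for name in _OPTIONAL:
        if data.get(name) is not None:
            kwargs[name] = tuple(float(x) for x in data[name])
    return LandmarkSet(**kwargs)


def save_landmarks(lm: LandmarkSet, path) -> None:
    data = {"coordinate_convention": COORDINATE_CONVENTION}
    for name in _REQUIRED + _OPTIONAL:
        val = getattr(lm, name)
        if val is not None:
            data[name] = list(val)
    Path(path).write_text(json.dumps(data, indent=2))
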