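"""CT volume container and I/O.

A :class:`Volume` is the package's in-memory representation of a CT scan:
a 3D scalar grid (axial slices x rows x columns) with voxel spacing in mm
and an intensity kind — either calibrated Hounsfield units (``"HU"``) or
8-bit display gray values (``"gray8"``, range 0..255) as produced by
window/level conversion.

Coordinate convention (fixed package-wide): indices are 0-based and refer
to voxel centers; axis order is (slice, row, column); the axial slice index
increases cranial -> caudal.  World (mm) coordinates are
``origin + index * spacing`` per axis, in the same (z, y, x) order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Volume",
    "WindowSpec",
    "round_half_up",
    "read_dicom_series",
    "write_dicom_series",
    "read_raw_volume",
    "write_raw_volume",
    "window_to_gray8",
    "export_png",
]


def round_half_up(x):
    """Round to the nearest integer with exact .5 ties going up."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class Volume:
    """A 3D CT volume with geometry and intensity semantics."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]  # (slice, row, col) mm
    intensity_kind: str = "HU"  # "HU" or "gray8"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s < 2 for s in self.voxels.shape):
            raise ValueError("each volume dimension must have at least 2 samples")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive mm values")
        if self.intensity_kind not in ("HU", "gray8"):
            raise ValueError(f"unknown intensity kind {self.intensity_kind!r}")
        if self.intensity_kind == "gray8":
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < 0 or hi > 255:
                raise ValueError("gray8 voxels must lie in [0, 255]")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_mm(self, index_zyx) -> np.ndarray:
        """Map (slice, row, col) voxel indices to world mm coordinates."""
        idx = np.asarray(index_zyx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def mm_to_index(self, point_mm) -> np.ndarray:
        p = np.asarray(point_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass(frozen=True)
class WindowSpec:
    """CT display window: center ``level`` and full ``width`` in HU."""

    level: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")


#: Soft-tissue display window used by default for Eustachian-tube work:
#: air maps to 0 and cortical bone saturates at 255, which preserves the
#: air / soft-tissue / bone separability the densitometry relies on.
SOFT_TISSUE_WINDOW = WindowSpec(level=40.0, width=400.0)


def window_to_gray8(v: Volume, w: WindowSpec = SOFT_TISSUE_WINDOW) -> Volume:
    """Convert an HU volume to 8-bit display gray values.

    The window ``[level - width/2, level + width/2]`` maps linearly onto
    [0, 255]; values outside are clamped; results are rounded half-up to
    integers.  Monotone non-decreasing in the input HU.
    """
    if v.intensity_kind != "HU":
        raise ValueError("window_to_gray8 expects an HU volume")
    lo = w.level - w.width / 2.0
    scaled = (np.asarray(v.voxels, dtype=float) - lo) / w.width * 255.0
    gray = np.clip(round_half_up(scaled), 0, 255).astype(np.uint8)
    return Volume(gray, v.spacing, "gray8", v.origin)


# ---------------------------------------------------------------------------
# DICOM series I/O (single-frame axial CT; enhanced multi-frame unsupported)
# ---------------------------------------------------------------------------


def read_dicom_series(directory) -> Volume:
    """Read a directory of single-frame CT slices into a Volume.

    Slices are sorted by spatial position along the slice axis.  Rescale
    slope/intercept are applied, so 16-bit data comes back as HU; 8-bit
    data with an identity rescale is treated as display gray values.

    Raises ``ValueError("mixed series")`` if the directory holds more than
    one series and ``ValueError("incomplete geometry")`` if spacing cannot
    be established from the headers.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ""))
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:
            continue
    if len(datasets) < 2:
        raise ValueError("need at least 2 DICOM slices of one series")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) != 1:
        raise ValueError("mixed series")

    def position(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        loc = getattr(ds, "SliceLocation", None)
        if loc is not None:
            return float(loc)
        raise ValueError("incomplete geometry")

    try:
        datasets.sort(key=position)
        zs = np.array([position(ds) for ds in datasets])
    except ValueError:
        raise ValueError("incomplete geometry") from None

    ds0 = datasets[0]
    ps = getattr(ds0, "PixelSpacing", None)
    if ps is None:
        raise ValueError("incomplete geometry")
    dz = np.diff(zs)
    if len(dz) and np.all(dz > 0):
        slice_spacing = float(np.median(dz))
    else:
        st = getattr(ds0, "SliceThickness", None)
        if st is None:
            raise ValueError("incomplete geometry")
        slice_spacing = float(st)

    slope = float(getattr(ds0, "RescaleSlope", 1.0))
    intercept = float(getattr(ds0, "RescaleIntercept", 0.0))
    bits = int(getattr(ds0, "BitsAllocated", 16))

    frames = np.stack([ds.pixel_array for ds in datasets]).astype(float)
    ipp = getattr(ds0, "ImagePositionPatient", [0.0, 0.0, zs[0]])
    origin = (float(zs[0]), float(ipp[1]), float(ipp[0]))
    spacing = (slice_spacing, float(ps[0]), float(ps[1]))

    if bits == 8 and slope == 1.0 and intercept == 0.0:
        return Volume(frames.astype(np.uint8), spacing, "gray8", origin)
    return Volume(frames * slope + intercept, spacing, "HU", origin)


def write_dicom_series(v: Volume, directory) -> list[Path]:
    """Write a Volume as a single-frame DICOM series (one file per slice)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    gray8 = v.intensity_kind == "gray8"
    paths = []
    for i in range(v.shape[0]):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [v.origin[2], v.origin[1], v.origin[0] + i * v.spacing[0]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceThickness = v.spacing[0]
        ds.PixelSpacing = [v.spacing[1], v.spacing[2]]
        ds.Rows, ds.Columns = v.shape[1], v.shape[2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        if gray8:
            ds.BitsAllocated = ds.BitsStored = 8
            ds.HighBit = 7
            ds.PixelRepresentation = 0
            ds.PixelData = np.ascontiguousarray(v.voxels[i], dtype=np.uint8).tobytes()
        else:
            ds.BitsAllocated = ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 1
            ds.RescaleSlope = 1.0
            ds.RescaleIntercept = 0.0
            ds.PixelData = np.ascontiguousarray(
                round_half_up(v.voxels[i]), dtype=np.int16
            ).tobytes()
        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Raw array + JSON sidecar fallback (no DICOM machinery required)
# ---------------------------------------------------------------------------


def write_raw_volume(v: Volume, basepath) -> tuple[Path, Path]:
    """Write voxels as .npy plus a JSON sidecar with geometry metadata."""
    basepath = Path(basepath)
    npy = basepath.with_suffix(".npy")
    meta = basepath.with_suffix(".json")
    np.save(npy, v.voxels)
    meta.write_text(
        json.dumps(
            {
                "shape": list(v.shape),
                "spacing_mm": list(v.spacing),
                "intensity_kind": v.intensity_kind,
                "origin_mm": list(v.origin),
                "coordinate_convention": "zyx0",
            },
            indent=2,
        )
    )
    return npy, meta


def read_raw_volume(basepath) -> Volume:
    basepath = Path(basepath)
    meta = json.loads(basepath.with_suffix(".json").read_text())
    voxels = np.load(basepath.with_suffix(".npy"))
    return Volume(
        voxels,
        tuple(meta["spacing_mm"]),
        meta["intensity_kind"],
        tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))),
    )


def export_png(image2d: np.ndarray, path) -> None:
    """Export a 2D gray image (0..255) as PNG for visual QC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(str(path), np.asarray(image2d, dtype=float), cmap="gray", vmin=0, vmax=255)
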