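"""DICOM CT ingestion, Hounsfield-unit windowing and the PNG slice store.

A CT series is read into a calibrated :class:`HUVolume` (rescale slope and
intercept applied, slices sorted by along-axis position). Windowing maps an
HU interval, defined by a window center ``w_c`` and width ``w_l``, linearly
onto an integer output range via the DICOM linear VOI convention

    y = ((x - (w_c - 0.5)) / (w_l - 1) + 0.5) * (y_max - y_min) + y_min

with values outside the window clamped to ``y_min`` / ``y_max`` and the
result rounded to the nearest integer, half away from zero. The defaults
(center 50 HU, width 400 HU, 16-bit output) give good soft-tissue contrast
in portal-venous abdominal CT.

Windowed slices are stored as 16-bit grayscale PNGs, organ masks as 8-bit
{0, 255} PNGs, and each converted scan carries a JSON manifest listing the
slice files in order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pydicom
from PIL import Image


class NoInputError(ValueError):
    """Empty directory or slice list."""


class MixedSeriesError(ValueError):
    """A directory contained files from more than one DICOM series."""


class GeometryError(ValueError):
    """Slices of one series disagree on shape or geometry."""


class DataError(ValueError):
    """Non-finite or otherwise invalid pixel data."""


class FormatError(ValueError):
    """Unsupported image bit depth or PNG dialect."""


class MaskDialectError(FormatError):
    """A mask PNG contained values other than {0, 255}."""


class OverwriteError(FileExistsError):
    """Refusing to overwrite an existing converted scan."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HUVolume:
    """Ordered stack of calibrated HU slices with acquisition metadata."""

    slices: np.ndarray  # (n_slices, rows, cols) float HU
    pixel_spacing: Tuple[float, float] = (1.0, 1.0)  # mm (row, col)
    slice_thickness: float = 1.0  # mm
    patient_id: str = "anon"
    phase: str = ""

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError("volume must be (n_slices>=1, rows, cols)")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """HU windowing parameters: center, width and integer output range."""

    center: float = 50.0
    width: float = 400.0
    y_min: int = 0
    y_max: int = 65535

    def __post_init__(self):
        if self.width <= 1:
            raise ValueError("window width must exceed 1 HU")
        if self.y_max <= self.y_min:
            raise ValueError("y_max must exceed y_min")

    @property
    def bit_depth(self) -> int:
        return 16 if self.y_max > 255 else 8

    @classmethod
    def for_bits(cls, bits: int, center: float = 50.0, width: float = 400.0) -> "WindowSpec":
        if bits == 16:
            return cls(center, width, 0, 65535)
        if bits == 8:
            return cls(center, width, 0, 255)
        raise FormatError(f"unsupported bit depth: {bits}")


@dataclass
class SliceImage:
    """Windowed slice intensities as unsigned integers in [y_min, y_max]."""

    pixels: np.ndarray
    bit_depth: int = 16

    def __post_init__(self):
        if self.bit_depth not in (8, 16):
            raise FormatError(f"unsupported bit depth: {self.bit_depth}")
        dtype = np.uint16 if self.bit_depth == 16 else np.uint8
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise ValueError("slice image must be 2-D")
        self.pixels = p.astype(dtype)


@dataclass
class MaskImage:
    """Binary per-pixel annotation for one slice."""

    pixels: np.ndarray
    label: str = "pancreas"

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.pixels = p.astype(bool)

    @property
    def empty(self) -> bool:
        return not self.pixels.any()


# ---------------------------------------------------------------------------
# DICOM reading
# ---------------------------------------------------------------------------

def _slice_position(ds) -> float:
    """Signed distance of a slice along the stack normal."""
    try:
        iop = np.array(ds.ImageOrientationPatient, dtype=float)
        ipp = np.array(ds.ImagePositionPatient, dtype=float)
        normal = np.cross(iop[:3], iop[3:])
        return float(np.dot(normal, ipp))
    except (AttributeError, TypeError, ValueError):
        return float("nan")


def read_dicom_series(directory) -> HUVolume:
    """Read one DICOM series into a calibrated, position-sorted HU volume.

    Stored values are converted to HU with the per-file rescale slope and
    intercept. Slices are ordered by ascending position along the stack
    normal; files without position information fall back to instance-number
    ordering.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(p))
        except Exception:
            continue  # non-DICOM files in the directory are ignored
    if not datasets:
        raise NoInputError(f"no DICOM files in {directory}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise MixedSeriesError(
            f"directory {directory} mixes {len(uids)} series: {sorted(uids)}"
        )

    shapes = {ds.pixel_array.shape for ds in datasets}
    if len(shapes) > 1:
        raise GeometryError(f"inconsistent slice shapes: {sorted(shapes)}")

    positions = [_slice_position(ds) for ds in datasets]
    if any(np.isnan(positions)):
        keys = [float(getattr(ds, "InstanceNumber", i)) for i, ds in enumerate(datasets)]
    else:
        keys = positions
    order = np.argsort(keys, kind="stable")
    datasets = [datasets[i] for i in order]

    hu = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu.append(ds.pixel_array.astype(np.float64) * slope + intercept)

    first = datasets[0]
    spacing = tuple(float(v) for v in getattr(first, "PixelSpacing", (1.0, 1.0)))
    return HUVolume(
        slices=np.stack(hu),
        pixel_spacing=spacing,  # type: ignore[arg-type]
        slice_thickness=float(getattr(first, "SliceThickness", 1.0)),
        patient_id=str(getattr(first, "PatientID", "anon")),
        phase=str(getattr(first, "SeriesDescription", "")),
    )


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def _round_half_away(y: np.ndarray) -> np.ndarray:
    return np.where(y >= 0, np.floor(y + 0.5), np.ceil(y - 0.5))


def apply_window(hu_slice: np.ndarray, spec: WindowSpec = WindowSpec()) -> SliceImage:
    """Map an HU slice through the linear window defined by ``spec``."""
    x = np.asarray(hu_slice, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite HU values in input slice")
    wc, wl = spec.center, spec.width
    span = spec.y_max - spec.y_min
    y = ((x - (wc - 0.5)) / (wl - 1.0) + 0.5) * span + spec.y_min
    lower = wc - 0.5 - (wl - 1.0) / 2.0
    upper = wc - 0.5 + (wl - 1.0) / 2.0
    y = np.where(x <= lower, spec.y_min, np.where(x >= upper, spec.y_max, y))
    y = np.clip(_round_half_away(y), spec.y_min, spec.y_max)
    return SliceImage(pixels=y, bit_depth=spec.bit_depth)


# ---------------------------------------------------------------------------
# PNG store
# ---------------------------------------------------------------------------

def write_png(image, path) -> None:
    """Write a :class:`SliceImage` or :class:`MaskImage` losslessly as PNG."""
    path = Path(path)
    if isinstance(image, MaskImage):
        arr = np.where(image.pixels, 255, 0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path, format="PNG")
    elif isinstance(image, SliceImage):
        if image.bit_depth == 16:
            Image.fromarray(image.pixels.astype("<u2")).save(path, format="PNG")
        else:
            Image.fromarray(image.pixels.astype(np.uint8), mode="L").save(path, format="PNG")
    else:
        raise FormatError(f"cannot write object of type {type(image).__name__}")


def read_png(path, *, mask: bool = False, label: str = "pancreas"):
    """Read a PNG written by :func:`write_png`.

    With ``mask=True`` the file must be an 8-bit image with values only in
    {0, 255}; anything else raises :class:`MaskDialectError`.
    """
    arr = np.asarray(Image.open(Path(path)))
    if mask:
        if not np.isin(arr, (0, 255)).all():
            raise MaskDialectError(f"{path}: mask values outside {{0, 255}}")
        return MaskImage(pixels=arr == 255, label=label)
    if arr.dtype == np.uint8:
        return SliceImage(pixels=arr, bit_depth=8)
    if arr.dtype in (np.uint16, np.int32):
        a = arr.astype(np.int64)
        if a.min() < 0 or a.max() > 65535:
            raise FormatError(f"{path}: values outside 16-bit range")
        return SliceImage(pixels=a.astype(np.uint16), bit_depth=16)
    raise FormatError(f"{path}: unsupported PNG dtype {arr.dtype}")


# ---------------------------------------------------------------------------
# Conversion pipeline
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"


def _slice_name(patient_id: str, index: int) -> str:
    return f"{patient_id}_{index:04d}.png"


def convert_volume(volume: HUVolume, spec: WindowSpec, out_dir,
                   masks: Optional[Sequence[np.ndarray]] = None,
                   source: str = "local", force: bool = False) -> dict:
    """Window every axial slice to PNG and write a JSON manifest.

    File names are ``<patientID>_<sliceIndex>.png`` with 0-based, 4-digit
    zero-padded indices; masks (if given) go to ``<name>_mask.png``. The
    returned manifest dict is also written to ``out_dir/manifest.json``.
    An existing manifest in ``out_dir`` aborts the conversion unless
    ``force=True``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / MANIFEST_NAME
    if manifest_path.exists() and not force:
        raise OverwriteError(f"{manifest_path} exists; pass force=True to overwrite")
    if masks is not None and len(masks) != volume.n_slices:
        raise GeometryError("mask count does not match slice count")

    entries = []
    for i in range(volume.n_slices):
        img = apply_window(volume.slices[i], spec)
        name = _slice_name(volume.patient_id, i)
        write_png(img, out_dir / name)
        entry = {"index": i, "image": name, "mask": None}
        if masks is not None:
            mask_name = name.replace(".png", "_mask.png")
            write_png(MaskImage(pixels=np.asarray(masks[i], dtype=bool)), out_dir / mask_name)
            entry["mask"] = mask_name
        entries.append(entry)

    manifest = {
        "patient_id": volume.patient_id,
        "source": source,
        "phase": volume.phase,
        "pixel_spacing": list(volume.pixel_spacing),
        "slice_thickness": volume.slice_thickness,
        "window": {"center": spec.center, "width": spec.width,
                   "y_min": spec.y_min, "y_max": spec.y_max},
        "slices": entries,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    manifest["_dir"] = str(out_dir)
    return manifest


def load_manifest(path) -> dict:
    """Load a scan manifest; ``path`` may be the JSON file or its directory."""
    path = Path(path)
    if path.is_dir():
        path = path / MANIFEST_NAME
    manifest = json.loads(path.read_text())
    manifest["_dir"] = str(path.parent)
    return manifest


def manifest_slice_arrays(manifest: dict):
    """Yield (index, image array, mask array or None) in slice order."""
    base = Path(manifest["_dir"])
    for entry in manifest["slices"]:
        img = read_png(base / entry["image"]).pixels
        mask = None
        if entry.get("mask"):
            mask = read_png(base / entry["mask"], mask=True).pixels
        yield entry["index"], img, mask
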