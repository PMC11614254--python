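"""Deterministic CT-like phantom volumes with pancreas-like ground truth.

Real abdominal CT of the pancreas is hard to segment because neighbouring
soft-tissue organs have similar attenuation. The phantom emulates exactly
that regime without any data download: a body ellipse of soft tissue
(~55 HU) surrounded by air (-1000 HU), one elongated target blob at a
slightly higher attenuation (~90 HU) present on a contiguous central run of
slices, and optional distractor blobs whose mean HU lies within +/-15 HU of
the target. Gaussian noise is added everywhere. The ground-truth mask is
true exactly on target-blob pixels, and identical seeds give bit-identical
volumes.

The target blob is an axis-rotated super-ellipse whose cross-sectional area
tapers from head to tail slice, a crude but sufficient stand-in for the
pancreas' head-body-tail profile. Distractors never overlap the target, so
the ground truth stays unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .dicom_io import HUVolume, WindowSpec, convert_volume

AIR_HU = -1000.0


@dataclass(frozen=True)
class PhantomConfig:
    n_slices: int = 16
    size: int = 64  # pixels per side; must be divisible by 32
    seed: int = 0
    organ_hu: float = 90.0
    background_hu: float = 55.0
    noise_sd: float = 10.0
    organ_present: bool = True
    distractor_count: int = 2

    def __post_init__(self):
        if self.size % 32:
            raise ValueError("size must be divisible by 32 for model compatibility")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


def _super_ellipse(size: int, center, a: float, b: float, theta: float,
                   exponent: float = 2.5) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    return (np.abs(u / a) ** exponent + np.abs(v / b) ** exponent) <= 1.0


def _body_ellipse(size: int) -> np.ndarray:
    c = (size - 1) / 2.0
    return _super_ellipse(size, (c, c), 0.44 * size, 0.38 * size, 0.0, exponent=2.0)


def generate_phantom(config: PhantomConfig) -> Tuple[HUVolume, np.ndarray]:
    """Generate one phantom scan; returns (HU volume, boolean mask volume)."""
    rng = np.random.default_rng(config.seed)
    size, n = config.size, config.n_slices
    body = _body_ellipse(size)
    c = (size - 1) / 2.0

    hu = np.full((n, size, size), AIR_HU)
    hu[:, body] = config.background_hu
    masks = np.zeros((n, size, size), dtype=bool)

    # contiguous central run of organ-bearing slices (about half the stack)
    run = max(1, n // 2)
    start = (n - run) // 2
    organ_slices = range(start, start + run)

    # target geometry, fixed per scan with mild jitter
    theta = rng.uniform(-np.pi / 5, np.pi / 5)
    a0 = 0.20 * size * rng.uniform(0.9, 1.1)  # long semi-axis
    b0 = 0.08 * size * rng.uniform(0.9, 1.1)
    center0 = (c + rng.uniform(-0.05, 0.05) * size,
               c + rng.uniform(-0.05, 0.05) * size)

    if config.organ_present:
        for j, k in enumerate(organ_slices):
            # taper cross-section from head (1.0) to tail (0.4)
            frac = j / max(run - 1, 1)
            scale = np.sqrt(1.0 - 0.6 * frac)
            blob = _super_ellipse(size, center0, a0 * scale, b0 * scale, theta)
            blob &= body  # mask stays inside the body
            masks[k] = blob
            hu[k][blob] = config.organ_hu

    # distractor blobs: similar HU, never overlapping the target mask
    for _ in range(config.distractor_count):
        d_hu = config.organ_hu + rng.uniform(-15.0, 15.0)
        for _attempt in range(20):
            dc = (c + rng.uniform(-0.22, 0.22) * size,
                  c + rng.uniform(-0.22, 0.22) * size)
            da = rng.uniform(0.04, 0.09) * size
            db = rng.uniform(0.04, 0.09) * size
            dth = rng.uniform(0, np.pi)
            blob = _super_ellipse(size, dc, da, db, dth, exponent=2.0) & body
            if not (blob & masks).any():
                hu[:, blob] = d_hu
                break

    if config.noise_sd > 0:
        hu += rng.normal(0.0, config.noise_sd, size=hu.shape)

    volume = HUVolume(
        slices=hu,
        pixel_spacing=(0.8, 0.8),
        slice_thickness=2.0,
        patient_id=f"phantom{config.seed:05d}",
        phase="portal venous",
    )
    return volume, masks


def _child_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def absent_indices(n_scans: int, fraction_absent: float) -> set:
    """Deterministic assignment of organ-absent scans: round(frac*n) scans
    at evenly spaced indices."""
    k = int(round(fraction_absent * n_scans))
    if k <= 0:
        return set()
    return {int(round(i * n_scans / k)) % n_scans for i in range(k)}


def generate_dataset(n_scans: int, template: PhantomConfig, seed: int,
                     out_dir, fraction_absent: float = 0.0,
                     spec: WindowSpec = WindowSpec(), force: bool = False) -> List[dict]:
    """Generate ``n_scans`` phantoms and convert them to the PNG store.

    Per-scan seeds are derived deterministically from ``seed``; a
    ``fraction_absent`` share of scans (rounded, evenly spaced) is generated
    with no target organ. Returns the list of per-scan manifests.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    out_dir = Path(out_dir)
    absent = absent_indices(n_scans, fraction_absent)
    manifests = []
    for i in range(n_scans):
        cfg = replace(template, seed=_child_seed(seed, i),
                      organ_present=(i not in absent) and template.organ_present)
        volume, masks = generate_phantom(cfg)
        volume.patient_id = f"phantom{seed:05d}_{i:03d}"
        manifest = convert_volume(volume, spec, out_dir / volume.patient_id,
                                  masks=list(masks), source="phantom", force=force)
        manifests.append(manifest)
    return manifests


# ---------------------------------------------------------------------------
# Synthetic DICOM fixtures (for exercising the DICOM reader without data)
# ---------------------------------------------------------------------------

def write_synthetic_dicom_series(volume: HUVolume, out_dir,
                                 slope: float = 1.0, intercept: float = -1024.0,
                                 series_uid: Optional[str] = None,
                                 instance_numbers: Optional[List[int]] = None,
                                 shuffle_files: bool = False) -> List[Path]:
    """Write an HU volume as a minimal single-series DICOM directory.

    Stored values are ``(HU - intercept) / slope`` rounded to uint16, so the
    reader recovers HU to within rescale quantisation. ``instance_numbers``
    and ``shuffle_files`` let tests scramble on-disk order to exercise
    position sorting.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    n = volume.n_slices
    numbers = instance_numbers or list(range(1, n + 1))
    order = list(range(n))
    if shuffle_files:
        order = order[::-1]

    paths = []
    for file_idx, i in enumerate(order):
        stored = np.clip(
            np.round((volume.slices[i] - intercept) / slope), 0, 65535
        ).astype(np.uint16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientID = volume.patient_id
        ds.SeriesDescription = volume.phase
        ds.InstanceNumber = numbers[i]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * volume.slice_thickness]
        ds.PixelSpacing = [volume.pixel_spacing[0], volume.pixel_spacing[1]]
        ds.SliceThickness = volume.slice_thickness
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored.tobytes()
        path = out_dir / f"slice_{file_idx:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
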