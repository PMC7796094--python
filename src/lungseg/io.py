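"""Reading CT slices, writing masks, and dataset splitting.

CT slices arrive as single-frame DICOM files whose stored integers must be
rescaled to Hounsfield units (HU) through the ``RescaleSlope`` /
``RescaleIntercept`` tags. Binary lung masks are exchanged as 8-bit BMP or
PNG rasters with lung = 255 and background = 0; internally lung = 1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from PIL import Image

HU_MIN = -2000.0
HU_MAX = 4000.0

MASK_FORMATS = ("bmp", "png")


@dataclass
class CTSlice:
    """A 2-D HU-calibrated CT slice with identity metadata."""

    pixels: np.ndarray
    patient_id: str = ""
    slice_id: str = ""
    source: str = "dicom"  # "dicom" or "phantom"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("CTSlice.pixels must be a non-empty 2-D array")
        if self.source not in ("dicom", "phantom"):
            raise ValueError(f"unknown source {self.source!r}")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(
                f"HU values [{lo:.1f}, {hi:.1f}] outside plausible range "
                f"[{HU_MIN:.0f}, {HU_MAX:.0f}]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def read_dicom_slice(path: str | os.PathLike) -> CTSlice:
    """Read a single-frame CT DICOM file and rescale stored values to HU.

    HU = stored_value * RescaleSlope + RescaleIntercept. Both rescale tags
    must be present; a missing tag raises rather than silently assuming a
    default calibration.
    """
    ds = pydicom.dcmread(path)
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames != 1:
        raise ValueError(
            f"{path}: multi-frame DICOM ({n_frames} frames) is not supported; "
            "expected one slice per file"
        )
    for tag in ("RescaleSlope", "RescaleIntercept"):
        if getattr(ds, tag, None) is None:
            raise ValueError(f"{path}: missing required DICOM tag {tag}")
    stored = ds.pixel_array.astype(np.float64)
    hu = stored * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
    return CTSlice(
        pixels=hu.astype(np.float32),
        patient_id=str(getattr(ds, "PatientID", "")),
        slice_id=str(getattr(ds, "SOPInstanceUID", "")),
        source="dicom",
    )


def write_dicom_slice(
    ct: CTSlice,
    path: str | os.PathLike,
    slope: float = 1.0,
    intercept: float = -1024.0,
) -> None:
    """Write a minimal single-frame CT DICOM file (fixture-grade writer).

    Stores ``round((HU - intercept) / slope)`` as signed 16-bit integers, so
    HU grids that are integral on that grid round-trip exactly. Not intended
    for clinical interchange.
    """
    stored = np.rint((ct.pixels.astype(np.float64) - intercept) / slope)
    if stored.min() < -32768 or stored.max() > 32767:
        raise ValueError("rescaled stored values overflow int16")
    stored = stored.astype(np.int16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientID = ct.patient_id
    if ct.slice_id:
        ds.SeriesDescription = ct.slice_id
    ds.Modality = "CT"
    ds.Rows, ds.Columns = ct.pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _as_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask values must be exactly 0 or 1")
    return arr.astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a {0,1} mask as an 8-bit raster, lung (1) -> 255."""
    arr = _as_binary(mask)
    if format is None:
        format = os.path.splitext(str(path))[1].lstrip(".").lower() or "png"
    format = format.lower()
    if format not in MASK_FORMATS:
        raise ValueError(f"unsupported mask format {format!r}; use one of {MASK_FORMATS}")
    Image.fromarray(arr * np.uint8(255), mode="L").save(path, format=format.upper())


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit mask raster back to a {0,1} array (foreground = >=128)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr >= 128).astype(np.uint8)


@dataclass
class DatasetSplit:
    """A deterministic train/val/test partition of sample identifiers."""

    train_ids: list = field(default_factory=list)
    val_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)
    seed: int = 0
    fractions: tuple = (0.7, 0.15, 0.15)

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split partitions must be pairwise disjoint")


def split_dataset(ids, fractions=(0.7, 0.15, 0.15), seed: int = 0) -> DatasetSplit:
    """Randomly partition ``ids`` into train/val/test.

    Partition sizes are ``round(n * f)`` per fraction with any remainder
    assigned to the training set (1714 ids at 70/15/15 gives 1200/257/257).
    The permutation is driven solely by ``seed``.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative reals")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    n = len(ids)
    n_train = int(round(n * fractions[0]))
    n_val = int(round(n * fractions[1]))
    n_test = int(round(n * fractions[2]))
    n_train += n - (n_train + n_val + n_test)  # remainder to train
    if n_train < 0:
        raise ValueError("rounding produced a negative training size")

    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in perm]
    return DatasetSplit(
        train_ids=shuffled[:n_train],
        val_ids=shuffled[n_train : n_train + n_val],
        test_ids=shuffled[n_train + n_val :],
        seed=seed,
        fractions=fractions,
    )
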