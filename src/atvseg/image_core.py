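"""Domain types for CT volumes and organ masks, with file I/O.

Conventions used throughout the package:

* pixel values are Hounsfield units stored as float64 (the denoiser
  produces non-integer values even though CT files store integers);
* in-plane coordinates are (x, y) = (column, row), 0-based, pixel centres;
* slices are ordered by ascending through-plane position.

Volumes are exchanged as single-frame DICOM CT series (via pydicom);
masks as NIfTI rasters with a JSON sidecar carrying the organ label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = [
    "ImageSlice",
    "ImageVolume",
    "BinaryMask",
    "read_ct_series",
    "write_ct_series",
    "read_mask",
    "write_mask",
]

#: SOP class of a single-frame CT image object.
_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"


@dataclass
class ImageSlice:
    """One axial CT slice: HU pixels plus in-plane geometry.

    ``pixels`` is indexed [row, column] = [y, x]; ``spacing`` is (dx, dy)
    in mm along columns and rows respectively.
    """

    pixels: np.ndarray
    spacing: tuple[float, float]
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        dx, dy = self.spacing
        if dx <= 0 or dy <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.spacing = (float(dx), float(dy))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageVolume:
    """Ordered stack of slices sharing shape and spacing."""

    slices: list[ImageSlice]
    slice_thickness: float = 3.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("a volume needs at least one slice")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        first = self.slices[0]
        for sl in self.slices[1:]:
            if sl.shape != first.shape:
                raise ValueError(
                    f"slice shapes differ: {first.shape} vs {sl.shape}"
                )
            if sl.spacing != first.spacing:
                raise ValueError(
                    f"slice spacings differ: {first.spacing} vs {sl.spacing}"
                )
        indices = [sl.slice_index for sl in self.slices]
        expected = list(range(indices[0], indices[0] + len(indices)))
        if indices != expected:
            raise ValueError(f"slice_index values must be consecutive, got {indices}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx)."""
        ny, nx = self.slices[0].shape
        return (len(self.slices), ny, nx)

    @property
    def spacing(self) -> tuple[float, float]:
        return self.slices[0].spacing

    def to_array(self) -> np.ndarray:
        """Stack pixels into a (nz, ny, nx) float64 array."""
        return np.stack([sl.pixels for sl in self.slices])

    @classmethod
    def from_array(
        cls,
        voxels: np.ndarray,
        spacing: tuple[float, float] = (1.0, 1.0),
        slice_thickness: float = 3.0,
        metadata: dict | None = None,
    ) -> "ImageVolume":
        """Build a volume from a (nz, ny, nx) array of HU values."""
        voxels = np.asarray(voxels, dtype=np.float64)
        if voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {voxels.shape}")
        slices = [
            ImageSlice(pixels=voxels[k], spacing=spacing, slice_index=k)
            for k in range(voxels.shape[0])
        ]
        return cls(slices=slices, slice_thickness=slice_thickness,
                   metadata=metadata or {})


@dataclass
class BinaryMask:
    """Per-organ boolean volume congruent with an ImageVolume."""

    voxels: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask voxels must be 3D, got shape {self.voxels.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def volume_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_congruent(self, other) -> None:
        """Raise if geometry differs from another mask or volume."""
        if self.shape != other.shape:
            raise ValueError(
                f"geometry mismatch: mask {self.label!r} has shape {self.shape}, "
                f"reference has shape {other.shape}"
            )


# --------------------------------------------------------------------------
# DICOM CT series I/O
# --------------------------------------------------------------------------

def write_ct_series(volume: ImageVolume, path: str | Path) -> list[Path]:
    """Write a volume as one single-frame CT DICOM file per slice.

    HU values are rounded to integers and stored as unsigned 16-bit with
    rescale intercept -1024 and slope 1, so re-reading returns the HU grid
    up to that integer quantisation.  Raises before writing anything if an
    HU value is not representable.
    """
    arr = volume.to_array()
    stored = np.round(arr) + 1024.0
    if stored.min() < 0 or stored.max() > 65535:
        raise ValueError(
            f"HU range [{arr.min():.1f}, {arr.max():.1f}] not representable "
            "with intercept -1024 in unsigned 16-bit storage"
        )
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    series_uid = generate_uid()
    study_uid = generate_uid()
    dx, dy = volume.spacing
    written: list[Path] = []
    for k, sl in enumerate(volume.slices):
        ds = Dataset()
        ds.SOPClassUID = _CT_SOP_CLASS
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = volume.metadata.get("patient_name", "phantom")
        ds.PatientID = volume.metadata.get("patient_id", "phantom")
        if "kvp" in volume.metadata:
            ds.KVP = volume.metadata["kvp"]
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(k) * volume.slice_thickness]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        # DICOM PixelSpacing is (row spacing, column spacing) = (dy, dx)
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = volume.slice_thickness
        ds.RescaleIntercept = -1024.0
        ds.RescaleSlope = 1.0
        ds.Rows, ds.Columns = sl.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored[k].astype(np.uint16).tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta

        out = path / f"ct_{k:04d}.dcm"
        ds.save_as(out, enforce_file_format=True)
        written.append(out)
    return written


def read_ct_series(path: str | Path) -> ImageVolume:
    """Read a directory of single-frame CT files into an ImageVolume.

    Slices are sorted by through-plane position regardless of file names;
    stored values are converted to HU via the rescale slope/intercept of
    each file.  Mixed series, inconsistent matrix sizes and missing rescale
    tags all raise.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix != ".json")
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        if getattr(ds, "Modality", "CT") != "CT":
            continue
        datasets.append(ds)
    if not datasets:
        raise ValueError(f"no CT image files found in {path}")

    series = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series) > 1:
        raise ValueError(
            f"directory {path} mixes multiple series: {sorted(map(str, series))}"
        )

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent in-plane shapes within series: {sorted(shapes)}")

    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(
                "missing RescaleSlope/RescaleIntercept tag; refusing to guess HU scaling"
            )

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))

    slices = []
    for k, ds in enumerate(datasets):
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        dy, dx = (float(v) for v in ds.PixelSpacing)
        slices.append(ImageSlice(pixels=hu, spacing=(dx, dy), slice_index=k))

    thickness = float(getattr(datasets[0], "SliceThickness", 3.0))
    metadata = {}
    if "KVP" in datasets[0]:
        metadata["kvp"] = float(datasets[0].KVP)
    return ImageVolume(slices=slices, slice_thickness=thickness, metadata=metadata)


# --------------------------------------------------------------------------
# Mask I/O (NIfTI raster + JSON sidecar for the label)
# --------------------------------------------------------------------------

def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a mask as a uint8 NIfTI file with a JSON label sidecar."""
    path = Path(path)
    if path.suffix != ".nii" and not path.name.endswith(".nii.gz"):
        path = path.with_suffix(".nii")
    path.parent.mkdir(parents=True, exist_ok=True)
    # store as (nx, ny, nz) — NIfTI's fastest-varying axis is x
    data = np.asarray(mask.voxels, dtype=np.uint8).transpose(2, 1, 0)
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    sidecar = path.parent / (path.name.split(".")[0] + ".json")
    sidecar.write_text(json.dumps({"label": mask.label, "shape": list(mask.shape)}))
    return path


def read_mask(path: str | Path, geometry: ImageVolume | None = None) -> BinaryMask:
    """Read a mask raster; optionally check congruence with a volume."""
    path = Path(path)
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj).transpose(2, 1, 0).astype(bool)
    sidecar = path.parent / (path.name.split(".")[0] + ".json")
    label = "mask"
    if sidecar.exists():
        label = json.loads(sidecar.read_text()).get("label", "mask")
    mask = BinaryMask(voxels=voxels, label=label)
    if geometry is not None and mask.shape != geometry.shape:
        raise ValueError(
            f"geometry mismatch: mask file {path} has shape {mask.shape}, "
            f"reference volume has shape {geometry.shape}"
        )
    return mask
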