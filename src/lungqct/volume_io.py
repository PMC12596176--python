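"""CT volume and metadata I/O.

The in-memory unit for every stage of the pipeline is :class:`VoxelVolume`:
a 3-D array of Hounsfield Units with physical spacing and origin.  The axis
convention is fixed throughout the package:

* axis 0 = x, left-right
* axis 1 = y, anterior-posterior
* axis 2 = z, cranio-caudal

Voxel indices are 0-based and world coordinates are millimetres at voxel
centers, so voxel ``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``.

Two file formats are supported: NIfTI (single file, via nibabel) and DICOM
series (one file per slice, via pydicom).  HU calibration on DICOM read is
mandatory: slices without rescale slope/intercept are rejected rather than
silently mis-scaled.  The slice interval is taken from inter-slice position
differences, not the slice-thickness tag, because quantitative chest
reconstructions routinely use overlapping slices (e.g. 0.75 mm thickness on
a 0.5 mm grid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import nibabel as nib
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = [
    "VoxelVolume",
    "ProtocolMeta",
    "read_volume",
    "write_volume",
    "read_dicom_series",
    "write_dicom_series",
]


@dataclass
class VoxelVolume:
    """A 3-D HU grid with physical geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Hounsfield Units, finite.
    spacing : tuple of float
        Voxel pitch in mm along (x, y, z); strictly positive.
    origin : tuple of float
        World position (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        if self.voxels.shape[2] < 1:
            raise ValueError("volume must contain at least one slice")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal; axes never permuted)."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class ProtocolMeta:
    """Scalar acquisition/reconstruction metadata for one protocol."""

    scanner_label: str = ""
    recon_label: str = ""
    ctdi_vol: float = float("nan")
    scan_length: float = 30.0
    kvp: str = ""
    rotation_time: str = ""
    pitch: str = ""

    def __post_init__(self) -> None:
        if self.scan_length <= 0:
            raise ValueError("scan_length must be positive")
        if not np.isnan(self.ctdi_vol) and self.ctdi_vol <= 0:
            raise ValueError("ctdi_vol must be positive when provided")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProtocolMeta":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# NIfTI


def write_volume(vol: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii or .nii.gz); returns the path."""
    path = Path(path)
    if path.suffix not in (".nii", ".gz"):
        raise ValueError(f"unsupported volume format: {path.name} (use .nii/.nii.gz)")
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), vol.affine())
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a NIfTI volume written by :func:`write_volume`."""
    path = Path(path)
    if path.suffix not in (".nii", ".gz"):
        raise ValueError(f"unsupported volume format: {path.name} (use .nii/.nii.gz)")
    img = nib.load(str(path))
    aff = img.affine
    off = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if np.abs(off).max() > 1e-6:
        raise ValueError("non-diagonal affine: volume axes are rotated/permuted")
    spacing = tuple(np.diag(aff[:3, :3]))
    if any(s <= 0 for s in spacing):
        raise ValueError("negative affine diagonal: unsupported axis flip")
    return VoxelVolume(
        np.asanyarray(img.dataobj).astype(np.float64),
        spacing=spacing,
        origin=tuple(aff[:3, 3]),
    )


# ---------------------------------------------------------------------------
# DICOM series

_INTERCEPT_DEFAULT = -1024.0


def write_dicom_series(
    vol: VoxelVolume,
    directory: str | Path,
    meta: ProtocolMeta | None = None,
) -> list[Path]:
    """Write one CT slice per file using the slope-1 / intercept -1024 convention.

    Stored pixel values are uint16 ``HU + 1024`` clipped to [0, 65535]; reading
    back therefore round-trips any HU in [-1024, 64511] exactly for integral
    HU and to <1 HU for fractional values (values are rounded to integers, the
    DICOM CT storage granularity).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    paths = []
    stored = np.round(vol.voxels - _INTERCEPT_DEFAULT).clip(0, 65535).astype(np.uint16)
    for k in range(vol.shape[2]):
        ds = Dataset()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            vol.origin[0],
            vol.origin[1],
            vol.origin[2] + k * vol.spacing[2],
        ]
        ds.SliceThickness = vol.spacing[2]
        ds.PixelSpacing = [vol.spacing[1], vol.spacing[0]]  # row (y), col (x)
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = _INTERCEPT_DEFAULT
        ds.Rows = vol.shape[1]
        ds.Columns = vol.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        if meta is not None:
            ds.StationName = meta.scanner_label[:16]
            ds.ConvolutionKernel = meta.recon_label[:16]
            if not np.isnan(meta.ctdi_vol):
                ds.CTDIvol = meta.ctdi_vol
        # pixel array is (Rows, Cols) = (y, x)
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        fmeta = FileMetaDataset()
        fmeta.TransferSyntaxUID = ExplicitVRLittleEndian
        fmeta.MediaStorageSOPClassUID = ds.SOPClassUID
        fmeta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        ds.file_meta = fmeta
        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    if meta is not None:
        meta.to_json(directory / "protocol_meta.json")
    return paths


def read_dicom_series(directory: str | Path) -> tuple[VoxelVolume, ProtocolMeta]:
    """Read one CT series (one file per slice) into a volume plus metadata.

    Slices are sorted by position along the slice normal regardless of file
    names; mixed series or inconsistent geometry are rejected with the
    offending attribute named.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise ValueError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(str(p)) for p in files]

    def _require_consistent(attr):
        vals = {tuple(np.atleast_1d(getattr(s, attr))) for s in slices}
        if len(vals) > 1:
            raise ValueError(f"inconsistent {attr} across series")

    for attr in ("SeriesInstanceUID", "Rows", "Columns", "PixelSpacing",
                 "ImageOrientationPatient"):
        _require_consistent(attr)
    for s in slices:
        if "RescaleSlope" not in s or "RescaleIntercept" not in s:
            raise ValueError(
                "missing RescaleSlope/RescaleIntercept: HU calibration is mandatory"
            )
    orient = np.array(slices[0].ImageOrientationPatient, dtype=float)
    normal = np.cross(orient[:3], orient[3:])
    pos = np.array([s.ImagePositionPatient for s in slices], dtype=float)
    along = pos @ normal
    order = np.argsort(along)
    slices = [slices[i] for i in order]
    along = along[order]
    if len(slices) > 1:
        steps = np.diff(along)
        if steps.min() <= 0:
            raise ValueError("duplicate ImagePositionPatient: not a single series stack")
        if np.ptp(steps) > 1e-3:
            raise ValueError("inconsistent slice interval (ImagePositionPatient)")
        dz = float(steps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    row_sp, col_sp = (float(v) for v in slices[0].PixelSpacing)
    data = np.stack(
        [
            s.pixel_array.astype(np.float64) * float(s.RescaleSlope)
            + float(s.RescaleIntercept)
            for s in slices
        ],
        axis=-1,
    )  # (y, x, z)
    voxels = np.ascontiguousarray(np.transpose(data, (1, 0, 2)))  # (x, y, z)
    origin = tuple(np.array(slices[0].ImagePositionPatient, dtype=float))
    vol = VoxelVolume(voxels, spacing=(col_sp, row_sp, dz), origin=origin)

    sidecar = directory / "protocol_meta.json"
    if sidecar.exists():
        meta = ProtocolMeta.from_json(sidecar)
    else:
        s0 = slices[0]
        meta = ProtocolMeta(
            scanner_label=str(getattr(s0, "StationName", "")),
            recon_label=str(getattr(s0, "ConvolutionKernel", "")),
            ctdi_vol=float(getattr(s0, "CTDIvol", float("nan"))),
            kvp=str(getattr(s0, "KVP", "")),
        )
    return vol, meta
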