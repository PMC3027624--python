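"""Reading, writing and canonicalization of medical image volumes.

All volumes are held as :class:`ImageVolume`: a 3-D scalar array indexed
``data[i, j, k]`` together with a 4x4 affine mapping voxel indices to world
millimetres in the RAS+ convention (x grows to the patient's right, y
anterior, z superior).  Every input — NIfTI or DICOM series — is reoriented
to this canonical frame on load so that ROIs, the atlas and serial scans
all live in one consistent space.  Intensities are kept in native units
(DICOM rescale slope/intercept is applied, nothing else): the pipeline
self-normalizes through the normal-parenchyma mode correction, so absolute
scanner units are irrelevant.

Voxel indexing is 0-based and a voxel's world position is the position of
its *center*.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import VolumeReadError

__all__ = [
    "ImageVolume",
    "VoxelVolume",
    "read_volume",
    "write_volume",
    "write_dicom_series",
    "voxel_volume",
]

# DICOM patient coordinates are LPS; internal frame is RAS.
_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass
class ImageVolume:
    """A 3-D scalar image on a regular grid.

    Parameters
    ----------
    data:
        3-D float array of intensities, indexed ``[i, j, k]``.
    spacing:
        Voxel edge lengths ``(dx, dy, dz)`` in mm (column norms of the
        affine's linear part).
    affine:
        4x4 voxel-index -> world-mm map (RAS+).
    valid_mask:
        Optional boolean array flagging voxels that carry real signal;
        resampling marks out-of-field voxels False.  ``None`` means all
        voxels are valid.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    valid_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be 3-D with every axis >= 1")
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        self.spacing = tuple(float(s) for s in sp)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        col_norms = np.linalg.norm(self.affine[:3, :3], axis=0)
        if not np.allclose(col_norms, sp, rtol=1e-4, atol=1e-4):
            raise ValueError(
                f"spacing {tuple(sp)} inconsistent with affine column norms {tuple(col_norms)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "ImageVolume", atol: float = 1e-3) -> bool:
        """True if *other* shares this volume's shape and affine (within atol mm)."""
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def voxel_centers_world(self, k: int | None = None) -> np.ndarray:
        """World coordinates of voxel centers, shape (nx, ny[, nz], 3).

        With ``k`` given, only that axial slice is produced.
        """
        nx, ny, nz = self.shape
        if k is None:
            ii, jj, kk = np.meshgrid(
                np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
            )
        else:
            ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
            kk = np.full_like(ii, k)
        idx = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
        world = idx @ self.affine.T
        return world[..., :3]


@dataclass(frozen=True)
class VoxelVolume:
    """Volume of a single voxel in mm^3."""

    value: float

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("voxel volume must be positive")


def voxel_volume(vol: ImageVolume) -> VoxelVolume:
    """mm^3 per voxel: the product of the three spacings."""
    dx, dy, dz = vol.spacing
    return VoxelVolume(dx * dy * dz)


# ---------------------------------------------------------------------------
# canonicalization


def _canonicalize(data: np.ndarray, affine: np.ndarray) -> ImageVolume:
    """Reorient to the closest-to-RAS axis permutation/flip.

    Pure axis relabelling: the multiset of intensities is untouched.
    """
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img = nib.as_closest_canonical(img)
    aff = img.affine
    spacing = tuple(np.linalg.norm(aff[:3, :3], axis=0))
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, aff)


# ---------------------------------------------------------------------------
# NIfTI


def _read_nifti(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeReadError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return _canonicalize(data, img.affine)


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume (or mask) as NIfTI; float64 data, RAS affine."""
    nib.save(nib.Nifti1Image(vol.data, vol.affine), str(path))


# ---------------------------------------------------------------------------
# DICOM series


def _read_dicom_series(directory: Path) -> ImageVolume:
    files = sorted(
        p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", "")
    )
    if not files:
        raise VolumeReadError(f"{directory}: no DICOM files found")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(str(f)))
        except Exception as e:  # noqa: BLE001 - rewrap with file context
            raise VolumeReadError(f"{f}: unreadable DICOM file ({e})") from e

    iop0 = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    ps0 = np.asarray(slices[0].PixelSpacing, dtype=float)
    for s in slices[1:]:
        if not np.allclose(np.asarray(s.ImageOrientationPatient, float), iop0, atol=1e-4):
            raise VolumeReadError(f"{directory}: inconsistent slice orientation across series")
        if not np.allclose(np.asarray(s.PixelSpacing, float), ps0, atol=1e-4):
            raise VolumeReadError(f"{directory}: inconsistent in-plane pixel spacing")

    row, col = iop0[:3], iop0[3:]
    normal = np.cross(row, col)
    # sort slices along the stack normal and check for gaps
    pos = [float(np.dot(normal, np.asarray(s.ImagePositionPatient, float))) for s in slices]
    order = np.argsort(pos)
    slices = [slices[i] for i in order]
    pos = np.asarray(pos, float)[order]
    if len(slices) < 2:
        dz = float(getattr(slices[0], "SliceThickness", 1.0) or 1.0)
    else:
        steps = np.diff(pos)
        dz = float(np.median(steps))
        if dz <= 0:
            raise VolumeReadError(f"{directory}: duplicate slice positions in series")
        bad = np.where(np.abs(steps - dz) > 0.05 * dz)[0]
        if bad.size:
            i = int(bad[0])
            raise VolumeReadError(
                f"{directory}: gap or irregular spacing between slices {i} and {i + 1} "
                f"(step {steps[i]:.3f} mm, expected {dz:.3f} mm)"
            )

    arrs = []
    for s in slices:
        a = s.pixel_array.astype(np.float64)
        slope = float(getattr(s, "RescaleSlope", 1.0) or 1.0)
        inter = float(getattr(s, "RescaleIntercept", 0.0) or 0.0)
        arrs.append(a * slope + inter)
    # pixel_array rows index y (column direction), columns index x (row direction)
    stack = np.stack(arrs, axis=-1)  # (rows, cols, nslices)
    data = np.transpose(stack, (1, 0, 2))  # -> (x=i along row dir, y=j, k)

    ipp0 = np.asarray(slices[0].ImagePositionPatient, dtype=float)
    affine_lps = np.eye(4)
    affine_lps[:3, 0] = row * ps0[1]  # step between columns (along row direction)
    affine_lps[:3, 1] = col * ps0[0]  # step between rows
    affine_lps[:3, 2] = normal * dz
    affine_lps[:3, 3] = ipp0
    affine_ras = _LPS_TO_RAS @ affine_lps
    return _canonicalize(data, affine_ras)


def write_dicom_series(vol: ImageVolume, directory: str | os.PathLike) -> list[Path]:
    """Write a volume as a flat DICOM series (one file per axial slice).

    Geometry is emitted in DICOM's LPS patient frame so that reading the
    series back reproduces the RAS volume.  Intensities are stored as
    int16 with a rescale intercept, so arbitrary-offset synthetic data
    round-trips at integer precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dir_ras = np.asarray(vol.affine[:3, :3]) / np.asarray(vol.spacing)
    dir_lps = _LPS_TO_RAS[:3, :3] @ dir_ras
    series_uid = generate_uid()
    study_uid = generate_uid()
    lo = float(vol.data.min())
    paths = []
    for k in range(vol.shape[2]):
        sl = vol.data[:, :, k]
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = sl.shape[1], sl.shape[0]
        ds.PixelSpacing = [float(vol.spacing[1]), float(vol.spacing[0])]
        ds.SliceThickness = float(vol.spacing[2])
        ds.ImageOrientationPatient = [*map(float, dir_lps[:, 0]), *map(float, dir_lps[:, 1])]
        ipp_ras = vol.affine @ np.array([0.0, 0.0, float(k), 1.0])
        ds.ImagePositionPatient = list(map(float, (_LPS_TO_RAS @ ipp_ras)[:3]))
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = lo
        ds.PixelData = np.round(sl.T - lo).astype(np.uint16).tobytes()
        p = directory / f"slice{k:04d}.dcm"
        ds.save_as(str(p), enforce_file_format=True)
        paths.append(p)
    return paths


def read_volume(path: str | os.PathLike, format: str | None = None) -> ImageVolume:
    """Read a volume from a NIfTI file or a DICOM series directory.

    ``format`` may be ``"nifti"`` or ``"dicom-series"``; by default it is
    inferred (directory -> DICOM, file -> NIfTI).  The result is always in
    the canonical RAS frame.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeReadError(f"no such file or directory: {path}")
    if format is None:
        format = "dicom-series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom-series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r} (expected 'nifti' or 'dicom-series')")
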