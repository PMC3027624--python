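"""Gross regions of interest: representation, rasterization, transfer.

Three roles exist: ``tumor`` (the grossly outlined lesion including cavity
and rim), ``normal`` (uninvolved parenchyma used for the brightness
correction factor — must avoid vessels, ventricles and CSF spaces) and
``mucosa`` (a manual override for the atlas-detected nasal mucosa).

Outlines arrive either as binary NIfTI masks or as per-slice closed
polygons with vertices in world millimetres; polygons are rasterized by
the voxel-center rule (a voxel belongs to the region iff its center lies
inside a polygon, even-odd rule), which is deterministic and independent
of vertex orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import GridMismatchError, RoiError
from .registration import AffineTransform, RigidTransform, resample
from .volume_io import ImageVolume, read_volume, write_volume

__all__ = ["RegionOfInterest", "PolygonSet", "rasterize", "transfer_roi", "load_roi"]

ROLES = ("tumor", "normal", "mucosa")
SOURCES = ("drawn", "transferred", "atlas")

NORMAL_MIN_VOXELS = 100
NORMAL_WARN_VOXELS = 1000


@dataclass
class RegionOfInterest:
    """A binary mask bound to a specific reference grid."""

    mask: np.ndarray
    role: str
    reference_affine: np.ndarray
    source: str = "drawn"

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise RoiError("ROI mask must be 3-D")
        if self.role not in ROLES:
            raise RoiError(f"unknown ROI role {self.role!r}; expected one of {ROLES}")
        if self.source not in SOURCES:
            raise RoiError(f"unknown ROI source {self.source!r}")
        self.reference_affine = np.asarray(self.reference_affine, dtype=float)
        if self.voxel_count < 1:
            raise RoiError(f"{self.role} ROI is empty (zero voxels)")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def check_grid(self, vol: ImageVolume) -> None:
        if self.mask.shape != vol.shape or not np.allclose(
            self.reference_affine, vol.affine, atol=1e-3
        ):
            raise GridMismatchError(
                f"{self.role} ROI grid (shape {self.mask.shape}) does not match "
                f"the reference image grid (shape {vol.shape})"
            )

    def as_volume(self) -> ImageVolume:
        spacing = tuple(np.linalg.norm(self.reference_affine[:3, :3], axis=0))
        return ImageVolume(self.mask.astype(np.float64), spacing, self.reference_affine)

    def save(self, path) -> None:
        write_volume(self.as_volume(), path)


def check_disjoint(a: RegionOfInterest, b: RegionOfInterest) -> None:
    """Tumor and normal (or mucosa) regions must not overlap: the correction
    factor and the threshold must come from uninvolved tissue."""
    if a.mask.shape == b.mask.shape and bool(np.any(a.mask & b.mask)):
        raise RoiError(
            f"{a.role} and {b.role} ROIs overlap "
            f"({int(np.sum(a.mask & b.mask))} shared voxels); they must be disjoint"
        )


@dataclass
class PolygonSet:
    """Hand-outline storage: closed polygons per axial slice.

    ``slices`` maps slice index k -> list of (n, 2) vertex arrays in world
    mm (x, y).  Each polygon needs >= 3 vertices and must be simple
    (non-self-intersecting).
    """

    role: str
    slices: dict[int, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ROLES:
            raise RoiError(f"unknown ROI role {self.role!r}")
        cleaned: dict[int, list[np.ndarray]] = {}
        for k, polys in self.slices.items():
            out = []
            for verts in polys:
                v = np.asarray(verts, dtype=float)
                if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
                    raise RoiError("each polygon needs >= 3 (x, y) vertices")
                if not Polygon(v).is_valid:
                    raise RoiError(f"self-intersecting polygon on slice {k}")
                out.append(v)
            cleaned[int(k)] = out
        self.slices = cleaned

    @classmethod
    def from_json(cls, path) -> "PolygonSet":
        doc = json.loads(Path(path).read_text())
        slices: dict[int, list[np.ndarray]] = {}
        for s in doc["slices"]:
            slices.setdefault(int(s["index"]), []).append(np.asarray(s["vertices"], float))
        return cls(role=doc["role"], slices=slices)

    def to_json(self, path, reference_id: str = "") -> None:
        doc = {
            "role": self.role,
            "reference_image": reference_id,
            "slices": [
                {"index": k, "vertices": np.asarray(v).tolist()}
                for k, polys in sorted(self.slices.items())
                for v in polys
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def rasterize(polys: PolygonSet, reference: ImageVolume) -> RegionOfInterest:
    """Voxel-center rasterization of per-slice polygons onto *reference*.

    A voxel is included iff its center's world (x, y) lies strictly inside
    a polygon of its slice (even-odd rule; polygons are simple, so this
    coincides with ordinary containment).  Vertex ordering (cw/ccw) does
    not matter.
    """
    mask = np.zeros(reference.shape, dtype=bool)
    for k, polygons in polys.slices.items():
        if not (0 <= k < reference.shape[2]):
            raise RoiError(f"polygon slice index {k} outside the image (nz={reference.shape[2]})")
        centers = reference.voxel_centers_world(k)  # (nx, ny, 3)
        xs = centers[..., 0].ravel()
        ys = centers[..., 1].ravel()
        inside = np.zeros(xs.shape, dtype=bool)
        for verts in polygons:
            inside ^= shapely.contains_xy(Polygon(verts), xs, ys)
        mask[:, :, k] |= inside.reshape(reference.shape[:2])
    if not mask.any():
        raise RoiError("ROI rasterized to zero voxels")
    return RegionOfInterest(mask, polys.role, reference.affine, source="drawn")


def transfer_roi(
    roi: RegionOfInterest,
    t: RigidTransform | AffineTransform,
    target: ImageVolume,
) -> RegionOfInterest:
    """Map an ROI onto another scan's grid through a known world transform.

    This realizes the serial workflow in which the tumor region outlined
    on the baseline scan is carried forward to each follow-up after
    fusion.  Nearest-neighbor mapping keeps the mask binary.
    """
    moved = resample(roi.as_volume(), t, target, interp="nearest", fill_value=0.0)
    mask = moved.data > 0.5
    if not mask.any():
        raise RoiError(
            f"transferred {roi.role} ROI is empty on the target grid "
            "(transform maps it outside the field of view?)"
        )
    return RegionOfInterest(mask, roi.role, target.affine, source="transferred")


def load_roi(path, role: str, reference: ImageVolume) -> RegionOfInterest:
    """Load an ROI from a polygon JSON or binary NIfTI mask file."""
    path = Path(path)
    if path.suffix == ".json":
        return rasterize(PolygonSet.from_json(path), reference)
    vol = read_volume(path)
    if vol.shape != reference.shape:
        raise GridMismatchError(
            f"mask {path} shape {vol.shape} does not match reference {reference.shape}"
        )
    mask = vol.data > 0.5
    if not mask.any():
        raise RoiError(f"mask {path} contains no voxels")
    roi = RegionOfInterest(mask, role, reference.affine, source="drawn")
    if role == "normal" and roi.voxel_count < NORMAL_MIN_VOXELS:
        raise RoiError(
            f"normal-parenchyma ROI has only {roi.voxel_count} voxels "
            f"(>= {NORMAL_MIN_VOXELS} required for a stable mode estimate)"
        )
    return roi
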