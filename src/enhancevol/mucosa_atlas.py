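"""Automatic nasal-mucosa localization from a packaged anatomic atlas.

The nasal mucosa enhances strongly and reliably after gadolinium, which
makes it a convenient per-scan reference for calibrating the enhancement
threshold.  The atlas bundle holds a template volume plus a binary mucosa
label on the template grid; detection affinely registers the template to
the patient's post-contrast scan and propagates the label with
nearest-neighbor mapping.  A hand-drawn mucosa ROI always takes
precedence over detection (the override path).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import RegistrationError, RoiError
from .registration import RegistrationSettings, register_affine, resample
from .rois import RegionOfInterest, check_disjoint
from .volume_io import ImageVolume, read_volume, write_volume

__all__ = ["AtlasBundle", "load_atlas", "save_atlas", "detect_mucosa"]


@dataclass
class AtlasBundle:
    """Template volume + mucosa label mask on the template grid."""

    template: ImageVolume
    mucosa_label: np.ndarray
    metadata: str = ""

    def __post_init__(self):
        self.mucosa_label = np.asarray(self.mucosa_label).astype(bool)
        if self.mucosa_label.shape != self.template.shape:
            raise ValueError("mucosa label grid does not match template grid")
        if not self.mucosa_label.any():
            raise ValueError("atlas mucosa label is empty")


def load_atlas(directory) -> AtlasBundle:
    """Read an atlas bundle directory {template.nii.gz, mucosa_label.nii.gz, metadata.txt}."""
    directory = Path(directory)
    template = read_volume(directory / "template.nii.gz")
    label_vol = read_volume(directory / "mucosa_label.nii.gz")
    meta_path = directory / "metadata.txt"
    metadata = meta_path.read_text() if meta_path.exists() else ""
    return AtlasBundle(template, label_vol.data > 0.5, metadata)


def save_atlas(atlas: AtlasBundle, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(atlas.template, directory / "template.nii.gz")
    label = ImageVolume(
        atlas.mucosa_label.astype(np.float64), atlas.template.spacing, atlas.template.affine
    )
    write_volume(label, directory / "mucosa_label.nii.gz")
    (directory / "metadata.txt").write_text(atlas.metadata or "synthetic atlas bundle\n")


def detect_mucosa(
    post: ImageVolume,
    atlas: AtlasBundle,
    tumor: RegionOfInterest | None = None,
    settings: RegistrationSettings | None = None,
) -> RegionOfInterest:
    """Locate the nasal mucosa on a post-contrast scan via the atlas.

    Registers ``atlas.template`` to *post* with an affine model and maps
    the mucosa label through the recovered transform (nearest neighbor,
    so the mask stays binary).  If a tumor ROI is supplied, any overlap
    between the detected mucosa and the tumor is a hard error — the
    threshold reference must be uninvolved tissue; in that case (or on
    registration failure) supply a manual mucosa ROI instead.
    """
    try:
        t = register_affine(atlas.template, post, settings)
    except RegistrationError as e:
        raise RegistrationError(
            f"atlas-to-patient registration failed ({e}); "
            "draw a manual mucosa ROI and pass it as the mucosa source"
        ) from e
    label_vol = ImageVolume(
        atlas.mucosa_label.astype(np.float64), atlas.template.spacing, atlas.template.affine
    )
    moved = resample(label_vol, t, post, interp="nearest", fill_value=0.0)
    mask = moved.data > 0.5
    if not mask.any():
        raise RoiError(
            "atlas mucosa label mapped to zero voxels on the patient grid "
            "(does the scan cover the nasal region?); "
            "draw a manual mucosa ROI and pass it as the mucosa source"
        )
    roi = RegionOfInterest(mask, "mucosa", post.affine, source="atlas")
    if tumor is not None:
        check_disjoint(roi, tumor)
    return roi
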