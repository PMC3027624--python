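"""Conversion between :class:`ImageVolume` and SimpleITK images.

SimpleITK is agnostic about anatomical axis labels, so images are handed
over with their RAS affine used directly as origin/direction/spacing; all
transforms produced by registration therefore live in the same RAS world
frame as the rest of the package.
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk

from .volume_io import ImageVolume


def to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0)).astype(np.float64))
    )
    spacing = np.asarray(vol.spacing)
    direction = vol.affine[:3, :3] / spacing
    img.SetSpacing(tuple(map(float, spacing)))
    img.SetOrigin(tuple(map(float, vol.affine[:3, 3])))
    img.SetDirection(tuple(map(float, direction.ravel())))
    return img


def from_sitk(img: sitk.Image) -> ImageVolume:
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0)).astype(np.float64)
    spacing = np.asarray(img.GetSpacing())
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    affine = np.eye(4)
    affine[:3, :3] = direction * spacing
    affine[:3, 3] = np.asarray(img.GetOrigin())
    return ImageVolume(data, tuple(spacing), affine)
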