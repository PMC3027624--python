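"""The core enhancement-volumetry computation.

The algorithm isolates contrast enhancement by voxelwise subtraction of
the fused pre-contrast scan from the post-contrast scan, then makes the
result comparable across scans in two steps:

1. **Brightness correction.**  MRI pixel values are not standardized, so
   the subtraction carries an unknown global offset.  Inside a user-drawn
   normal-parenchyma region the true enhancement is zero; the *mode* of
   the subtraction values there estimates the offset and is subtracted
   from every subsequent value (the "correction factor").
2. **Per-scan enhancement threshold.**  The nasal mucosa enhances
   strongly on every contrasted scan.  After correction, the top 5% of
   mucosa values are discarded as potential outliers and the threshold is
   set to 25% of the remaining maximum.  Both fractions are configurable;
   25% vs 40% is the comparison clinically examined.

A tumor voxel is *enhancing* iff its corrected subtraction value exceeds
the threshold (strictly, by default).  Enhancing volume = count x voxel
volume.  Because any constant added to either scan moves the mode by the
same amount, the result is invariant to global brightness offsets; joint
rescaling of both scans scales correction and threshold together and
leaves the enhancement mask unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .errors import (
    GridMismatchError,
    PipelineStageError,
    RoiError,
    ThresholdError,
)
from .mucosa_atlas import AtlasBundle, detect_mucosa
from .registration import RegistrationSettings, RigidTransform, register_rigid, resample
from .rois import RegionOfInterest, check_disjoint
from .volume_io import ImageVolume, VoxelVolume, voxel_volume

__all__ = [
    "SubtractionMap",
    "CorrectionFactor",
    "EnhancementThreshold",
    "EnhancingVolumeResult",
    "AnalysisParams",
    "subtract",
    "correction_factor",
    "apply_correction",
    "enhancement_threshold",
    "enhancing_volume",
    "quantify",
]

MIN_NORMAL_VOXELS = 100


@dataclass
class SubtractionMap:
    """Voxelwise post - pre on the post-contrast grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    valid_mask: np.ndarray

    @property
    def shape(self):
        return self.data.shape


@dataclass(frozen=True)
class CorrectionFactor:
    """Mode of normal-parenchyma subtraction values (global brightness offset)."""

    value: float
    bin_width: float
    n_voxels: int


@dataclass(frozen=True)
class EnhancementThreshold:
    """Mucosa-referenced enhancement cut-off and its provenance."""

    value: float
    threshold_fraction: float
    exclusion_fraction: float
    remaining_max: float
    n_mucosa_voxels: int


@dataclass
class EnhancingVolumeResult:
    voxel_count: int
    volume_cm3: float
    enhancement_mask: np.ndarray
    threshold: EnhancementThreshold
    correction: CorrectionFactor

    def to_dict(self) -> dict:
        return {
            "voxel_count": self.voxel_count,
            "volume_cm3": self.volume_cm3,
            "threshold": {
                "value": self.threshold.value,
                "threshold_fraction": self.threshold.threshold_fraction,
                "exclusion_fraction": self.threshold.exclusion_fraction,
                "remaining_max": self.threshold.remaining_max,
                "n_mucosa_voxels": self.threshold.n_mucosa_voxels,
            },
            "correction": {
                "value": self.correction.value,
                "bin_width": self.correction.bin_width,
                "n_voxels": self.correction.n_voxels,
            },
        }


@dataclass
class AnalysisParams:
    """Tunable parameters of the full pipeline.

    Defaults are the method's published operating point: threshold at 25%
    of the trimmed mucosa maximum, top-5% mucosa trim, 1-unit mode bins
    (integer MRI data), strict ``>`` at the cut-off.
    """

    threshold_fraction: float = 0.25
    exclusion_fraction: float = 0.05
    bin_width: float = 1.0
    strict_greater: bool = True
    skip_registration: bool = False
    registration: RegistrationSettings = field(default_factory=RegistrationSettings)


def subtract(post: ImageVolume, pre_resampled: ImageVolume) -> SubtractionMap:
    """Elementwise post - pre on the shared (post) grid.

    Voxels where the resampled pre-contrast scan had no data (out of
    field) are excluded from every downstream statistic via the map's
    ``valid_mask``.
    """
    if not post.same_grid(pre_resampled):
        raise GridMismatchError(
            "pre-contrast volume is not on the post-contrast grid; resample it first"
        )
    valid = np.ones(post.shape, dtype=bool)
    if pre_resampled.valid_mask is not None:
        valid &= pre_resampled.valid_mask
    if post.valid_mask is not None:
        valid &= post.valid_mask
    return SubtractionMap(
        post.data - pre_resampled.data, post.spacing, post.affine.copy(), valid
    )


def correction_factor(
    sub: SubtractionMap,
    normal: RegionOfInterest,
    bin_width: float = 1.0,
) -> CorrectionFactor:
    """Mode of the subtraction values inside the normal-parenchyma ROI.

    Estimated from a fixed-width histogram (default 1 intensity unit,
    suiting integer MRI data; reduce for float data).  The mode is the
    center of the most populated bin; ties break toward the lowest bin.
    """
    if normal.role != "normal":
        raise RoiError(f"correction factor needs a 'normal' ROI, got role {normal.role!r}")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = sub.data[normal.mask & sub.valid_mask]
    if values.size < MIN_NORMAL_VOXELS:
        raise RoiError(
            f"normal ROI supplies only {values.size} valid voxels; "
            f">= {MIN_NORMAL_VOXELS} required for a stable mode"
        )
    # bins centered on multiples of bin_width, so integer-valued data maps
    # onto exact integer modes
    first = round(float(values.min()) / bin_width)
    last = round(float(values.max()) / bin_width)
    edges = (np.arange(first, last + 2) - 0.5) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    i = int(np.argmax(counts))  # argmax takes the first maximum: low-bin tie-break
    mode = float((first + i) * bin_width)
    return CorrectionFactor(mode, float(bin_width), int(values.size))


def apply_correction(
    sub: SubtractionMap,
    roi: RegionOfInterest,
    c: CorrectionFactor,
) -> np.ndarray:
    """Corrected values (subtraction minus correction factor) inside an ROI.

    Negative corrected values are retained — they simply never exceed a
    positive threshold.
    """
    roi_valid = roi.mask & sub.valid_mask
    if not roi_valid.any():
        raise RoiError(f"{roi.role} ROI has no valid voxels on the subtraction map")
    return sub.data[roi_valid] - c.value


def enhancement_threshold(
    corrected_mucosa: np.ndarray,
    exclusion_fraction: float = 0.05,
    threshold_fraction: float = 0.25,
) -> EnhancementThreshold:
    """Derive the enhancement cut-off from corrected mucosa values.

    The ``k = ceil(exclusion_fraction * n)`` largest values are discarded
    (order-statistic trim guarding against spill-over artifacts), and the
    cut-off is ``threshold_fraction`` times the maximum of what remains.
    """
    values = np.asarray(corrected_mucosa, dtype=float).ravel()
    n = values.size
    if n == 0:
        raise ThresholdError("mucosa value collection is empty")
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if not (0.0 <= exclusion_fraction < 1.0):
        raise ValueError("exclusion_fraction must lie in [0, 1)")
    k = math.ceil(exclusion_fraction * n)
    if k >= n:
        raise ThresholdError(
            f"top-{exclusion_fraction:.0%} trim removes all {n} mucosa values"
        )
    remaining_max = float(np.sort(values)[::-1][k])
    if remaining_max <= 0:
        raise ThresholdError(
            "mucosa shows no net enhancement (trimmed maximum <= 0); "
            "check fusion and the mucosa region"
        )
    return EnhancementThreshold(
        value=float(threshold_fraction * remaining_max),
        threshold_fraction=float(threshold_fraction),
        exclusion_fraction=float(exclusion_fraction),
        remaining_max=remaining_max,
        n_mucosa_voxels=int(n),
    )


def enhancing_volume(
    sub: SubtractionMap,
    tumor: RegionOfInterest,
    c: CorrectionFactor,
    th: EnhancementThreshold,
    vv: VoxelVolume,
    strict_greater: bool = True,
) -> EnhancingVolumeResult:
    """Count supra-threshold voxels inside the tumor ROI -> volume in cm^3.

    Zero enhancing voxels is a valid result (e.g. complete response).
    """
    if tumor.role != "tumor":
        raise RoiError(f"enhancing_volume needs a 'tumor' ROI, got role {tumor.role!r}")
    if th.value <= 0:
        raise ThresholdError("enhancement threshold must be positive")
    corrected = sub.data - c.value
    above = corrected > th.value if strict_greater else corrected >= th.value
    mask = above & tumor.mask & sub.valid_mask
    count = int(mask.sum())
    return EnhancingVolumeResult(
        voxel_count=count,
        volume_cm3=count * vv.value / 1000.0,
        enhancement_mask=mask,
        threshold=th,
        correction=c,
    )


MucosaSource = Union[AtlasBundle, RegionOfInterest]


def quantify(
    pre: ImageVolume,
    post: ImageVolume,
    tumor: RegionOfInterest,
    normal: RegionOfInterest,
    mucosa_source: MucosaSource,
    params: AnalysisParams | None = None,
) -> EnhancingVolumeResult:
    """Full pipeline: fuse, subtract, correct, threshold, count.

    ``mucosa_source`` is either an :class:`AtlasBundle` (automatic
    detection) or a hand-drawn mucosa :class:`RegionOfInterest`
    (override; used unchanged).  Deterministic for fixed inputs.
    Stage failures raise :class:`PipelineStageError` naming the stage.
    """
    params = params or AnalysisParams()

    def stage(name, fn):
        try:
            return fn()
        except PipelineStageError:
            raise
        except Exception as e:  # noqa: BLE001 - rewrap with stage context
            raise PipelineStageError(name, str(e)) from e

    stage("validate-rois", lambda: (tumor.check_grid(post), normal.check_grid(post)))
    stage("validate-rois", lambda: check_disjoint(tumor, normal))

    if params.skip_registration:
        if not pre.same_grid(post):
            raise PipelineStageError(
                "fusion", "skip_registration requires pre and post on the same grid"
            )
        fusion = RigidTransform.identity()
    else:
        fusion = stage("fusion", lambda: register_rigid(pre, post, params.registration))
    pre_on_post = stage("fusion", lambda: resample(pre, fusion, post, interp="linear"))

    sub = stage("subtraction", lambda: subtract(post, pre_on_post))
    corr = stage(
        "correction-factor", lambda: correction_factor(sub, normal, params.bin_width)
    )

    if isinstance(mucosa_source, RegionOfInterest):
        if mucosa_source.role != "mucosa":
            raise PipelineStageError(
                "mucosa", f"override ROI has role {mucosa_source.role!r}, expected 'mucosa'"
            )
        mucosa = mucosa_source  # manual override: atlas detection skipped
        stage("mucosa", lambda: mucosa.check_grid(post))
    else:
        mucosa = stage(
            "mucosa",
            lambda: detect_mucosa(post, mucosa_source, tumor, params.registration),
        )
    stage("mucosa", lambda: check_disjoint(mucosa, tumor))

    corrected_mucosa = stage(
        "mucosa-correction", lambda: apply_correction(sub, mucosa, corr)
    )
    th = stage(
        "threshold",
        lambda: enhancement_threshold(
            corrected_mucosa, params.exclusion_fraction, params.threshold_fraction
        ),
    )
    return stage(
        "enhancing-volume",
        lambda: enhancing_volume(
            sub, tumor, corr, th, voxel_volume(post), params.strict_greater
        ),
    )
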