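"""Synthetic pre/post-contrast phantom volumes with exact ground truth.

The generator builds geometric head phantoms that reproduce, feature by
feature, the imaging situations the volumetric method is designed for:

* a dark resection **cavity** whose thin **rim** brightens only after
  contrast (the enhancing tumor), with a collapse factor to shrink the
  cavity while the rim grows;
* **subacute blood**: cavity contents intrinsically bright on *both*
  scans, which naive post-contrast reading mistakes for enhancement;
* thin **meningeal enhancement** hugging the inner skull surface next to
  the cavity (the generous-vs-narrow ROI experiment);
* normal **parenchyma** carrying a constant pre/post brightness offset
  (what the mode correction must absorb);
* a strongly enhancing **nasal mucosa** slab in the inferior slices (the
  threshold reference), doubling as the test atlas;
* **Rician noise**, the magnitude-image noise law of MRI, synthesized
  from two independent Gaussian channels.

Everything is deterministic given the integer seed, and the noiseless
``post - pre`` difference equals the specified contrast map exactly, so
every downstream quantity has a closed-form truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation

from .mucosa_atlas import AtlasBundle, save_atlas
from .rois import RegionOfInterest
from .volume_io import ImageVolume, write_volume

__all__ = ["PhantomSpec", "PhantomTruth", "generate", "scenario", "write_fixture", "SCENARIOS"]


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise description of one phantom scan pair.

    Lengths in mm, intensities in arbitrary MRI units.  All component
    centers are relative to the head center (the world origin), except
    via ``anatomy_offset_mm`` which shifts the whole anatomy inside the
    fixed grid (emulating patient repositioning between visits).
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    head_radii_mm: tuple[float, float, float] = (55.0, 55.0, 40.0)
    parenchyma_pre: float = 400.0
    global_offset: float = 10.0  # post = pre + offset outside enhancing tissue

    cavity_center_mm: tuple[float, float, float] = (16.0, 10.0, 4.0)
    cavity_radii_mm: tuple[float, float, float] = (14.0, 12.0, 9.0)
    collapse_factor: float = 1.0  # multiplies cavity radii (cavity shrinkage)
    cavity_intensity: float = 100.0

    rim_thickness_mm: float = 3.0
    rim_contrast: float = 150.0  # post-only brightening at the cavity-facing edge
    rim_contrast_min: float = 90.0  # fades to this at the rim's outer margin

    blood_intensity: float = 0.0  # added inside the cavity core
    blood_on_post_only: bool = False  # True models true enhancement, not blood

    meninges_contrast: float = 0.0  # post-only; 0 disables the meninges patch
    meninges_shell: tuple[float, float] = (0.90, 1.0)  # of head ellipsoid radius

    mucosa_center_mm: tuple[float, float, float] = (0.0, 40.0, -38.0)
    mucosa_half_size_mm: tuple[float, float, float] = (8.0, 6.0, 4.0)
    mucosa_pad_mm: float = 6.0  # surrounding facial soft tissue (same pre intensity)
    mucosa_pre: float = 300.0
    mucosa_contrast: float = 300.0

    normal_center_mm: tuple[float, float, float] = (-28.0, -16.0, 5.0)
    normal_half_size_mm: tuple[float, float, float] = (12.0, 12.0, 10.0)

    anatomy_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    roi_margin_mm: float = 6.0  # how generously the "drawn" tumor ROI overshoots

    noise: str = "none"  # none | gaussian | rician
    noise_sigma: float = 0.0
    seed: int = 0


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying one generated scan pair."""

    enhancing_mask: np.ndarray  # noiseless post-pre > offset inside the lesion
    enhancing_count: int
    rim_mask: np.ndarray
    cavity_mask: np.ndarray
    blood_mask: np.ndarray
    meninges_mask: np.ndarray
    mucosa_mask: np.ndarray
    head_mask: np.ndarray
    tumor_narrow: RegionOfInterest
    tumor_generous: RegionOfInterest
    normal: RegionOfInterest
    mucosa_roi: RegionOfInterest
    global_offset: float
    spec: PhantomSpec = field(repr=False)


def _grid_affine(spec: PhantomSpec) -> np.ndarray:
    affine = np.diag([*spec.spacing, 1.0]).astype(float)
    affine[:3, 3] = -(np.asarray(spec.shape) - 1) / 2.0 * np.asarray(spec.spacing)
    return affine


def _ellipsoid(centers: np.ndarray, center, radii) -> np.ndarray:
    rel = (centers - np.asarray(center)) / np.asarray(radii)
    return np.sum(rel**2, axis=-1) <= 1.0


def _box(centers: np.ndarray, center, half) -> np.ndarray:
    return np.all(np.abs(centers - np.asarray(center)) <= np.asarray(half), axis=-1)


def _apply_noise(img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise == "none" or spec.noise_sigma == 0:
        return img
    if spec.noise == "gaussian":
        return img + rng.normal(0.0, spec.noise_sigma, img.shape)
    if spec.noise == "rician":
        n1 = rng.normal(0.0, spec.noise_sigma, img.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, img.shape)
        return np.sqrt((img + n1) ** 2 + n2**2)
    raise ValueError(f"unknown noise model {spec.noise!r}")


def generate(spec: PhantomSpec) -> tuple[ImageVolume, ImageVolume, PhantomTruth, AtlasBundle]:
    """Render one pre/post pair, its ground truth, and the matching atlas.

    Deterministic for a fixed spec (including seed).  The atlas bundle's
    template is the noiseless post-contrast volume with the mucosa slab
    as its label, so atlas detection can be tested against a known
    mapping.
    """
    affine = _grid_affine(spec)
    probe = ImageVolume(np.zeros(spec.shape), spec.spacing, affine)
    centers = probe.voxel_centers_world()  # (nx, ny, nz, 3)
    off = np.asarray(spec.anatomy_offset_mm)

    head = _ellipsoid(centers, off, spec.head_radii_mm)
    cav_center = np.asarray(spec.cavity_center_mm) + off
    cav_radii = np.asarray(spec.cavity_radii_mm) * spec.collapse_factor
    cavity = _ellipsoid(centers, cav_center, cav_radii) & head
    rim = np.zeros(spec.shape, bool)
    if spec.rim_thickness_mm > 0 and spec.rim_contrast != 0:
        outer = _ellipsoid(centers, cav_center, cav_radii + spec.rim_thickness_mm)
        rim = outer & ~cavity & head
    blood = np.zeros(spec.shape, bool)
    if spec.blood_intensity != 0:
        blood = _ellipsoid(centers, cav_center, cav_radii * 0.75) & cavity
    meninges = np.zeros(spec.shape, bool)
    if spec.meninges_contrast != 0:
        rel = (centers - off) / np.asarray(spec.head_radii_mm)
        rho = np.sqrt(np.sum(rel**2, axis=-1))
        lo, hi = spec.meninges_shell
        toward = np.zeros(spec.shape, bool)
        u = cav_center - off
        u = u / np.linalg.norm(u)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.sum(rel * u, axis=-1) / np.maximum(rho, 1e-9)
        toward = cosang > 0.75
        meninges = (rho >= lo) & (rho <= hi) & toward
    mucosa = _box(centers, np.asarray(spec.mucosa_center_mm) + off, spec.mucosa_half_size_mm)
    if not mucosa.any():
        raise ValueError("mucosa slab lies outside the grid")

    # facial soft tissue embedding the mucosa, so the slab never borders
    # air (its edges would otherwise dominate the subtraction statistics
    # under sub-voxel fusion error)
    pad = _box(
        centers,
        np.asarray(spec.mucosa_center_mm) + off,
        np.asarray(spec.mucosa_half_size_mm) + spec.mucosa_pad_mm,
    )

    # noiseless pre
    pre = np.zeros(spec.shape, float)
    pre[head] = spec.parenchyma_pre
    pre[pad] = spec.mucosa_pre
    pre[cavity] = spec.cavity_intensity
    pre[rim] = spec.parenchyma_pre
    pre[mucosa] = spec.mucosa_pre
    if spec.blood_intensity != 0 and not spec.blood_on_post_only:
        pre[blood] += spec.blood_intensity

    # contrast map: exactly what (noiseless post - pre - offset) must equal
    contrast = np.zeros(spec.shape, float)
    if rim.any():
        # rim enhancement fades radially from the cavity face outward
        rho_out = np.sqrt(
            np.sum(((centers - cav_center) / (cav_radii + spec.rim_thickness_mm)) ** 2, axis=-1)
        )
        rho_in = cav_radii.mean() / (cav_radii.mean() + spec.rim_thickness_mm)
        frac = np.clip((1.0 - rho_out) / max(1.0 - rho_in, 1e-9), 0.0, 1.0)
        contrast[rim] = (
            spec.rim_contrast_min
            + (spec.rim_contrast - spec.rim_contrast_min) * frac[rim]
        )
    contrast[meninges] += spec.meninges_contrast
    contrast[mucosa] = spec.mucosa_contrast
    if spec.blood_intensity != 0 and spec.blood_on_post_only:
        contrast[blood] += spec.blood_intensity
    post = pre + contrast + spec.global_offset

    # ROIs: the grossly drawn outlines a user would supply.  The narrow
    # tumor outline is an ellipsoid overshooting the lesion by an
    # isotropic margin; the generous one also swallows the meninges.
    narrow_mask = _ellipsoid(
        centers, cav_center, cav_radii + spec.rim_thickness_mm + spec.roi_margin_mm
    )
    generous_mask = narrow_mask | (
        binary_dilation(meninges, iterations=2) if meninges.any() else meninges
    )
    normal_mask = _box(centers, np.asarray(spec.normal_center_mm) + off, spec.normal_half_size_mm)
    for name, m in (("normal", normal_mask), ("mucosa", mucosa)):
        if np.any(m & generous_mask):
            raise ValueError(f"phantom {name} region overlaps the tumor region; adjust geometry")
    if np.any(normal_mask & mucosa):
        raise ValueError("phantom normal and mucosa regions overlap; adjust geometry")

    tumor_narrow = RegionOfInterest(narrow_mask, "tumor", affine, source="drawn")
    tumor_generous = RegionOfInterest(generous_mask, "tumor", affine, source="drawn")
    normal_roi = RegionOfInterest(normal_mask, "normal", affine, source="drawn")
    mucosa_roi = RegionOfInterest(mucosa, "mucosa", affine, source="drawn")

    enhancing = rim.copy()
    if spec.blood_on_post_only and spec.blood_intensity > 0:
        enhancing |= blood
    truth = PhantomTruth(
        enhancing_mask=enhancing,
        enhancing_count=int(enhancing.sum()),
        rim_mask=rim,
        cavity_mask=cavity,
        blood_mask=blood,
        meninges_mask=meninges,
        mucosa_mask=mucosa,
        head_mask=head,
        tumor_narrow=tumor_narrow,
        tumor_generous=tumor_generous,
        normal=normal_roi,
        mucosa_roi=mucosa_roi,
        global_offset=spec.global_offset,
        spec=spec,
    )

    atlas = AtlasBundle(
        template=ImageVolume(post.copy(), spec.spacing, affine.copy()),
        mucosa_label=mucosa.copy(),
        metadata="synthetic phantom atlas: template is the noiseless post-contrast "
        "volume; label is the nasal-mucosa slab",
    )

    rng = np.random.default_rng(spec.seed)
    pre_noisy = _apply_noise(pre, spec, rng)
    post_noisy = _apply_noise(post, spec, rng)
    return (
        ImageVolume(pre_noisy, spec.spacing, affine.copy()),
        ImageVolume(post_noisy, spec.spacing, affine.copy()),
        truth,
        atlas,
    )


# ---------------------------------------------------------------------------
# canned scenarios

SERIAL_RIM_THICKNESS_MM = (2.5, 3.5, 3.0, 4.0, 5.0, 4.5, 5.5, 6.0)
SERIAL_NOISE_SIGMA = 2.0

SCENARIOS = (
    "rim_baseline",
    "cavity_collapse",
    "subacute_blood",
    "meningeal_rim",
    "serial_series",
)


def scenario(name: str, seed: int = 0) -> list[PhantomSpec]:
    """Canned phantom specs reproducing each study situation.

    ``rim_baseline``: one noiseless cavity-with-enhancing-rim pair.
    ``cavity_collapse``: baseline plus a follow-up whose cavity has
    collapsed (smaller extents) while the rim thickened (more enhancing
    tissue) — caliper readings shrink, true volume grows.
    ``subacute_blood``: cavity filled with intrinsically bright blood on
    both scans, no enhancing rim.
    ``meningeal_rim``: rim plus adjacent meningeal enhancement, for the
    narrow-vs-generous ROI comparison.
    ``serial_series``: eight timepoints with a prescribed rim-thickness
    (hence true-volume) trajectory, mild Rician noise and small patient
    repositioning between visits.
    """
    base = PhantomSpec(seed=seed)
    if name == "rim_baseline":
        return [base]
    if name == "cavity_collapse":
        baseline = dataclasses.replace(base, rim_thickness_mm=2.5)
        collapsed = dataclasses.replace(
            base, collapse_factor=0.6, rim_thickness_mm=5.5, seed=seed + 1
        )
        return [baseline, collapsed]
    if name == "subacute_blood":
        return [
            dataclasses.replace(
                base, rim_thickness_mm=0.0, rim_contrast=0.0, blood_intensity=450.0
            )
        ]
    if name == "meningeal_rim":
        return [dataclasses.replace(base, meninges_contrast=130.0)]
    if name == "serial_series":
        specs = []
        jitter = [
            (0.0, 0.0, 0.0),
            (1.0, -0.5, 0.5),
            (-0.8, 0.6, -0.4),
            (0.5, 1.0, 0.3),
            (-1.2, -0.7, 0.6),
            (0.9, 0.2, -0.8),
            (-0.4, 1.1, 0.2),
            (1.1, -0.9, -0.5),
        ]
        for i, (t, j) in enumerate(zip(SERIAL_RIM_THICKNESS_MM, jitter)):
            specs.append(
                dataclasses.replace(
                    base,
                    rim_thickness_mm=t,
                    meninges_contrast=130.0,
                    anatomy_offset_mm=j,
                    noise="rician",
                    noise_sigma=SERIAL_NOISE_SIGMA,
                    seed=seed * 1000 + i,
                )
            )
        return specs
    raise ValueError(f"unknown scenario {name!r}; valid names: {', '.join(SCENARIOS)}")


def write_fixture(outdir, spec: PhantomSpec) -> Path:
    """Render a spec and write the complete fixture directory.

    Layout: ``pre.nii.gz``, ``post.nii.gz``, ``rois/{tumor,tumor_generous,
    normal,mucosa}.nii.gz``, ``atlas/``, ``truth.json``.
    """
    outdir = Path(outdir)
    pre, post, truth, atlas = generate(spec)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(pre, outdir / "pre.nii.gz")
    write_volume(post, outdir / "post.nii.gz")
    roi_dir = outdir / "rois"
    roi_dir.mkdir(exist_ok=True)
    truth.tumor_narrow.save(roi_dir / "tumor.nii.gz")
    truth.tumor_generous.save(roi_dir / "tumor_generous.nii.gz")
    truth.normal.save(roi_dir / "normal.nii.gz")
    truth.mucosa_roi.save(roi_dir / "mucosa.nii.gz")
    save_atlas(atlas, outdir / "atlas")
    (outdir / "truth.json").write_text(
        json.dumps(
            {
                "enhancing_count": truth.enhancing_count,
                "cavity_count": int(truth.cavity_mask.sum()),
                "blood_count": int(truth.blood_mask.sum()),
                "meninges_count": int(truth.meninges_mask.sum()),
                "global_offset": truth.global_offset,
                "voxel_volume_mm3": float(np.prod(spec.spacing)),
                "spec": dataclasses.asdict(spec),
            },
            indent=1,
        )
    )
    return outdir
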