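# Methods

## The problem

After surgical resection of an enhancing brain tumor, response assessment
on MRI is dominated by the geometry of the resection cavity rather than by
the tumor itself. Caliper criteria — RECIST's longest 1-D diameter and the
Macdonald 2-D product of perpendicular diameters — are measured across the
whole lesion, so a cavity that collapses over time shrinks the caliper
readings even while rim enhancement (the actual tumor surrogate) grows.
Intrinsically T1-bright material such as subacute blood further confounds
reading of the post-contrast scan alone. `enhancevol` implements a
nearly-automated volumetric alternative that needs only standard pre- and
post-contrast T1 acquisitions.

## Pipeline

Given a pre-contrast volume `P`, a post-contrast volume `Q`, a grossly
outlined tumor ROI `T`, a normal-parenchyma ROI `N` (avoiding vessels,
ventricles and CSF), and a nasal-mucosa reference region `M` (atlas-derived
or hand-drawn):

1. **Fusion.** `P` is rigidly registered to `Q` (6 degrees of freedom,
   Mattes mutual-information objective, multi-resolution) and resampled
   onto `Q`'s grid with linear interpolation. Same-subject pre/post pairs
   differ essentially by pose and contrast uptake, so a rigid model is the
   minimal one consistent with "fusion"; the MI objective tolerates the
   intensity differences contrast injection introduces.
2. **Subtraction.** `S = Q − P_fused`, voxelwise, on `Q`'s grid. Voxels
   that left the field of view during resampling are flagged and excluded
   from every statistic.
3. **Brightness correction.** MRI intensities are not standardized across
   scans, so `S` carries an unknown global offset. Inside `N` the true
   enhancement is zero; the **mode** of `S` over `N` estimates the offset
   (`c`, the *correction factor*) and is subtracted from all subsequent
   values. The mode is taken from a fixed-width histogram, default bin
   width 1 native intensity unit (suiting integer MRI data; reduce it for
   float data), bins centered on multiples of the bin width, ties broken
   toward the lowest bin.
4. **Threshold.** The nasal mucosa enhances strongly and reliably on every
   contrasted scan, making it a per-scan calibration target. With
   corrected mucosa values `m_i = S_i − c` over `M`, the largest
   `k = ceil(0.05 · n)` values are discarded (an order-statistic trim
   guarding against registration spill-over and artifacts) and the
   enhancement cut-off is `θ = f · max(remaining)` with `f = 0.25` by
   default (`f = 0.40` is the alternative operating point studied for
   sensitivity).
5. **Counting.** A tumor voxel is enhancing iff `S_i − c > θ` (strictly;
   an inclusive `≥` is available via `strict_greater=False`). Enhancing
   volume = count × voxel volume / 1000 (cm³).

Two invariances follow directly and are enforced by tests: adding any
constant to either scan moves the mode by the same amount and cancels
(exactly, up to mode-bin quantization of the constant), and jointly
scaling both scans by `k > 0` scales `c` and `θ` by `k`, leaving the
enhancement mask unchanged.

### Atlas-based mucosa detection

The atlas bundle is a template volume plus a binary mucosa label on the
template grid. Detection registers the template to the patient's
post-contrast scan with an affine model and propagates the label by
nearest-neighbor mapping. A hand-drawn mucosa ROI always overrides
detection. Detected mucosa intersecting the tumor ROI is a hard error: the
calibration region must be uninvolved tissue. The packaged test atlas is
the phantom's own template; a clinical atlas is a pluggable asset, not a
repository deliverable.

### Serial analysis

Follow-up scans are rigidly registered to the **baseline post-contrast
scan**, and the baseline outlines (tumor, normal, optional mucosa) are
transferred through the recovered transform with nearest-neighbor mapping,
so the same anatomical region is measured at every visit. The serial
report gives per-timepoint volumes plus absolute and percent change
relative to baseline; response *categorization* (partial response /
progression rules) is deliberately out of scope.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `threshold_fraction` | 0.25 | fraction of the trimmed mucosa maximum used as cut-off; 0.40 is the studied alternative |
| `exclusion_fraction` | 0.05 | fraction of mucosa voxels trimmed from the top before taking the maximum |
| `bin_width` | 1.0 | mode-histogram bin width, native intensity units |
| `strict_greater` | True | `>` vs `≥` at the cut-off |
| `skip_registration` | False | bypass fusion when pre/post are already on one grid |
| registration `learning_rate` / `affine_learning_rate` | 2.0 / 0.2 | gradient-descent step sizes; affine scale/shear parameters need much smaller steps than rigid pose |

A recovered fusion transform within 10⁻³ mm / 10⁻³ degree of identity is
snapped to the exact identity so that already-aligned pairs are not
degraded by needless interpolation. Registration evaluates the metric
densely by default (`sampling_fraction = 1.0`), which makes every run
bit-reproducible; sub-sampled runs use a fixed seed.

## The phantom generator

Synthetic scan pairs provide exact ground truth for every scenario the
method targets. A head-sized ellipsoid of parenchyma (pre intensity 400,
2 mm isotropic grid, 64×64×48) contains:

* a dark resection **cavity** (intensity 100) with a **rim** that
  brightens only post-contrast, fading radially from 150 at the cavity
  face to 90 at its outer margin — every rim voxel sits above the 25%
  threshold (75) so noiseless recovery is exact, while the 40% threshold
  (120) genuinely cuts into the fading rim;
* optional **subacute blood** filling the cavity core, equally bright on
  both scans (or, as a control variant, bright only on post);
* an optional **meningeal** patch at the inner skull surface next to the
  cavity (contrast 130, just above the 40% cut);
* a **nasal-mucosa** slab (contrast 300) in the inferior slices, embedded
  in a non-enhancing facial-soft-tissue pad so the slab never borders air
  — otherwise sub-voxel fusion error at an air interface inflates the
  subtraction maximum beyond what the 5% trim can absorb, exactly the
  artifact the trim models at realistic scale;
* a constant global pre/post **offset** (default 10) that the mode
  correction must absorb;
* **Rician noise** synthesized from two independent Gaussian channels
  (the magnitude-MRI noise law), all randomness flowing from one integer
  seed.

The cavity-collapse scenario shrinks the cavity radii by a factor 0.6
while thickening the rim from 2.5 mm to 5.5 mm: lesion bounding extents
(hence caliper readings) decrease while true enhancing volume increases.
The serial scenario prescribes an eight-visit rim-thickness trajectory
(2.5, 3.5, 3.0, 4.0, 5.0, 4.5, 5.5, 6.0 mm) with mild Rician noise
(σ = 2) and millimetre-scale patient repositioning between visits.

What the phantom does **not** emulate: anatomy (it is purely geometric),
bias fields, partial-volume fractions at tissue interfaces, motion or
susceptibility artifacts, and deformable anatomical change. Passing
phantom tests therefore demonstrates correctness of the measurement chain
under its stated model, not clinical performance on patient data.

## Numerical choices and degenerate inputs

* Voxel indexing is 0-based; a voxel's world position is its center; the
  internal frame is RAS+ and every input is reoriented on load.
* Polygon ROIs rasterize by the voxel-center/even-odd rule; a polygon
  smaller than one voxel that covers no center is an error, not silently
  empty. Vertex orientation (cw/ccw) is irrelevant.
* The normal ROI must supply ≥ 100 valid voxels for a stable mode.
* `remaining_max ≤ 0` after the mucosa trim aborts with "mucosa shows no
  net enhancement" rather than producing a nonpositive threshold.
* Zero enhancing voxels is a valid result, not an error.
* The RECIST longest diameter is the maximum pairwise distance between
  in-mask voxel centers within one axial slice (convex-hull accelerated;
  brute force on degenerate point sets); the Macdonald perpendicular
  diameter is the extent of the projection onto the in-plane normal of
  the longest-diameter axis — a deterministic reading of "greatest
  perpendicular width". Diameters span the full lesion including the
  cavity, as caliper readings across cystic lesions do; pass an
  enhancing-only mask to measure enhancing extents instead.
* Bidimensional products are reported to 3 significant figures, the
  precision such caliper products are quoted at clinically.

## Problem sizes

Tests and the acceptance script use the 64×64×48 × 2 mm phantom grid:
large enough that registration is a genuine sub-voxel estimation problem
and region statistics have realistic counts (rim ≈ 800 voxels, normal ROI
≈ 1400, mucosa ≈ 190), small enough that the full suite — including 20
noise realizations of the complete pipeline and the eight-visit serial
workflow with per-visit registration — runs in a few minutes.

## Known limitations

* Rigid-only fusion: real serial scans can involve deformation (cavity
  collapse itself is non-rigid); the transferred baseline ROI absorbs
  modest mismatch only because it is drawn generously.
* The mode estimator's bin width must be adapted to float-valued data.
* The threshold comparison is strict `>`; data sitting exactly at the
  cut-off (possible with integer data) counts as non-enhancing unless
  `strict_greater=False`.
* No partial-volume modelling: a voxel is counted entirely or not at all.
* Non-enhancing tumor burden is invisible to this method by construction.
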