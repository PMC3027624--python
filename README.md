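# enhancevol

Volumetric response assessment of enhancing brain tumors from standard
pre- and post-contrast T1-weighted MRI.

Caliper-based response criteria (RECIST's longest diameter, the Macdonald
bidimensional product) measure across the whole lesion, so after surgery
they track the resection cavity's shape more than the tumor: a collapsing
cavity shrinks the calipers even while rim enhancement grows, and
T1-bright blood products mimic enhancement on the post-contrast scan.
`enhancevol` instead measures *enhancing tissue volume* directly:

1. rigidly fuse the pre-contrast scan onto the post-contrast grid and
   subtract, `S = Q − P`;
2. estimate the global brightness offset as the **mode** of `S` inside a
   user-drawn normal-parenchyma region (correction factor `c`) — MRI pixel
   values are not standardized, and this absorbs contrast-dose and scanner
   brightness differences between visits;
3. locate the **nasal mucosa** (a reliably enhancing reference structure)
   from a packaged atlas, trim the top 5% of its corrected values, and set
   the enhancement threshold `θ = 0.25 × max(remaining)`;
4. count tumor-ROI voxels with `S − c > θ`; enhancing volume =
   count × voxel volume.

The only manual step is gross outlining of the tumor and normal regions;
outlines drawn at baseline are transferred automatically to follow-up
scans after registration. Conventional RECIST/Macdonald measurements are
computed from the same masks for side-by-side comparison, and a phantom
generator reproduces every scenario the method targets (cavity collapse,
subacute blood, narrow-vs-generous outlines, threshold sensitivity) with
exact ground truth.

## Worked example

```python
import dataclasses
from enhancevol import AnalysisParams, quantify
from enhancevol.phantom import generate, scenario

spec = scenario("rim_baseline", seed=0)[0]          # cavity + enhancing rim
pre, post, truth, atlas = generate(spec)
result = quantify(pre, post, truth.tumor_narrow, truth.normal, atlas)
print(result.voxel_count, truth.enhancing_count)    # 800 800
print(result.volume_cm3)                            # 6.4
print(round(result.threshold.value, 2),             # 75.0
      result.correction.value)                      # 10.0
```

The pipeline recovers the constructed 800 enhancing rim voxels exactly
(6.4 cm³ at 2 mm isotropic voxels). The correction factor 10.0 is the
phantom's built-in global pre/post brightness offset, and the threshold is
25% of the trimmed corrected-mucosa maximum (mucosa contrast 300, hence
≈ 75). On the subacute-blood phantom — the cavity equally bright on both
scans — the same call returns 0 enhancing voxels, while a 40% threshold on
the rim phantom returns 347 voxels (only the rim's bright cavity-facing
layer), illustrating the threshold-sensitivity comparison.

The same analyses run from the shell:

```sh
enhancevol phantom rim_baseline --seed 0 --out fx
enhancevol measure --pre fx/pre.nii.gz --post fx/post.nii.gz \
    --tumor-roi fx/rois/tumor.nii.gz --normal-roi fx/rois/normal.nii.gz \
    --atlas fx/atlas --out results/
enhancevol serial --timepoint base_pre.nii base_post.nii \
    --timepoint fu_pre.nii fu_post.nii \
    --tumor-roi tumor.nii.gz --normal-roi normal.nii.gz \
    --atlas fx/atlas --out serial_results/
```

`measure` writes `report.json` (volume, threshold and correction
provenance, RECIST/Macdonald readings, full parameter set) plus the
enhancement mask as NIfTI; `serial` adds per-timepoint volumes with
absolute and percent change from baseline as JSON and CSV.

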