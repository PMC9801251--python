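# vtamap

Data-driven delineation of the dopaminergic **ventral tegmental area
(VTA)** from magnetization-transfer (MT) MRI, together with an
effort-based model of motivation and the cohort statistics that link
brain to behavior.

The VTA is a small bilateral midbrain nucleus and a major source of
dopamine. Its neuromelanin content — a by-product of catecholamine
synthesis — gives it contrast on MT-weighted imaging, but at ~400 µm
resolution its delineation has traditionally relied on subjective
manual tracing. `vtamap` implements a fully automated alternative and
everything needed to validate it without any scan data, for researchers
studying dopaminergic integrity in mood/anxiety (MA) populations versus
healthy controls (HC).

## What the pipeline does

1. **Enhancement image** — the voxelwise ratio of an MT acquisition to
   a pulse-free (non-MT) acquisition: `enh = MT / nonMT`. Voxels rich
   in macromolecules such as neuromelanin appear hyperintense.
2. **Mixture classification** — in-brain enhancement intensities are
   modeled as a finite Gaussian mixture fitted by
   expectation–maximization (implemented in this package, log-domain,
   multi-start). A 3-component fit separates cerebrospinal fluid,
   white matter and a neuromelanin-related class (highest mean); a
   4-component refinement inside the neuromelanin class splits the VTA
   (lower enhancement) from the neighboring substantia nigra (SN,
   higher enhancement — the control region).
3. **Anatomical constraints** — candidates are clipped to a midbrain
   mask and a maximal lateral distance from the sagittal midline, and
   reduced to the largest connected component per hemisphere.
4. **ROI metrics** — volume (mm³) and mean enhancement per nucleus,
   normalized against whole-brain volume; test–retest reliability via
   Dice overlap and the intraclass correlation ICC(A,1).
5. **Motivation model** — accept/reject choices over effort (3–70
   button presses) for reward ($0.25–$2.00) are modeled with a
   psychometric sigmoid on min–max normalized axes,

   `p(accept) = 1 / (1 + exp(−(r − e − bias) / σ))`,

   where `bias` translates the curve (motivational tone) and `σ` sets
   its gradient (reward sensitivity; small σ = near-binary choices).
   Parameters are MAP-fitted per subject and condition
   (external offers / internally generated effort) and z-scored.
6. **Cohort statistics** — Welch group comparisons of VTA volume,
   VTA intensity and SN intensity (specificity control), sex-adjusted
   regressions of VTA intensity on the behavioral parameters, and
   Spearman correlations with symptom scales.

Because no public scan data exist for this problem, the package ships a
first-class synthetic-data module: midbrain phantoms with planted
CSF/WM/VTA/SN tiers (SN above VTA) and exact ground-truth masks,
two-group cohorts with configurable effect sizes, and simulated trial
sets — every stage is validated against planted truth.

## Worked example

```python
from vtamap import (PhantomSpec, make_phantom, compute_enhancement,
                    AnatomicalConstraints, segment_vta_sn,
                    dice, roi_volume, roi_mean_intensity)

spec = PhantomSpec(noise_sd=0.01, seed=2)          # 64x64x48 @ 0.4 mm
mt, non_mt, truth = make_phantom(spec)
enh, valid = compute_enhancement(mt, non_mt, truth.masks["brain"])
constraints = AnatomicalConstraints(midbrain=truth.masks["midbrain"])
seg = segment_vta_sn(enh, valid, constraints, seed=2)

print("VTA Dice vs truth :", round(dice(seg.vta, truth.masks["vta"]), 3))
print("VTA volume (mm^3) :", round(roi_volume(seg.vta), 2))
print("mean enh VTA / SN :", round(roi_mean_intensity(seg.vta, enh), 4),
      "/", round(roi_mean_intensity(seg.sn, enh), 4))
```

prints

```
VTA Dice vs truth : 0.998
VTA volume (mm^3) : 19.39
mean enh VTA / SN : 1.0791 / 1.1217
```

i.e. at a realistic noise level the delineation recovers the planted
VTA almost voxel-perfectly, its volume matches the planted ~19 mm³
nucleus, and the recovered mean enhancement reproduces the planted
tiers — with SN above VTA, the ordering expected from the higher
dopamine-neuron density of SN.

The same stages are available from the shell:

```bash
vtamap simulate phantom --seed 2 --out phantom/
vtamap enhance --mt phantom/mt.nii.gz --non-mt phantom/non_mt.nii.gz \
       --brain-mask phantom/mask_brain.nii.gz --out enh.nii.gz
vtamap segment --enh enh.nii.gz --brain-mask phantom/mask_brain.nii.gz \
       --midbrain-mask phantom/mask_midbrain.nii.gz --seed 2 --out-dir seg/
vtamap run-all --config configs/demo.json --out-dir demo_out
```

`run-all` executes the whole simulated study — cohort, per-subject
phantoms, segmentation, metrics, trial simulation and fitting, and the
statistical battery — and writes a manifest with a content hash for
every output, so identical configs yield bit-identical runs.

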