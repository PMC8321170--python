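# petas3d — fully 3D active-surface PET tumor segmentation

`petas3d` delineates the biological tumor volume (BTV) on 3D PET images for
radiotherapy planning and quantitative imaging research. It implements a
fully three-dimensional, operator-independent segmentation method: a
localized region-based active surface, represented as a level set, whose
driving energy combines the standardized uptake value (SUV) with a prior
from a three-class discriminant-analysis (DA) tissue classifier. Because
clinical PET studies with consensus gold standards are rarely shareable,
the package also ships a synthetic PET phantom generator, so the entire
pipeline is runnable and testable out of the box.

## The model

The tumor surface *S* is the zero level set of a signed-distance field
φ (φ < 0 inside, region *R*<sub>in</sub>; φ ≥ 0 outside, *R*<sub>out</sub>).
It evolves to minimize

```
E = ∫_S  λ ( ∫_{R_in} χ_l(x,s) P̄_out(x) dx  +  ∫_{R_out} χ_l(x,s) P̄_in(x) dx )
       + (1−λ) ( ∫_{R_in} χ_l(x,s) (SUV(x) − u_l(s))² dx
               + ∫_{R_out} χ_l(x,s) (SUV(x) − v_l(s))² dx )  dS
```

where χ_l(x,s) indicates a spherical neighborhood of radius *l* = 3 voxels
around each surface point, u_l / v_l are the localized interior / exterior
SUV means over that neighborhood, and P̄_in / P̄_out are the local mean
lesion / background classification produced by the DA classifier
(λ = 0.01). The classifier is a three-class linear DA over 27-element
vectors from 3×3×3 voxel windows; windows fully outside the gold standard
are *background*, windows with 1–17 of their 27 voxels inside are
*border-line* (no prior penalty), and windows with 18 or more are *lesion*.
The prior term penalizes voxels that the surface and the classifier assign
to conflicting sides. Because the surface is implicit, it splits and merges
freely: disjoint lesions and toroidal uptake patterns are segmented from a
single ellipsoid initialization, and evolution stops naturally when the
voxel sign pattern stabilizes — no iteration count needs tuning.

Evaluation follows the standard seven measures: sensitivity, specificity,
positive predictive value, accuracy, Dice similarity coefficient (DSC),
Hausdorff distance (HD) and Pearson correlation.

## Worked example

A self-contained run on the default synthetic study — a 64×64×48 grid at
the clinical voxel size 2.73 × 2.73 × 3.27 mm, a 25 mm spherical tumor at
8:1 tumor-to-background uptake, 4 mm PSF blur and 5 % Gaussian noise:

```python
from petas3d import PhantomSpec
from petas3d.pipeline import RunConfig, run

summary = run(RunConfig(out_dir="demo_run", seed=1,
                        phantom_spec=PhantomSpec(seed=1)))
print(summary["classifier_holdout"]["accuracy"])  # 0.9972288986285875
print(summary["segmentation"])
# {'iterations': 28, 'converged': True, 'mask_voxels': 2681,
#  'volume_ml': 65.33860542299999}
print(summary["metrics"]["dsc"], summary["metrics"]["hd"])
# 0.9994404029099049 1.0
```

The classifier labels held-out windows with 99.7 % accuracy; the surface
converges after 28 iterations (flip-fraction criterion, not an iteration
cap) to a 65.3 mL volume that overlaps the gold mask at DSC 0.9994 with a
Hausdorff distance of 1 voxel. All artifacts (NIfTI volumes and masks, the
serialized model, the per-iteration energy history, the metrics report)
land in `demo_run/`.

The same workflow is available from the shell:

```
petas3d phantom --shape sphere --seed 1 --out-vol vol.nii.gz --out-mask gold.nii.gz
petas3d train   --vol vol.nii.gz --gold gold.nii.gz --seed 1 --out model.json
petas3d segment --vol vol.nii.gz --model model.json --roi-box 10,10,8,54,54,40 \
                --out btv.nii.gz --history history.csv
petas3d evaluate --pred btv.nii.gz --gold gold.nii.gz
petas3d run --config run.yaml
```

## Layout

- `petas3d.volume_io` — NIfTI I/O, grid conventions, SUV conversion
- `petas3d.phantom` — synthetic PET phantoms with exact gold masks
- `petas3d.tissue_sampling` — 3×3×3 window extraction and labelling
- `petas3d.da_classifier` — linear DA training, CV, volume classification
- `petas3d.presegmentation` — ROI → seed → ellipsoid initialization
- `petas3d.active_surface` — energy, level-set evolution, convergence
- `petas3d.evaluation` — confusion rates, DSC, Hausdorff, Pearson
- `petas3d.pipeline` — end-to-end orchestration from one config

See `docs/methods.md` for the numerical design and its limitations.
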