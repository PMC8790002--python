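# livreg

Segmentation- and landmark-guided multi-modal liver registration with
spring-model regularization, plus voxel dosimetry for selective internal
radiation therapy (SIRT).

## The problem

SIRT plans and verifies the absorbed dose of ⁹⁰Y microspheres from several
image series that live in different spaces: the ⁹⁹ᵐTc-MAA SPECT/CT of the
pre-treatment simulation (the reference space for dosimetry), plus
diagnostic and post-treatment CT and MR volumes that carry the lesion
delineations. Lesion contours only become usable for dose estimation after a
liver registration that is accurate both at the organ outline and at the
lesions inside it. Non-contrast CT and artefact-prone MR make pure
intensity-driven registration fragile; liver segmentations and small
landmark structures (lesions, vessel knots, surgical clips) are the guidance
that stabilizes it.

`livreg` implements that workflow for researchers in medical image analysis
and radionuclide dosimetry:

* **three registration pipelines** sharing one affine + non-rigid skeleton:
  intensity-only (`image`), guided by liver segmentations (`seg`), and
  guided by a two-class liver + landmark map (`seg_lm`);
* **the combined non-rigid loss** `w_I·L_I + w_S·L_S + L_R`, with
  `L_I = −MI` (mutual information of the intensities), `L_S` the sum of
  squared differences of the (softly warped) segmentation channels, and
  `L_R` a spring model: every pair of face-adjacent voxels is connected by a
  spring at its grid rest length, `L_R = k · Σ (‖(p_i+d_i)−(p_j+d_j)‖ −
  ‖p_i−p_j‖)²`, which opposes topology-violating deformations;
* **evaluation statistics**: Dice coefficient (DSC), mean surface distance
  (MSD), landmark mass-center distances (MCD), their combination
  `RMSD = √((MSD² + Σᵢ MCDᵢ²)/(1+N))` per registration and the root mean
  square of RMSDs (RRMSD) per batch, plus grid search of `(w_I, w_S)`
  minimizing RRMSD;
* **voxel dosimetry** on the SPECT: fractional uptake normalization within
  the liver contour, local-deposition dose maps, per-lesion mean dose,
  V70/V100 and cumulative DVHs, and reference-vs-registered comparison
  statistics (relative mean-dose differences, V70/V100 differences,
  quartiles, Pearson correlations);
* **a phantom module** generating seed-deterministic synthetic studies
  (pseudo-CT/pseudo-MR pairs with nonlinear cross-modality intensity
  relations, multi-lobed livers, landmark spheres, SPECT-like counts) with
  exactly known affine + smooth-warp ground truth, since clinical SIRT data
  cannot be redistributed.

## Worked example

```python
from livreg import LiverRegistration, LossWeights
from livreg.evaluation import evaluate_registration, dsc
from livreg.phantom import PhantomConfig, generate_phantom
from livreg.transform import warp

study = generate_phantom(PhantomConfig(seed=7))      # 64³ voxels, 3 mm grid
model = LiverRegistration.from_study(study, mode="seg_lm")
result = model.fit(LossWeights(w_I=1.0, w_S=1.0, rigidity_k=0.05))
print(result.summary())

warped_liver = result.warp_mask(study.floating_liver)
report = evaluate_registration(
    warped_liver, study.reference_liver,
    [result.warp_mask(m) for m in study.floating_landmarks],
    study.reference_landmarks)
print(f"liver DSC {dsc(warped_liver, study.reference_liver):.3f}  "
      f"RMSD {report.rmsd_mm:.2f} mm")
```

Output of this exact snippet:

```
Liver registration results
==========================================
guidance mode        : seg_lm
weights              : w_I=1, w_S=1, k=0.05
converged            : False
affine translation mm: [-1.01 -8.68 -8.93]
affine matrix        :
[[ 0.985   0.0671 -0.0436]
 [-0.0627  1.0322  0.0339]
 [ 0.0701 -0.0287  0.984 ]]
field |d| (mm)       : median 12.44, max 19.25
min Jacobian det     : 0.463
final loss           : total=512.7 (L_I=-0.6647, L_S=477.5, L_R=35.91)
liver DSC 0.985  RMSD 0.54 mm
```

The affine stage recovered the simulated pose change, the non-rigid stage
reduced the landmark misalignment left by the smooth warp (RMSD 0.54 mm on
a 3 mm grid), and the spring term kept the deformation fold-free (positive
Jacobian). `converged: False` only records that the iteration cap, not the
loss tolerance, ended the final level.

The same pipelines are available from a shell:

```bash
livreg simulate --config phantom.yaml --out study/
livreg register --ref study/reference.nii.gz --flo study/floating.nii.gz \
    --ref-labels study/reference_liver.nii.gz \
    --flo-labels study/floating_liver.nii.gz --mode seg --out reg/
livreg evaluate --ref-liver study/reference_liver.nii.gz \
    --warped-liver reg/warped_labels.nii.gz --out report.json
livreg dose --spect study/spect_counts.nii.gz \
    --liver study/reference_liver.nii.gz --lesions lesions/ \
    --activity-gbq 1.8 --out dose/
```

## Layout

| module | contents |
| --- | --- |
| `livreg.grid` | `VolumeGrid`, `Image3D`, `LabelMap3D` containers |
| `livreg.io` | NIfTI read/write, affine JSON, grid resampling |
| `livreg.transform` | affine transforms, displacement fields, warping |
| `livreg.similarity` | joint histograms, mutual information, segmentation SSD |
| `livreg.registration` | spring energy, affine + non-rigid stages, `LiverRegistration` model |
| `livreg.evaluation` | DSC, MSD, MCD, RMSD, RRMSD, weight grid search |
| `livreg.dosimetry` | fractional uptake, local-deposition dose, DVH, comparisons |
| `livreg.phantom` | synthetic study generator |
| `livreg.cli` | `livreg` command-line entry point |

See `docs/methods.md` for the modelling choices and their rationale.
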