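# Methods

This note documents the models, numerical choices and limitations of
`livreg`: what the registrations optimize, what the synthetic studies
emulate (and what they do not), and where the design was genuinely open.

## Registration model

All geometry is world millimeters on axis-aligned grids; voxel index `i`
sits at `origin + i·spacing`. Transforms follow the pull-back convention:
an affine or displacement field maps *reference* points into *floating*
space, and warping evaluates `warped(x) = floating(x + d(x))`, so warped
volumes live on the reference grid. Out-of-support samples fill with 0 and
are excluded from similarity regions, avoiding boundary bias.

### Affine stage

Twelve degrees of freedom (matrix + translation, orientation-preserving).

* **Intensity mode** maximizes mutual information of the two intensity
  distributions, estimated from a dense 32×32 joint histogram with hard
  binning. MI is not smoothly differentiable through that estimator, so the
  search is derivative-free (Powell) over a
  translation/rotation/scale/shear parameterization centered on the
  intensity centroid, in a 3-level multi-resolution pyramid (factor 2).
* **Segmentation modes** minimize the sum of squared differences between
  the reference segmentation channels and the affinely warped floating
  channels (channels slightly Gaussian-blurred, σ = 1 voxel, to smooth the
  SSD landscape at voxel scale). This objective has an analytic gradient in
  the affine parameters, so the fit is L-BFGS in a parameterization
  centered on the mask centroid with matrix variables scaled by the mask
  radius — without that scaling the matrix directions carry ~100× the
  curvature of the translations and quasi-Newton steps stall. Because the
  contour SSD can have rotational local minima, the fit is multi-start:
  centroid translation with identity matrix, a closed-form moment
  (centroid + principal axes) alignment, and coarse-level restarts from
  ±8° single-axis rotations; the candidate with the lowest final SSD wins.

### Non-rigid stage

A dense per-voxel displacement field, initialized by densifying the affine
(`d(x) = A·x + t − x`), minimizes

    w_I · L_I + w_S · L_S + L_R

* `L_I = −MI(reference, warped floating)`, reported from the hard-binned
  histogram within a region of interest (the dilated liver mask union by
  default, 12 mm dilation).
* `L_S = Σ_channels Σ_voxels (ref_c − warped_c)²` on one binary channel per
  foreground class — a single liver channel in `seg` mode, liver +
  landmark channels in `seg_lm` mode. Channels are warped with linear
  interpolation so the loss is continuous in the field; outputs are
  hardened with nearest-neighbor only at the end. Channels are weighted
  equally; a per-channel weight is deliberately not exposed because equal
  weighting is the documented behavior of the guided modes.
* `L_R = k · Σ_pairs (‖(p_i+d_i) − (p_j+d_j)‖ − ‖p_i−p_j‖)²` over
  6-connected voxel pairs, each unordered pair once, spacing-aware rest
  lengths. The exact distance-change form is used for both the energy and
  its analytic gradient (no small-displacement linearization). The spring
  acts on the *total* field including the affine initialization, so a pure
  scaling is (mildly) penalized; the weight search compensates. A uniform
  translation is exactly free; global rotations of the deformed points
  leave the energy invariant to numerical tolerance.

**Optimizer.** Steepest descent with Armijo backtracking in a 3-level
pyramid (factor 2), field upsampled between levels with *edge-extrapolating*
interpolation (zero-fill extrapolation would cut discontinuities into the
field at the volume boundary and create spurious folds). The first trial
step is scaled to move at most half a voxel. Acceptance always tests the
true (hard-histogram) total loss, so accepted steps never increase it — the
monotone-trace contract. Convergence: relative loss change < 1e-4 over 5
consecutive iterations, at most 60 iterations per level (the `converged`
flag records which of the two ended the run).

The MI gradient uses a smoothed surrogate: the joint density is Gaussian
smoothed (σ = 1 bin), the log-likelihood-ratio table
`L(a,b) = ln p(a,b) − ln p_a(a) − ln p_b(b)` is differentiated along the
floating-intensity axis, sampled per voxel, and multiplied by the warped
intensity gradient. Finite differences of the hard histogram would be far
too noisy. The similarity gradient is additionally smoothed with σ = 1
voxel before adding the (analytic) spring gradient — a stabilization, not a
regularizer; the spring term is the model's topology guard. Folding is
*not* enforced against: the minimum Jacobian determinant of `x + d(x)` is
computed as a diagnostic and logged when non-positive.

### Default weights

`w_I = 1, w_S = 1, k = 0.05`. `L_S` is a raw voxel-count-scale sum, so
`w_S = 1` makes segmentation guidance dominant where masks disagree —
intended for the guided modes. `k = 0.05` keeps the deformation fold-free
on the synthetic studies (minimum Jacobian ≈ 0.4–0.8) while leaving the
springs soft enough to track several-mm local shifts. These are defaults,
not claims of optimality; the grid search (`evaluation.grid_search_weights`)
is the principled way to choose them for a dataset, mirroring how such
hyper-parameters are tuned on training cases in practice. Ties break toward
smaller `w_S`, then smaller `w_I` (prefer less guidance at equal
performance), and the default search grids are log-spaced and include 0,
because an all-zero optimum (affine-only is best) is a legitimate outcome.

## Evaluation statistics

* **DSC** `2|A∩B|/(|A|+|B|)`; two empty masks define 1.0 with a warning.
* **MSD**: surface voxels are foreground voxels with a 6-connected
  background neighbor; the metric averages nearest-surface distances in
  *both* directions (the one-directional variant is not a pseudo-metric and
  the direction would be an arbitrary choice), voxel-center to voxel-center
  without sub-voxel contour extraction.
* **RMSD** `√((MSD² + Σ MCDᵢ²)/(1+N))`; with no landmarks it reduces to
  MSD. **RRMSD** is the root mean square of a batch's RMSDs.
* Landmark **MCD** is the distance of foreground centroids — independent of
  shape and volume changes, which is what makes it usable across
  modalities where a lesion's apparent extent differs.

## Dosimetry

The ⁹⁹ᵐTc-MAA SPECT surrogate's counts are normalized within the liver
contour to a fractional uptake map (`Σ f_v = 1` inside, 0 outside). The
local deposition model assigns each voxel the energy of its fractional
activity share:

    dose_v [Gy] = A [GBq] · C [J/GBq] · f_v / (ρ [kg/L] · V_voxel [L])

Defaults: `C = 49.67 J/GBq` (⁹⁰Y total emitted energy per unit activity)
and `ρ = 1.06 kg/L` (soft tissue); both configurable, as is the injected
activity. Energy conservation (`Σ dose·mass = A·C`) holds to 1e-6
relative by construction and is asserted in tests. Per-lesion statistics:
mean dose, V70/V100 (volume percentage at ≥ 70/100 Gy), cumulative DVH on
101 thresholds from 0 to the lesion maximum. Comparisons between reference
and registered lesion sets report `(D_f − D_r)/D_r` in percent for mean
dose (the only reading of "relative difference" that is actually
relative), V70/V100 differences in percentage points, quartiles, and
Pearson correlations. Lesion masks are resampled to the SPECT grid with
nearest neighbor before statistics; dose is always computed on the SPECT
grid.

## Synthetic studies

The phantom generator stands in for clinical SIRT data, which cannot be
redistributed. It emulates the *statistical structure* the method relies
on, not anatomy:

* **Liver**: a union of ellipsoidal lobes with a strict size hierarchy (one
  dominant lobe, one medium lobe, 1–2 small bumps), Gaussian-smoothed and
  thresholded — one 6-connected component occupying ~10–17% of a 64³,
  3 mm field of view. The hierarchy matters beyond realism: unions of
  similar-sized ellipsoids admit alternative affine matches of their own
  outline (affine maps send ellipsoids to ellipsoids), which makes the
  pose unidentifiable from the contour.
* **Landmarks**: spheres (default radius 7.5 mm) strictly inside the liver
  with ≥ 1.5-voxel margin, pairwise disjoint. Lesion size distribution in
  the clinic is broad; the radius is a config knob, not a modeled
  distribution.
* **Ground truth**: `T(x) = A·x + t + u(x)` with `A, t` sampled uniformly
  within bounds (default ±10 mm translation, ±5° rotation, ±5% scale,
  about the domain center) and `u` a per-axis band-limited Gaussian random
  field (σ = 40 mm default — inter-session liver deformation is dominated
  by breathing state and positioning and is smooth at the several-cm
  scale) scaled to a maximum amplitude (default 4 mm). The
  amplitude < smoothness constraint keeps `T` fold-free. The warp's
  *apparent affine component* — the least-squares affine fit of its
  normal-projected values over the liver boundary shell — is folded into
  `(A, t)`, because a contour-driven registration only observes boundary
  motion along the surface normal; with this split the recorded affine is
  exactly what an ideal segmentation-guided affine stage can see, making
  "the affine stage recovers the truth" a well-posed statement. The dense
  field `T − id` is recorded exactly on the reference grid.
* **Floating volumes** are rendered analytically in floating space: the
  smooth shape field and sphere membership are evaluated at `T⁻¹(y)`
  (fixed-point inversion of the affine + warp), then the modality model is
  applied with its own noise stream — the two sides are never intensity
  remaps of one voxel array.
* **Modalities**: pseudo-CT is a monotone per-class level map + Gaussian
  noise; pseudo-MR uses class levels that are *not* an affine function of
  the CT levels (liver brightest, lesions darker) times a smooth
  multiplicative bias field, so the cross-modality joint intensity
  relation is nonlinear and MI is genuinely exercised.
* **SPECT**: uniform background activity in the liver, a configurable
  lesion-to-liver uptake ratio (default 5), Gaussian PSF blur (default
  12 mm FWHM), Poisson sampling.

What passing tests on these phantoms do **not** show: robustness to real
CT/MR texture, scanner artefacts beyond a smooth bias field, respiratory
motion, sliding at the liver boundary, segmentation errors from an actual
CNN (masks here are exact by construction), or clinical lesion-shape
variability. Results on the phantoms bound the method's best case, not its
clinical accuracy.

## Problem sizes

Default studies are 64³ voxels at 3 mm — the working resolution of the
liver-segmentation CNNs this workflow is built around, and fine enough that
half a voxel (1.5 mm) is a meaningful accuracy target. The batch
experiments in `scripts/acceptance.py` use 48³ phantoms for the
multi-pipeline comparison and 32³ for the 3×3 weight grid search; these
sizes keep a full from-scratch reproduction in the minutes range on one
CPU while preserving every qualitative result (guidance ordering, non-rigid
improvement, grid-search behavior).

## Degenerate inputs and edge cases

* Constant images fall back to a single histogram bin (MI = 0) with a
  warning; empty similarity regions raise.
* Label maps refuse linear interpolation; soft warping is channel-wise.
* Empty masks raise in MSD/MCD; DSC of two empty masks is 1.0.
* Oblique NIfTI direction matrices are resampled to the nearest
  axis-aligned grid on load, with a warning.
* NaN voxels are rejected on load with their indices listed.
* Non-finite losses or gradients abort the non-rigid stage with a
  diagnostic rather than silently continuing.

## Known limitations

* Contour-driven affine recovery has an intrinsic identifiability floor:
  the normal-projected decomposition removes the warp's *linearized*
  affine signal from the boundary, but the segmentation SSD is nonlinear
  in boundary displacement, so a 6 mm warp leaves the SSD optimum
  typically ≲1 mm — occasionally 2–3 mm — away from the recorded affine,
  independent of the optimizer (verified by refitting from the truth
  itself). Sub-voxel recovery claims therefore hold in the typical case,
  not uniformly over warp realizations.
* The non-rigid optimizer is first-order; very large `w_S` with tiny `k`
  can still fold the field (the model only penalizes, never forbids,
  topology violation — the Jacobian diagnostic reports it).
* The spring energy on the total field slightly penalizes genuine global
  scaling; for strongly scaled pairs an affine-only run
  (`skip_nonrigid`) or a larger `w_I`/`w_S` may be preferable.
* MI uses hard binning (32 bins); no Parzen or normalized-MI variants.
* Grids are axis-aligned; oblique acquisitions are resampled on load
  rather than handled natively. DICOM series are out of scope (NIfTI
  only).
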