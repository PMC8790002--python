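"""Synthetic liver registration studies with known ground-truth deformation.

Clinical SIRT registration data (non-contrast CT, artefact-prone MR, MAA
SPECT, manual landmark and liver delineations) cannot be redistributed, so
this module generates seed-deterministic stand-ins that reproduce the
*statistical structure* the registration relies on:

* a smooth multi-lobed liver (union of overlapping ellipsoids, smoothed and
  thresholded) occupying a plausible share of the field of view;
* spherical landmarks (lesions, clips, vessel knots in the clinical data)
  strictly inside the liver and pairwise disjoint;
* a known reference→floating deformation, composed of a bounded random
  affine and a band-limited smooth warp, recorded exactly;
* cross-modality intensity mappings (pseudo-CT vs pseudo-MR with a
  multiplicative bias field) whose joint relation is nonlinear, so mutual
  information is genuinely exercised;
* a SPECT-like count map concentrating uptake in the lesions, blurred by a
  Gaussian PSF and Poisson-sampled.

The floating volumes are rendered analytically in floating space (geometry
membership evaluated at the inverse-deformed position), so the two
modalities are never plain intensity remaps of one voxel array.

The smooth warp is mean-centred over the liver and its mean displacement is
folded into the affine translation; this makes the affine/non-rigid split
of the ground truth unique.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .grid import Image3D, LabelMap3D, VolumeGrid
from .transform import AffineTransform, DisplacementField

logger = logging.getLogger(__name__)

__all__ = [
    "AffineMagnitude",
    "PhantomConfig",
    "PhantomStudy",
    "generate_phantom",
    "simulate_modality",
    "simulate_spect",
]


@dataclass(frozen=True)
class AffineMagnitude:
    """Bounds for the random ground-truth affine (sampled uniformly within)."""

    translation_mm: float = 10.0
    rotation_deg: float = 5.0
    scale: float = 0.05

    def __post_init__(self):
        if self.translation_mm < 0 or self.rotation_deg < 0 or not (0 <= self.scale < 1):
            raise ValueError("invalid affine magnitude bounds")


@dataclass(frozen=True)
class PhantomConfig:
    """Knobs of one synthetic study; identical configs give identical studies."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_landmarks: int = 3
    landmark_radius_mm: float = 7.5
    affine_magnitude: AffineMagnitude = dc_field(default_factory=AffineMagnitude)
    warp_amplitude_mm: float = 4.0
    warp_smoothness_mm: float = 40.0
    modality: str = "pseudo_mr"
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing_mm) or self.landmark_radius_mm <= 0:
            raise ValueError("lengths must be positive")
        if self.n_landmarks < 0:
            raise ValueError("n_landmarks must be >= 0")
        if self.warp_amplitude_mm < 0 or self.warp_smoothness_mm <= 0:
            raise ValueError("warp parameters must be nonnegative / positive")
        if self.warp_amplitude_mm >= self.warp_smoothness_mm:
            raise ValueError(
                "warp_amplitude_mm must stay below warp_smoothness_mm "
                "(keeps the ground-truth warp fold-free)"
            )
        if self.modality not in ("pseudo_ct", "pseudo_mr"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class PhantomStudy:
    """One synthetic reference/floating pair with its exact ground truth."""

    reference_image: Image3D
    floating_image: Image3D
    reference_liver: LabelMap3D
    floating_liver: LabelMap3D
    reference_landmarks: list[LabelMap3D]
    floating_landmarks: list[LabelMap3D]
    spect_counts: Image3D
    truth_affine: AffineTransform
    truth_field: DisplacementField
    seed: int

    def reference_labelmap(self, with_landmarks: bool = True) -> LabelMap3D:
        return _combine_labels(self.reference_liver, self.reference_landmarks, with_landmarks)

    def floating_labelmap(self, with_landmarks: bool = True) -> LabelMap3D:
        return _combine_labels(self.floating_liver, self.floating_landmarks, with_landmarks)


def _combine_labels(liver: LabelMap3D, landmarks: list[LabelMap3D], with_landmarks: bool) -> LabelMap3D:
    labels = (liver.labels > 0).astype(np.int32)
    if with_landmarks:
        for lm in landmarks:
            labels[lm.labels > 0] = 2
    return LabelMap3D(liver.grid, labels)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _liver_shape_field(grid: VolumeGrid, rng: np.random.Generator) -> np.ndarray:
    """Smooth scalar field whose >0.5 level set is the multi-lobed liver."""
    extent = np.array(grid.shape) * np.array(grid.spacing_mm)
    center = np.asarray(grid.origin_mm) + extent / 2
    pts = grid.world_points()
    # A strict lobe-size hierarchy (one dominant lobe, one medium lobe, small
    # surface bumps) mimics the right/left-lobe anatomy and, importantly,
    # makes the contour pose-identifiable: similar-sized interchangeable
    # lobes would admit alternative affine matches of the outline.
    union = np.zeros(grid.shape, dtype=bool)
    dom_center = center + rng.uniform(-0.05, 0.05, 3) * extent
    dom_semi = rng.permutation(np.array([0.34, 0.29, 0.24])) * extent \
        * rng.uniform(0.92, 1.08, 3)
    lobes = [(dom_center, dom_semi)]
    mid_dir = rng.standard_normal(3)
    mid_dir /= np.linalg.norm(mid_dir)
    mid_semi = rng.uniform(0.17, 0.21, 3) * extent
    lobes.append((dom_center + mid_dir * dom_semi * 0.8, mid_semi))
    for _ in range(int(rng.integers(1, 3))):
        bump_dir = rng.standard_normal(3)
        bump_dir /= np.linalg.norm(bump_dir)
        bump_semi = rng.uniform(0.10, 0.13, 3) * extent
        lobes.append((dom_center + bump_dir * dom_semi * 0.9, bump_semi))
    for lobe_center, semi in lobes:
        lobe_center = np.clip(lobe_center, center - 0.30 * extent, center + 0.30 * extent)
        rel = (pts - lobe_center) / np.minimum(semi, extent * 0.35)
        union |= np.einsum("...i,...i->...", rel, rel) <= 1.0
    sigma_vox = 2.0
    fieldv = ndimage.gaussian_filter(union.astype(float), sigma_vox)
    return fieldv


def _place_landmarks(
    liver: np.ndarray, grid: VolumeGrid, n: int, radius_mm: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Sphere centers (world mm) strictly inside the liver, pairwise disjoint."""
    if n == 0:
        return []
    margin = radius_mm + 1.5 * max(grid.spacing_mm)
    depth = ndimage.distance_transform_edt(liver, sampling=grid.spacing_mm)
    candidates = np.argwhere(depth > margin)
    if candidates.size == 0:
        raise ValueError("liver too small to host any landmark of this radius")
    centers: list[np.ndarray] = []
    min_sep = 2 * radius_mm + max(grid.spacing_mm)
    for _ in range(500):
        if len(centers) == n:
            break
        c = grid.index_to_world(candidates[rng.integers(len(candidates))])
        if all(np.linalg.norm(c - other) > min_sep for other in centers):
            centers.append(c)
    if len(centers) < n:
        raise ValueError(
            f"could only place {len(centers)}/{n} disjoint landmarks after bounded retries"
        )
    return centers


# ---------------------------------------------------------------------------
# ground-truth deformation
# ---------------------------------------------------------------------------


def _random_affine(bounds: AffineMagnitude, center: np.ndarray, rng: np.random.Generator) -> AffineTransform:
    from scipy.spatial.transform import Rotation

    t = rng.uniform(-bounds.translation_mm, bounds.translation_mm, 3)
    rot = rng.uniform(-bounds.rotation_deg, bounds.rotation_deg, 3)
    scale = rng.uniform(1 - bounds.scale, 1 + bounds.scale, 3)
    m = Rotation.from_euler("zyx", rot, degrees=True).as_matrix() @ np.diag(scale)
    return AffineTransform(m, center - m @ center + t)


def _random_warp(
    grid: VolumeGrid, amplitude_mm: float, smoothness_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited zero-boundary random displacement (nx, ny, nz, 3), mm."""
    if amplitude_mm == 0:
        return np.zeros(grid.shape + (3,))
    sigma_vox = [smoothness_mm / s for s in grid.spacing_mm]
    comps = []
    for _ in range(3):
        noise = rng.standard_normal(grid.shape)
        comps.append(ndimage.gaussian_filter(noise, sigma_vox))
    warp = np.stack(comps, axis=-1)
    peak = np.abs(warp).max()
    if peak > 0:
        warp *= amplitude_mm / peak
    return warp


def _interp_field(warp: np.ndarray, grid: VolumeGrid, points_mm: np.ndarray) -> np.ndarray:
    """Sample a gridded vector field (mm) at arbitrary world points."""
    idx = ((points_mm - np.asarray(grid.origin_mm)) / np.asarray(grid.spacing_mm)).T
    out = np.empty_like(points_mm)
    for k in range(3):
        out[:, k] = ndimage.map_coordinates(warp[..., k], idx, order=1, mode="nearest")
    return out


def _invert_deformation(
    affine: AffineTransform, warp: np.ndarray, grid: VolumeGrid, points_mm: np.ndarray,
    n_iter: int = 20,
) -> np.ndarray:
    """Fixed-point inverse of T(x) = A x + t + u(x) at the given points."""
    inv = affine.inverse()
    x = inv.apply(points_mm)
    for _ in range(n_iter):
        u = _interp_field(warp, grid, x)
        x_new = inv.apply(points_mm - u)
        if np.max(np.abs(x_new - x)) < 1e-4:
            x = x_new
            break
        x = x_new
    return x


# ---------------------------------------------------------------------------
# modality and SPECT simulation
# ---------------------------------------------------------------------------

_CT_LEVELS = {0: 20.0, 1: 100.0, 2: 150.0}
_MR_LEVELS = {0: 30.0, 1: 200.0, 2: 80.0}  # deliberately non-monotone vs CT


def simulate_modality(
    geometry_labels: LabelMap3D,
    modality: str,
    noise_sd: float,
    seed: int,
) -> Image3D:
    """Render class geometry as a pseudo-CT or pseudo-MR intensity volume.

    Pseudo-CT is a monotone per-class level map plus additive Gaussian
    noise.  Pseudo-MR uses class levels that are *not* an affine remap of
    the CT levels, modulated by a smooth multiplicative bias field — so the
    cross-modality joint intensity relation is nonlinear and favors mutual
    information over intensity-difference similarity.
    """
    if modality == "pseudo_ct":
        levels = _CT_LEVELS
    elif modality == "pseudo_mr":
        levels = _MR_LEVELS
    else:
        raise ValueError(f"unknown modality {modality!r}")
    rng = np.random.default_rng(seed)
    labels = geometry_labels.labels
    vals = np.zeros(labels.shape, dtype=float)
    for lab, level in levels.items():
        vals[labels == lab] = level
    extra = set(np.unique(labels)) - set(levels)
    if extra:
        raise ValueError(f"labels {sorted(extra)} have no intensity level")
    if modality == "pseudo_mr":
        bias_noise = rng.standard_normal(labels.shape)
        sigma_vox = [30.0 / s for s in geometry_labels.grid.spacing_mm]
        bias = ndimage.gaussian_filter(bias_noise, sigma_vox)
        peak = np.abs(bias).max()
        if peak > 0:
            bias = 1.0 + 0.3 * bias / peak
        else:
            bias = np.ones_like(bias)
        vals *= bias
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, labels.shape)
    return Image3D(geometry_labels.grid, vals)


def simulate_spect(
    landmark_masks: list[LabelMap3D],
    liver_mask: LabelMap3D,
    lesion_to_liver_ratio: float = 5.0,
    psf_fwhm_mm: float = 12.0,
    seed: int = 0,
    background_counts: float = 20.0,
    poisson: bool = True,
) -> Image3D:
    """MAA-SPECT-like counts: lesion-concentrated uptake, PSF blur, Poisson noise.

    The noise-free map is ``background_counts`` per liver voxel and
    ``ratio`` times that inside lesions, blurred by a Gaussian of the given
    FWHM.  Counts are nonnegative everywhere.
    """
    if lesion_to_liver_ratio <= 0:
        raise ValueError("lesion_to_liver_ratio must be positive")
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be nonnegative")
    inside = liver_mask.labels > 0
    if not inside.any():
        raise ValueError("empty liver mask")
    counts = np.zeros(liver_mask.grid.shape)
    counts[inside] = background_counts
    for lm in landmark_masks:
        counts[(lm.labels > 0) & inside] = background_counts * lesion_to_liver_ratio
    if psf_fwhm_mm > 0:
        sigma_mm = psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sigma_vox = [sigma_mm / s for s in liver_mask.grid.spacing_mm]
        counts = ndimage.gaussian_filter(counts, sigma_vox)
    if poisson:
        counts = np.random.default_rng(seed).poisson(counts).astype(float)
    return Image3D(liver_mask.grid, np.maximum(counts, 0.0))


# ---------------------------------------------------------------------------
# the study generator
# ---------------------------------------------------------------------------


def generate_phantom(config: PhantomConfig) -> PhantomStudy:
    """Build one complete synthetic study from a config (seed-deterministic)."""
    grid = VolumeGrid(config.grid_shape, config.spacing_mm)
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(6)
    rng_shape = np.random.default_rng(seeds[0])
    rng_affine = np.random.default_rng(seeds[1])
    rng_warp = np.random.default_rng(seeds[2])
    sub_seed = root.generate_state(4, dtype=np.uint32)

    # reference geometry
    shape_field = _liver_shape_field(grid, rng_shape)
    ref_liver_arr = shape_field > 0.5
    frac = ref_liver_arr.mean()
    if not (0.05 < frac < 0.5):
        logger.warning("liver occupies %.1f%% of the volume", 100 * frac)
    centers = _place_landmarks(ref_liver_arr, grid, config.n_landmarks,
                               config.landmark_radius_mm, rng_shape)
    pts = grid.world_points()
    ref_landmarks = []
    for c in centers:
        d2 = np.sum((pts - c) ** 2, axis=-1)
        ref_landmarks.append(LabelMap3D(grid, (d2 <= config.landmark_radius_mm**2).astype(np.uint8)))
    ref_liver = LabelMap3D(grid, ref_liver_arr.astype(np.uint8))

    # ground truth deformation T(x) = A x + t + u(x), reference -> floating
    extent = np.array(grid.shape) * np.array(grid.spacing_mm)
    domain_center = np.asarray(grid.origin_mm) + extent / 2
    affine = _random_affine(config.affine_magnitude, domain_center, rng_affine)
    warp = _random_warp(grid, config.warp_amplitude_mm, config.warp_smoothness_mm, rng_warp)
    if config.warp_amplitude_mm > 0:
        # Make the affine/non-rigid split identifiable: fold the warp's
        # apparent affine component into the recorded affine.  A
        # segmentation-driven stage only sees boundary motion along the
        # surface normal, so the component is fit by least squares of the
        # normal-projected warp over the liver boundary shell; the recorded
        # warp then carries no affine signal visible to the liver contour.
        shell = ndimage.binary_dilation(ref_liver_arr) ^ ndimage.binary_erosion(ref_liver_arr)
        normals = np.stack(np.gradient(shape_field, *grid.spacing_mm), axis=-1)[shell]
        norms = np.linalg.norm(normals, axis=1)
        keep = norms > 1e-9
        normals = normals[keep] / norms[keep, None]
        shell_pts = pts[shell][keep]
        u_shell = warp[shell][keep]
        design = np.concatenate(
            [(normals[:, :, None] * shell_pts[:, None, :]).reshape(len(normals), 9), normals],
            axis=1,
        )
        beta, *_ = np.linalg.lstsq(design, np.sum(normals * u_shell, axis=1), rcond=None)
        b_mat, b_vec = beta[:9].reshape(3, 3), beta[9:]
        warp = warp - (pts.reshape(-1, 3) @ b_mat.T + b_vec).reshape(grid.shape + (3,))
        peak = np.abs(warp).max()
        if peak > config.warp_amplitude_mm:
            warp *= config.warp_amplitude_mm / peak  # scaling keeps the normal LS residual property
        affine = AffineTransform(affine.matrix + b_mat, affine.translation + b_vec)
    total = affine.apply(pts.reshape(-1, 3)) + warp.reshape(-1, 3) - pts.reshape(-1, 3)
    truth_field = DisplacementField(grid, total.reshape(grid.shape + (3,)))

    # floating geometry, rendered analytically at the inverse-deformed points
    flo_pts = pts.reshape(-1, 3)
    back = _invert_deformation(affine, warp, grid, flo_pts)
    shape_at_back = ndimage.map_coordinates(
        shape_field, grid.world_to_index(back).T, order=1, mode="constant", cval=0.0
    ).reshape(grid.shape)
    flo_liver = LabelMap3D(grid, (shape_at_back > 0.5).astype(np.uint8))
    flo_landmarks = []
    for c in centers:
        d2 = np.sum((back - c) ** 2, axis=1).reshape(grid.shape)
        lm = (d2 <= config.landmark_radius_mm**2) & (flo_liver.labels > 0)
        flo_landmarks.append(LabelMap3D(grid, lm.astype(np.uint8)))

    # intensities: the reference emulates the MAA CT, the floating the
    # configured modality, each with its own noise stream
    ref_labels = _combine_labels(ref_liver, ref_landmarks, True)
    flo_labels = _combine_labels(flo_liver, flo_landmarks, True)
    ref_img = simulate_modality(ref_labels, "pseudo_ct", config.noise_sd, int(sub_seed[0]))
    flo_img = simulate_modality(flo_labels, config.modality, config.noise_sd, int(sub_seed[1]))

    spect = simulate_spect(ref_landmarks, ref_liver, seed=int(sub_seed[2]))

    return PhantomStudy(
        reference_image=ref_img,
        floating_image=flo_img,
        reference_liver=ref_liver,
        floating_liver=flo_liver,
        reference_landmarks=ref_landmarks,
        floating_landmarks=flo_landmarks,
        spect_counts=spect,
        truth_affine=affine,
        truth_field=truth_field,
        seed=config.seed,
    )
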