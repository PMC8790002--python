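"""Multi-modal liver registration: affine stage + spring-regularized non-rigid stage.

Three pipelines are provided, differing only in what guides them:

* ``image``   — affine and non-rigid stages driven by mutual information of
  the intensities alone;
* ``seg``     — liver segmentations drive the affine stage and add a
  segmentation term to the non-rigid loss;
* ``seg_lm``  — a two-class map (liver + landmarks) replaces the liver
  segmentation, otherwise identical to ``seg``.

The non-rigid stage minimizes the weighted sum

    w_I * L_I  +  w_S * L_S  +  L_R

over a dense per-voxel displacement field, where L_I = -MI of the
intensities, L_S is the sum of squared differences between the reference and
(softly) warped segmentation channels, and L_R is a spring model: every pair
of face-adjacent voxels is connected by a spring at its grid rest length, and
the energy penalizes changes of the deformed inter-voxel distances —
discouraging topology-violating deformations.

The public fitting surface follows the model/results idiom:
:class:`LiverRegistration` is built from the data, ``fit()`` runs the
pipeline and returns a :class:`RegistrationResult` carrying the affine, the
full displacement field, the loss trace and warping helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .grid import Image3D, LabelMap3D, VolumeGrid
from .io import resample_to_grid
from .similarity import image_loss, joint_histogram, mi_voxel_weights, mutual_information
from .transform import AffineTransform, DisplacementField, affine_to_field

logger = logging.getLogger(__name__)

__all__ = [
    "LossWeights",
    "RegistrationConfig",
    "RegistrationResult",
    "LiverRegistration",
    "spring_energy",
    "total_loss",
    "register_affine",
    "register_nonrigid",
    "run_pipeline",
    "GUIDANCE_MODES",
]

GUIDANCE_MODES = ("image", "seg", "seg_lm")


@dataclass(frozen=True)
class LossWeights:
    """Tunables of the non-rigid loss w_I*L_I + w_S*L_S + L_R."""

    w_I: float = 1.0
    w_S: float = 1.0
    rigidity_k: float = 0.05

    def __post_init__(self):
        if self.w_I < 0 or self.w_S < 0:
            raise ValueError("similarity weights must be nonnegative")
        if self.rigidity_k <= 0:
            raise ValueError("spring rigidity must be positive")


@dataclass(frozen=True)
class RegistrationConfig:
    """Optimizer and estimator settings shared by the pipelines.

    The defaults favor robustness at the modest working resolutions this
    package targets (the clinical workflow it models runs on ~3 mm grids).
    """

    bins: int = 32
    levels: int = 3
    pyramid_factor: float = 2.0
    # affine stage
    affine_maxfev: tuple[int, ...] = (800, 500, 300)
    affine_xtol: float = 1e-3
    affine_rotation_starts_deg: tuple[float, ...] = (-8.0, 8.0)
    # non-rigid stage
    max_iter: int = 60
    tol: float = 1e-4
    patience: int = 5
    armijo_c1: float = 1e-4
    max_backtracks: int = 10
    grad_smooth_vox: float = 1.0
    skip_nonrigid: bool = False
    region_dilation_mm: float = 12.0
    seg_soft_sigma_vox: float = 1.0


@dataclass
class RegistrationResult:
    """Fit output: transform estimates, diagnostics and warping helpers."""

    mode: str
    weights: LossWeights
    config: RegistrationConfig
    affine: AffineTransform
    field: DisplacementField
    loss_trace: pd.DataFrame
    converged: bool
    floating_image: Image3D
    floating_labels: LabelMap3D | None = None
    diagnostics: dict = dc_field(default_factory=dict)

    @property
    def warped_image(self) -> Image3D:
        from .transform import warp

        return warp(self.floating_image, self.field, "linear")

    def warp_mask(self, mask: LabelMap3D) -> LabelMap3D:
        """Pull a floating-space mask onto the reference grid (hardened)."""
        from .transform import warp

        return warp(mask, self.field, "nearest")

    @property
    def warped_labels(self) -> LabelMap3D | None:
        if self.floating_labels is None:
            return None
        return self.warp_mask(self.floating_labels)

    def summary(self) -> str:
        rows = [
            "Liver registration results",
            "=" * 42,
            f"guidance mode        : {self.mode}",
            f"weights              : w_I={self.weights.w_I:g}, "
            f"w_S={self.weights.w_S:g}, k={self.weights.rigidity_k:g}",
            f"converged            : {self.converged}",
            f"affine translation mm: "
            + np.array2string(self.affine.translation, precision=2),
            f"affine matrix        :\n{np.array2string(self.affine.matrix, precision=4)}",
            f"field |d| (mm)       : median {np.median(self.field.magnitude()):.2f}, "
            f"max {self.field.magnitude().max():.2f}",
        ]
        if "min_jacobian" in self.diagnostics:
            rows.append(f"min Jacobian det     : {self.diagnostics['min_jacobian']:.3f}")
        if len(self.loss_trace):
            last = self.loss_trace.iloc[-1]
            rows.append(
                f"final loss           : total={last['total']:.4g} "
                f"(L_I={last['L_I']:.4g}, L_S={last['L_S']:.4g}, L_R={last['L_R']:.4g})"
            )
        return "\n".join(rows)


# ---------------------------------------------------------------------------
# spring regularizer
# ---------------------------------------------------------------------------


def spring_energy(fld: DisplacementField, rigidity_k: float) -> float:
    """Spring energy over all 6-connected voxel pairs.

    L_R = k * sum over unordered face-adjacent pairs (i, j) of
    (||(p_i + d_i) - (p_j + d_j)|| - ||p_i - p_j||)^2, in world mm.
    """
    return _spring_energy_arr(fld.vectors, fld.grid.spacing_mm, rigidity_k)


def _spring_energy_arr(vec: np.ndarray, spacing, k: float) -> float:
    total = 0.0
    for axis in range(3):
        rest = spacing[axis]
        dd = np.diff(vec, axis=axis)  # d_{i+1} - d_i along the pair axis
        dd = dd.copy()
        dd[..., axis] += rest
        stretched = np.sqrt(np.sum(dd**2, axis=-1)) - rest
        total += float(np.sum(stretched**2))
    return k * total


def _spring_gradient_arr(vec: np.ndarray, spacing, k: float) -> np.ndarray:
    """d L_R / d d, same shape as ``vec``."""
    grad = np.zeros_like(vec)
    for axis in range(3):
        rest = spacing[axis]
        dd = np.diff(vec, axis=axis).copy()
        dd[..., axis] += rest
        length = np.sqrt(np.sum(dd**2, axis=-1))
        length = np.maximum(length, 1e-12)
        coef = 2.0 * k * (length - rest) / length  # per pair
        pair_grad = coef[..., None] * dd  # gradient wrt d_{i+1}
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        grad[tuple(sl_hi)] += pair_grad
        grad[tuple(sl_lo)] -= pair_grad
    return grad


# ---------------------------------------------------------------------------
# loss assembly helpers
# ---------------------------------------------------------------------------


def _soft_channels(labels: LabelMap3D) -> dict[int, np.ndarray]:
    return labels.channels()


def _sample(data: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(data, idx, order=1, mode="constant", cval=0.0)


def _target_idx(ref_grid: VolumeGrid, vectors: np.ndarray, flo_grid: VolumeGrid) -> np.ndarray:
    pts = ref_grid.world_points().reshape(-1, 3) + vectors.reshape(-1, 3)
    return ((pts - np.asarray(flo_grid.origin_mm)) / np.asarray(flo_grid.spacing_mm)).T


def _support_mask(idx: np.ndarray, shape) -> np.ndarray:
    ok = np.ones(idx.shape[1], dtype=bool)
    for a in range(3):
        ok &= (idx[a] >= 0) & (idx[a] <= shape[a] - 1)
    return ok


def _default_region(ref_labels, flo_labels_warped, ref_grid, dilation_mm) -> np.ndarray | None:
    """Similarity region: dilated union of the liver masks, if available."""
    if ref_labels is None:
        return None
    union = np.asarray(ref_labels, bool) | np.asarray(flo_labels_warped, bool)
    if not union.any():
        return None
    it = max(1, int(round(dilation_mm / min(ref_grid.spacing_mm))))
    return ndimage.binary_dilation(union, iterations=it)


def total_loss(
    ref_img: Image3D,
    flo_img: Image3D,
    ref_labels: LabelMap3D | None,
    flo_labels: LabelMap3D | None,
    fld: DisplacementField,
    weights: LossWeights,
    mode: str = "image",
    bins: int = 32,
    region: LabelMap3D | None = None,
) -> tuple[float, float, float, float]:
    """(total, L_I, L_S, L_R) of the combined non-rigid objective.

    In ``image`` mode L_S is identically 0; the guided modes require label
    maps (liver-only for ``seg``, liver+landmark two-class for ``seg_lm``).
    """
    from .similarity import segmentation_loss
    from .transform import warp, warp_channels

    if mode not in GUIDANCE_MODES:
        raise ValueError(f"unknown guidance mode {mode!r}")
    if mode != "image" and (ref_labels is None or flo_labels is None):
        raise ValueError(f"mode {mode!r} requires reference and floating label maps")
    warped = warp(flo_img, fld, "linear")
    l_i = image_loss(ref_img, warped, bins=bins, region=region)
    if mode == "image":
        l_s = 0.0
    else:
        warped_channels = warp_channels(_soft_channels(flo_labels), flo_img.grid, fld)
        l_s = segmentation_loss(ref_labels, warped_channels)
    l_r = spring_energy(fld, weights.rigidity_k)
    return weights.w_I * l_i + weights.w_S * l_s + l_r, l_i, l_s, l_r


# ---------------------------------------------------------------------------
# pyramid
# ---------------------------------------------------------------------------


def _coarsen_grid(grid: VolumeGrid, factor: float) -> VolumeGrid:
    shape = tuple(max(2, int(np.ceil(s / factor))) for s in grid.shape)
    spacing = tuple(sp * factor for sp in grid.spacing_mm)
    return VolumeGrid(shape, spacing, grid.origin_mm)


def _smooth_image_for_level(img: Image3D, factor: float) -> Image3D:
    if factor <= 1:
        return img
    sigma = 0.5 * factor
    return Image3D(img.grid, ndimage.gaussian_filter(img.values, sigma))


def _resample_channels(channels: dict[int, np.ndarray], grid: VolumeGrid,
                       target: VolumeGrid) -> dict[int, np.ndarray]:
    out = {}
    for lab, chan in channels.items():
        img = resample_to_grid(Image3D(grid, chan), target, "linear")
        out[lab] = np.clip(img.values, 0.0, 1.0)
    return out


def _resample_field(fld: DisplacementField, target: VolumeGrid) -> DisplacementField:
    # edge extrapolation: zero-filling outside the coarse support would cut
    # discontinuities into the field at the volume boundary
    idx = [
        (np.asarray(c) - fld.grid.origin_mm[a]) / fld.grid.spacing_mm[a]
        for a, c in enumerate(target.world_coordinates())
    ]
    mesh = np.meshgrid(*idx, indexing="ij")
    coords = np.stack([c.ravel() for c in mesh])
    comps = [
        ndimage.map_coordinates(fld.vectors[..., k], coords, order=1, mode="nearest")
        .reshape(target.shape)
        for k in range(3)
    ]
    return DisplacementField(target, np.stack(comps, axis=-1))


# ---------------------------------------------------------------------------
# affine stage
# ---------------------------------------------------------------------------

_PARAM_SCALE = np.array([5.0, 5.0, 5.0, 2.0, 2.0, 2.0, 0.05, 0.05, 0.05, 0.02, 0.02, 0.02])


def _intensity_centroid(img: Image3D) -> np.ndarray:
    v = img.values - img.values.min()
    total = v.sum()
    if total <= 0:
        return np.asarray(img.grid.origin_mm) + np.array(img.grid.shape) * np.array(img.grid.spacing_mm) / 2
    idx = np.array(ndimage.center_of_mass(v))
    return img.grid.index_to_world(idx)


def _mask_centroid(labels: LabelMap3D) -> np.ndarray:
    idx = np.argwhere(labels.labels > 0)
    if idx.size == 0:
        raise ValueError("cannot initialize from an empty label map")
    return labels.grid.index_to_world(idx.mean(axis=0))


def _moments(mask_arr: np.ndarray, grid: VolumeGrid) -> tuple[np.ndarray, np.ndarray]:
    """Centroid (mm) and covariance (mm^2) of a soft/binary mask."""
    w = np.asarray(mask_arr, float).ravel()
    pts = grid.world_points().reshape(-1, 3)
    total = w.sum()
    c = (w[:, None] * pts).sum(axis=0) / total
    rel = pts - c
    cov = (w[:, None, None] * rel[:, :, None] * rel[:, None, :]).sum(axis=0) / total
    return c, cov


def _moment_init(ref_labels: LabelMap3D, flo_labels: LabelMap3D) -> AffineTransform:
    """Affine aligning mask centroids and principal axes (closed form)."""
    c_r, cov_r = _moments(ref_labels.labels > 0, ref_labels.grid)
    c_f, cov_f = _moments(flo_labels.labels > 0, flo_labels.grid)
    lam_r, u_r = np.linalg.eigh(cov_r)
    lam_f, u_f = np.linalg.eigh(cov_f)
    # align corresponding eigenvectors (ascending eigenvalues), fix signs so
    # the rotation is the small one, and keep the orientation positive
    signs = np.sign(np.diag(u_f.T @ u_r))
    signs[signs == 0] = 1.0
    u_f = u_f * signs
    if np.linalg.det(u_f @ u_r.T) < 0:
        u_f[:, 0] = -u_f[:, 0]
    m = u_f @ np.diag(np.sqrt(lam_f / np.maximum(lam_r, 1e-9))) @ u_r.T
    if np.linalg.det(m) <= 0:
        m = np.eye(3)
    return AffineTransform(m, c_f - m @ c_r)


def _affine_ssd_fit(
    ref_ch: dict[int, np.ndarray],
    ref_grid: VolumeGrid,
    flo_ch: dict[int, np.ndarray],
    flo_grid: VolumeGrid,
    init: AffineTransform,
    maxiter: int = 200,
) -> AffineTransform:
    """L-BFGS fit of matrix+translation minimizing channel SSD (analytic grad)."""
    pts = ref_grid.world_points().reshape(-1, 3)
    spacing = np.asarray(flo_grid.spacing_mm)
    origin = np.asarray(flo_grid.origin_mm)
    grads = {lab: [np.gradient(ch, flo_grid.spacing_mm[a], axis=a) for a in range(3)]
             for lab, ch in flo_ch.items()}

    # parameterize about the weighted centroid of the reference channels with
    # matrix variables scaled by the mask radius, so matrix and translation
    # directions have comparable curvature for the quasi-Newton steps
    wsum = np.zeros(len(pts))
    for ref_c in ref_ch.values():
        wsum += ref_c.ravel()
    total = wsum.sum()
    center = (wsum[:, None] * pts).sum(axis=0) / max(total, 1e-12)
    rel = pts - center
    scale_l = max(np.sqrt((wsum * np.sum(rel**2, axis=1)).sum() / max(total, 1e-12)), 1.0)

    def unpack(p):
        m = p[:9].reshape(3, 3) / scale_l
        t = p[9:]
        return m, t

    def fun(p):
        m, t = unpack(p)  # y = m @ (x - c) + c + t
        y = rel @ m.T + center + t
        idx = ((y - origin) / spacing).T
        loss = 0.0
        g_y = np.zeros_like(pts)
        for lab, ref_c in ref_ch.items():
            w = _sample(flo_ch[lab], idx)
            resid = ref_c.ravel() - w
            loss += float(np.sum(resid**2))
            gvec = np.stack([_sample(g, idx) for g in grads[lab]], axis=-1)
            g_y += -2.0 * resid[:, None] * gvec
        g_m = (g_y.T @ rel) / scale_l
        g_t = g_y.sum(axis=0)
        return loss, np.concatenate([g_m.ravel(), g_t])

    m0 = init.matrix
    t0 = init.matrix @ center + init.translation - center
    p0 = np.concatenate([m0.ravel() * scale_l, t0])
    res = optimize.minimize(fun, p0, jac=True, method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10})
    m, t = unpack(res.x)
    if np.linalg.det(m) <= 0:
        logger.warning("affine SSD fit left the orientation-preserving set; keeping init")
        return init
    return AffineTransform(m, center + t - m @ center)


def register_affine(
    ref: Image3D,
    flo: Image3D,
    mode: str = "image",
    config: RegistrationConfig | None = None,
    ref_labels: LabelMap3D | None = None,
    flo_labels: LabelMap3D | None = None,
) -> AffineTransform:
    """12-parameter affine registration (reference → floating, world mm).

    ``image`` mode maximizes mutual information of the intensities with a
    multi-resolution Powell search (MI is not smoothly differentiable in the
    histogram estimator).  The guided modes minimize the segmentation SSD of
    softly warped label channels: a closed-form moment alignment (centroid +
    principal axes) initializes an L-BFGS refinement with analytic gradients.
    """
    config = config or RegistrationConfig()
    if mode not in GUIDANCE_MODES:
        raise ValueError(f"unknown guidance mode {mode!r}")
    use_labels = mode != "image"
    if use_labels and (ref_labels is None or flo_labels is None):
        raise ValueError(f"mode {mode!r} requires label maps for the affine stage")

    if use_labels:
        # centroid translation with an identity matrix is the robust start for
        # the moderate rotations of liver studies; the closed-form moment
        # alignment is kept as a second candidate for large misalignments and
        # the better final fit (by SSD) wins
        from scipy.spatial.transform import Rotation

        c_r = _mask_centroid(ref_labels)
        c_f = _mask_centroid(flo_labels)
        sigma = config.seg_soft_sigma_vox
        ref_ch = _soft_channels(ref_labels)
        flo_ch = _soft_channels(flo_labels)
        if sigma > 0:  # slight blurring smooths the SSD landscape at voxel scale
            ref_ch = {k: ndimage.gaussian_filter(v, sigma) for k, v in ref_ch.items()}
            flo_ch = {k: ndimage.gaussian_filter(v, sigma) for k, v in flo_ch.items()}

        def ssd_on(aff: AffineTransform, ref_ch_l, ref_grid) -> float:
            pts = ref_grid.world_points().reshape(-1, 3)
            idx = ((aff.apply(pts) - np.asarray(flo_labels.grid.origin_mm))
                   / np.asarray(flo_labels.grid.spacing_mm)).T
            return sum(
                float(np.sum((rc.ravel() - _sample(flo_ch[lab], idx)) ** 2))
                for lab, rc in ref_ch_l.items()
            )

        # multi-start over coarse rotations guards against rotational local
        # minima of the contour SSD; the centroid translation handles the
        # translation search and the moment alignment covers gross cases
        inits = [AffineTransform(np.eye(3), c_f - c_r),
                 _moment_init(ref_labels.as_binary(), flo_labels.as_binary())]
        for axis in range(3):
            for angle in config.affine_rotation_starts_deg:
                rot = Rotation.from_rotvec(
                    np.deg2rad(angle) * np.eye(3)[axis]).as_matrix()
                inits.append(AffineTransform(rot, c_f - rot @ c_r))

        coarse = _coarsen_grid(ref_labels.grid, config.pyramid_factor)
        ref_ch_c = _resample_channels(ref_ch, ref_labels.grid, coarse)
        scored = []
        for init in inits:
            fitted = _affine_ssd_fit(ref_ch_c, coarse, flo_ch, flo_labels.grid,
                                     init, maxiter=80)
            scored.append((ssd_on(fitted, ref_ch_c, coarse), fitted))
        scored.sort(key=lambda c: c[0])
        finals = []
        for _, cand in scored[:2]:  # refine the two best coarse candidates
            fitted = _affine_ssd_fit(ref_ch, ref_labels.grid, flo_ch,
                                     flo_labels.grid, cand)
            finals.append((ssd_on(fitted, ref_ch, ref_labels.grid), fitted))
        final = min(finals, key=lambda c: c[0])[1]
    else:
        c_ref = _intensity_centroid(ref)
        c_flo = _intensity_centroid(flo)
        params = AffineTransform.identity_params()
        params[:3] = c_flo - c_ref
        center = c_ref

        factors = [config.pyramid_factor ** (config.levels - 1 - i)
                   for i in range(config.levels)]
        maxfev = list(config.affine_maxfev)
        while len(maxfev) < config.levels:
            maxfev.insert(0, maxfev[0])

        for level, factor in enumerate(factors):
            ref_grid = _coarsen_grid(ref.grid, factor) if factor > 1 else ref.grid
            ref_l = resample_to_grid(_smooth_image_for_level(ref, factor), ref_grid, "linear")
            flo_s = _smooth_image_for_level(flo, factor)
            pts = ref_grid.world_points().reshape(-1, 3)
            flo_grid = flo.grid

            def objective(z):
                p = params + _PARAM_SCALE * z
                try:
                    aff = AffineTransform.from_params(p, center)
                except ValueError:
                    return 1e12
                tgt = aff.apply(pts)
                idx = ((tgt - np.asarray(flo_grid.origin_mm))
                       / np.asarray(flo_grid.spacing_mm)).T
                ok = _support_mask(idx, flo_grid.shape)
                if ok.mean() < 0.05:
                    return 1e12
                warped = _sample(flo_s.values, idx).reshape(ref_grid.shape)
                sel = ok.reshape(ref_grid.shape)
                h = joint_histogram(
                    Image3D(ref_grid, ref_l.values), Image3D(ref_grid, warped),
                    bins=config.bins,
                    region=LabelMap3D(ref_grid, sel.astype(np.uint8)),
                )
                return -mutual_information(h)

            res = optimize.minimize(
                objective, np.zeros(12), method="Powell",
                options={"maxfev": maxfev[level], "xtol": config.affine_xtol, "ftol": 1e-8},
            )
            params = params + _PARAM_SCALE * res.x
        final = AffineTransform.from_params(params, center)
    if use_labels:
        # sanity: the transform must bring the masks into overlap
        fld = affine_to_field(final, ref_labels.grid)
        from .transform import warp

        warped = warp(flo_labels.as_binary(), fld, "nearest")
        if not ((warped.labels > 0) & (ref_labels.labels > 0)).any():
            raise RuntimeError("affine stage produced non-overlapping segmentations")
    return final


# ---------------------------------------------------------------------------
# non-rigid stage
# ---------------------------------------------------------------------------


def _nonrigid_level(
    ref_vals: np.ndarray,
    ref_grid: VolumeGrid,
    flo_vals: np.ndarray,
    flo_grid: VolumeGrid,
    ref_ch: dict[int, np.ndarray],
    flo_ch: dict[int, np.ndarray],
    vec: np.ndarray,
    weights: LossWeights,
    config: RegistrationConfig,
    region_arr: np.ndarray | None,
    trace: list,
    level: int,
) -> tuple[np.ndarray, bool]:
    """Armijo-backtracking steepest descent on one pyramid level."""
    spacing = ref_grid.spacing_mm
    flo_grad = [np.gradient(flo_vals, flo_grid.spacing_mm[a], axis=a) for a in range(3)]
    ch_grads = {
        lab: [np.gradient(ch, flo_grid.spacing_mm[a], axis=a) for a in range(3)]
        for lab, ch in flo_ch.items()
    }
    use_seg = bool(flo_ch) and weights.w_S > 0
    use_mi = weights.w_I > 0

    def losses(v: np.ndarray) -> tuple[float, float, float, float]:
        idx = _target_idx(ref_grid, v, flo_grid)
        l_i = 0.0
        if use_mi:
            ok = _support_mask(idx, flo_grid.shape).reshape(ref_grid.shape)
            sel = ok if region_arr is None else (ok & region_arr)
            if sel.sum() < 8:
                sel = ok
            warped = _sample(flo_vals, idx).reshape(ref_grid.shape)
            h = joint_histogram(
                Image3D(ref_grid, ref_vals), Image3D(ref_grid, warped),
                bins=config.bins, region=LabelMap3D(ref_grid, sel.astype(np.uint8)),
            )
            l_i = -mutual_information(h)
        l_s = 0.0
        if use_seg:
            for lab, ref_c in ref_ch.items():
                w = np.clip(_sample(flo_ch[lab], idx).reshape(ref_grid.shape), 0, 1)
                l_s += float(np.sum((ref_c - w) ** 2))
        l_r = _spring_energy_arr(v, spacing, weights.rigidity_k)
        return weights.w_I * l_i + weights.w_S * l_s + l_r, l_i, l_s, l_r

    def gradient(v: np.ndarray) -> np.ndarray:
        idx = _target_idx(ref_grid, v, flo_grid)
        g_sim = np.zeros_like(v)
        if use_mi:
            ok = _support_mask(idx, flo_grid.shape).reshape(ref_grid.shape)
            sel = ok if region_arr is None else (ok & region_arr)
            if sel.sum() < 8:
                sel = ok
            warped = _sample(flo_vals, idx).reshape(ref_grid.shape)
            wts = mi_voxel_weights(ref_vals, warped, sel, bins=config.bins)
            gvec = np.stack([_sample(g, idx).reshape(ref_grid.shape) for g in flo_grad], -1)
            g_sim += weights.w_I * (-wts[..., None] * gvec)  # L_I = -MI
        if use_seg:
            for lab, ref_c in ref_ch.items():
                w = np.clip(_sample(flo_ch[lab], idx).reshape(ref_grid.shape), 0, 1)
                gvec = np.stack(
                    [_sample(g, idx).reshape(ref_grid.shape) for g in ch_grads[lab]], -1
                )
                g_sim += weights.w_S * (-2.0 * (ref_c - w))[..., None] * gvec
        if config.grad_smooth_vox > 0:
            for k in range(3):
                g_sim[..., k] = ndimage.gaussian_filter(g_sim[..., k], config.grad_smooth_vox)
        return g_sim + _spring_gradient_arr(v, spacing, weights.rigidity_k)

    current = losses(vec)
    trace.append({"level": level, "iter": 0, "total": current[0],
                  "L_I": current[1], "L_S": current[2], "L_R": current[3]})
    stall = 0
    converged = False
    min_spacing = min(spacing)
    for it in range(1, config.max_iter + 1):
        g = gradient(vec)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient in non-rigid stage")
        gmax = np.abs(g).max()
        if gmax == 0:
            converged = True
            break
        step = 0.5 * min_spacing / gmax  # first trial moves at most half a voxel
        gnorm2 = float(np.sum(g * g))
        accepted = False
        for _ in range(config.max_backtracks):
            trial = vec - step * g
            cand = losses(trial)
            if not np.isfinite(cand[0]):
                raise FloatingPointError("non-finite loss in non-rigid stage")
            if cand[0] <= current[0] - config.armijo_c1 * step * gnorm2:
                vec = trial
                prev_total = current[0]
                current = cand
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        trace.append({"level": level, "iter": it, "total": current[0],
                      "L_I": current[1], "L_S": current[2], "L_R": current[3]})
        denom = max(abs(prev_total), 1e-12)
        if abs(prev_total - current[0]) / denom < config.tol:
            stall += 1
            if stall >= config.patience:
                converged = True
                break
        else:
            stall = 0
    return vec, converged


def register_nonrigid(
    ref: Image3D,
    flo: Image3D,
    init_field: DisplacementField,
    weights: LossWeights | None = None,
    mode: str = "image",
    config: RegistrationConfig | None = None,
    ref_labels: LabelMap3D | None = None,
    flo_labels: LabelMap3D | None = None,
    affine: AffineTransform | None = None,
) -> RegistrationResult:
    """Dense non-rigid registration by multi-resolution steepest descent.

    The returned field is the *full* reference→floating map (it contains the
    affine initialization).  Accepted optimizer steps never increase the
    total loss, and the loss trace records (L_I, L_S, L_R, total) per
    accepted iteration and pyramid level.
    """
    weights = weights or LossWeights()
    config = config or RegistrationConfig()
    if mode not in GUIDANCE_MODES:
        raise ValueError(f"unknown guidance mode {mode!r}")
    if mode != "image" and (ref_labels is None or flo_labels is None):
        raise ValueError(f"mode {mode!r} requires label maps")
    if init_field.grid != ref.grid:
        raise ValueError("initial field must live on the reference grid")

    ref_ch_full = _soft_channels(ref_labels) if mode != "image" else {}
    flo_ch_full = _soft_channels(flo_labels) if mode != "image" else {}

    factors = [config.pyramid_factor ** (config.levels - 1 - i) for i in range(config.levels)]
    trace: list[dict] = []
    fld = init_field
    converged = True
    for level, factor in enumerate(factors):
        grid_l = _coarsen_grid(ref.grid, factor) if factor > 1 else ref.grid
        ref_l = resample_to_grid(_smooth_image_for_level(ref, factor), grid_l, "linear")
        flo_l = _smooth_image_for_level(flo, factor)
        ref_ch = _resample_channels(ref_ch_full, ref.grid, grid_l) if ref_ch_full else {}
        region = None
        if ref_labels is not None:
            ref_liv = _resample_channels(
                {1: (ref_labels.labels > 0).astype(float)}, ref_labels.grid, grid_l
            )[1] > 0.5
            region = _default_region(ref_liv, ref_liv, grid_l, config.region_dilation_mm)
        fld_l = _resample_field(fld, grid_l)
        vec, conv = _nonrigid_level(
            ref_l.values, grid_l, flo_l.values, flo.grid,
            ref_ch, flo_ch_full, fld_l.vectors.copy(),
            weights, config, region, trace, level,
        )
        converged = converged and conv
        fld = DisplacementField(grid_l, vec)
    final = _resample_field(fld, ref.grid) if fld.grid != ref.grid else fld

    diagnostics = {"min_jacobian": _min_jacobian(final)}
    if diagnostics["min_jacobian"] <= 0:
        logger.warning("non-rigid field folds (min Jacobian %.3f)", diagnostics["min_jacobian"])
    return RegistrationResult(
        mode=mode, weights=weights, config=config,
        affine=affine or AffineTransform.identity(),
        field=final,
        loss_trace=pd.DataFrame(trace),
        converged=converged,
        floating_image=flo,
        floating_labels=flo_labels,
        diagnostics=diagnostics,
    )


def _min_jacobian(fld: DisplacementField) -> float:
    """Minimum Jacobian determinant of x + d(x) (diagnostic only)."""
    jac = np.empty(fld.grid.shape + (3, 3))
    for i in range(3):
        for j in range(3):
            jac[..., i, j] = np.gradient(fld.vectors[..., i], fld.grid.spacing_mm[j], axis=j)
        jac[..., i, i] += 1.0
    return float(np.linalg.det(jac).min())


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class LiverRegistration:
    """Registration model: reference/floating volumes plus optional guidance.

    Parameters
    ----------
    reference, floating : Image3D
        The fixed (reference) and moving (floating) intensity volumes.
    ref_labels, flo_labels : LabelMap3D, optional
        Guidance maps: binary liver masks for ``seg`` mode, two-class
        liver+landmark maps for ``seg_lm``.
    mode : {"image", "seg", "seg_lm"}
    config : RegistrationConfig, optional

    ``fit(weights)`` runs the affine stage (image- or segmentation-driven per
    mode), converts it to a displacement field, and — unless
    ``config.skip_nonrigid`` — refines it with the spring-regularized
    non-rigid stage.
    """

    def __init__(
        self,
        reference: Image3D,
        floating: Image3D,
        ref_labels: LabelMap3D | None = None,
        flo_labels: LabelMap3D | None = None,
        mode: str = "image",
        config: RegistrationConfig | None = None,
    ):
        if mode not in GUIDANCE_MODES:
            raise ValueError(f"unknown guidance mode {mode!r}")
        if mode != "image" and (ref_labels is None or flo_labels is None):
            raise ValueError(f"mode {mode!r} requires guidance label maps")
        self.reference = reference
        self.floating = floating
        self.ref_labels = ref_labels
        self.flo_labels = flo_labels
        self.mode = mode
        self.config = config or RegistrationConfig()

    @classmethod
    def from_study(cls, study, mode: str = "seg_lm",
                   config: RegistrationConfig | None = None) -> "LiverRegistration":
        """Build from a :class:`~livreg.phantom.PhantomStudy`."""
        with_lm = mode == "seg_lm"
        return cls(
            study.reference_image, study.floating_image,
            ref_labels=None if mode == "image" else study.reference_labelmap(with_lm),
            flo_labels=None if mode == "image" else study.floating_labelmap(with_lm),
            mode=mode, config=config,
        )

    def fit(self, weights: LossWeights | None = None) -> RegistrationResult:
        weights = weights or LossWeights()
        affine = register_affine(
            self.reference, self.floating, self.mode, self.config,
            self.ref_labels, self.flo_labels,
        )
        init = affine_to_field(affine, self.reference.grid)
        if self.config.skip_nonrigid:
            return RegistrationResult(
                mode=self.mode, weights=weights, config=self.config,
                affine=affine, field=init,
                loss_trace=pd.DataFrame(
                    columns=["level", "iter", "total", "L_I", "L_S", "L_R"]
                ),
                converged=True,
                floating_image=self.floating, floating_labels=self.flo_labels,
            )
        return register_nonrigid(
            self.reference, self.floating, init, weights, self.mode, self.config,
            self.ref_labels, self.flo_labels, affine=affine,
        )


def run_pipeline(
    reference: Image3D,
    floating: Image3D,
    mode: str = "image",
    weights: LossWeights | None = None,
    config: RegistrationConfig | None = None,
    ref_labels: LabelMap3D | None = None,
    flo_labels: LabelMap3D | None = None,
) -> RegistrationResult:
    """Functional one-call form of :class:`LiverRegistration` + ``fit``."""
    model = LiverRegistration(reference, floating, ref_labels, flo_labels, mode, config)
    return model.fit(weights)
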