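"""Affine transforms, dense displacement fields, and warping.

Conventions
-----------
Everything uses the pull-back convention: a transform or field maps points of
the *reference* space into the *floating* space, and warping evaluates

    warped(x) = floating(x + d(x))

so that the warped floating volume lives on the reference grid.  An affine
maps a reference world point ``x`` (mm) to ``A @ x + t``.

The 12-parameter affine used by the optimizers is parameterized as
translation (3, mm) + rotation (3, Euler ZYX, degrees) + scale (3) +
shear (3), applied about a configurable center so the parameters stay
well-conditioned; it is stored canonically as matrix + translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .grid import Image3D, LabelMap3D, VolumeGrid

__all__ = [
    "AffineTransform",
    "DisplacementField",
    "affine_to_field",
    "apply_affine_points",
    "warp",
    "warp_channels",
]


@dataclass(frozen=True)
class AffineTransform:
    """World-coordinate affine map x -> matrix @ x + translation (mm)."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.linalg.det(m) <= 0:
            raise ValueError("affine must be orientation-preserving (det > 0)")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_params(cls, params: np.ndarray, center: np.ndarray | None = None) -> "AffineTransform":
        """Build from the 12-vector [t(3) mm, rot(3) deg ZYX, scale(3), shear(3)].

        Rotation/scale/shear act about ``center`` (world mm, default origin):
        y = M (x - c) + c + t  with  M = R @ diag(s) @ Sh.
        """
        params = np.asarray(params, dtype=float)
        t, rot_deg, scale, shear = params[:3], params[3:6], params[6:9], params[9:12]
        rotm = Rotation.from_euler("zyx", rot_deg, degrees=True).as_matrix()
        sh = np.eye(3)
        sh[0, 1], sh[0, 2], sh[1, 2] = shear
        m = rotm @ np.diag(scale) @ sh
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        return cls(m, c - m @ c + t)

    @staticmethod
    def identity_params() -> np.ndarray:
        return np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.matrix.T + self.translation

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: first apply ``other``, then ``self``."""
        return AffineTransform(self.matrix @ other.matrix,
                               self.matrix @ other.translation + self.translation)

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)


def apply_affine_points(a: AffineTransform, points: np.ndarray) -> np.ndarray:
    """Map world points (N, 3) through an affine."""
    return a.apply(points)


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (mm) on the reference grid."""

    grid: VolumeGrid
    vectors: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != self.grid.shape + (3,):
            raise ValueError(
                f"field shape {v.shape} does not match grid {self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("displacement field contains non-finite vectors")
        self.vectors = v

    @classmethod
    def zero(cls, grid: VolumeGrid) -> "DisplacementField":
        return cls(grid, np.zeros(grid.shape + (3,)))

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.grid, self.vectors.copy())


def affine_to_field(a: AffineTransform, grid: VolumeGrid) -> DisplacementField:
    """Densify an affine into a displacement field: d(x) = (A x + t) - x."""
    pts = grid.world_points()
    vec = pts.reshape(-1, 3) @ (a.matrix - np.eye(3)).T + a.translation
    return DisplacementField(grid, vec.reshape(grid.shape + (3,)))


def _sample(data: np.ndarray, index_coords: np.ndarray, order: int, cval: float = 0.0) -> np.ndarray:
    """map_coordinates on flattened (3, N) continuous indices."""
    return ndimage.map_coordinates(data, index_coords, order=order, mode="constant", cval=cval)


def _target_indices(fld: DisplacementField, src_grid: VolumeGrid) -> np.ndarray:
    """Continuous source-voxel indices of x + d(x), shape (3, N)."""
    pts = fld.grid.world_points().reshape(-1, 3) + fld.vectors.reshape(-1, 3)
    idx = (pts - np.asarray(src_grid.origin_mm)) / np.asarray(src_grid.spacing_mm)
    return idx.T


def warp(
    vol: Image3D | LabelMap3D,
    fld: DisplacementField,
    interpolation: str = "linear",
) -> Image3D | LabelMap3D:
    """Pull a floating volume back onto the reference grid of the field.

    Images use linear interpolation; label maps use nearest (or "linear"
    per-channel via :func:`warp_channels` when a soft result is wanted).
    Out-of-support voxels fill with 0.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    is_label = isinstance(vol, LabelMap3D)
    if is_label and interpolation == "linear":
        raise ValueError("use warp_channels for soft (linear) label warping")
    data = np.asarray(vol.labels if is_label else vol.values, dtype=float)
    idx = _target_indices(fld, vol.grid)
    out = _sample(data, idx, order=0 if is_label else 1).reshape(fld.grid.shape)
    if is_label:
        return LabelMap3D(fld.grid, np.rint(out).astype(np.int32))
    return Image3D(fld.grid, out)


def warp_channels(channels: dict[int, np.ndarray], src_grid: VolumeGrid,
                  fld: DisplacementField) -> dict[int, np.ndarray]:
    """Linearly warp each binary class channel, keeping values in [0, 1]."""
    idx = _target_indices(fld, src_grid)
    out: dict[int, np.ndarray] = {}
    for lab, chan in channels.items():
        w = _sample(np.asarray(chan, float), idx, order=1).reshape(fld.grid.shape)
        out[lab] = np.clip(w, 0.0, 1.0)
    return out
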