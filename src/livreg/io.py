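"""NIfTI input/output and grid resampling.

Volumes are exchanged as NIfTI-1 (.nii / .nii.gz) through :mod:`nibabel`.
Integer-typed files load as :class:`~livreg.grid.LabelMap3D`, floating-point
files as :class:`~livreg.grid.Image3D`.  Displacement fields are 4D NIfTI
with the last axis holding the (x, y, z) vector components in millimeters.
Affine transforms travel as JSON ``{"matrix": 3x3, "translation": 3}``.

Grids are axis-aligned after load: a file whose direction matrix is not the
identity is resampled onto the nearest axis-aligned grid with a warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grid import Image3D, LabelMap3D, VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "read_affine_json",
    "write_affine_json",
    "resample_to_grid",
]


def _grid_from_nifti(img: nib.Nifti1Image) -> tuple[VolumeGrid, bool]:
    """Grid of a NIfTI volume; second return flags a non-axis-aligned file."""
    aff = img.affine
    direction = aff[:3, :3]
    spacing = np.linalg.norm(direction, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("degenerate NIfTI affine: zero-length axis")
    normalized = direction / spacing
    axis_aligned = np.allclose(normalized, np.eye(3), atol=1e-6)
    shape = img.shape[:3]
    grid = VolumeGrid(tuple(shape), tuple(spacing), tuple(aff[:3, 3]))
    return grid, not axis_aligned


def _resample_oblique(data: np.ndarray, affine: np.ndarray, grid: VolumeGrid, order: int) -> np.ndarray:
    """Resample an oblique volume onto the nearest axis-aligned grid."""
    target_world = grid.world_points().reshape(-1, 3)
    inv = np.linalg.inv(affine)
    idx = target_world @ inv[:3, :3].T + inv[:3, 3]
    out = ndimage.map_coordinates(
        np.asarray(data, dtype=float), idx.T, order=order, mode="constant", cval=0.0
    )
    return out.reshape(grid.shape)


def read_volume(path: str | Path) -> Image3D | LabelMap3D:
    """Read a 3D NIfTI volume as an image or a label map.

    Integer on-disk dtype yields a :class:`LabelMap3D`, anything else an
    :class:`Image3D`.  NaN voxels raise with the offending indices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    is_label = np.issubdtype(data.dtype, np.integer)
    if not is_label and np.isnan(data).any():
        bad = np.argwhere(np.isnan(data))
        raise ValueError(f"{path}: NaN voxels at indices {bad[:10].tolist()}")

    grid, oblique = _grid_from_nifti(img)
    if oblique:
        logger.warning("%s has a non-axis-aligned direction matrix; resampling", path)
        data = _resample_oblique(data, img.affine, grid, order=0 if is_label else 1)
        if is_label:
            data = np.rint(data).astype(np.int16)
    if is_label:
        return LabelMap3D(grid, data.astype(np.int32))
    return Image3D(grid, data.astype(float))


def write_volume(path: str | Path, vol: Image3D | LabelMap3D) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, LabelMap3D):
        data = vol.labels.astype(np.int16)
    else:
        data = vol.values.astype(np.float32)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vol.grid.spacing_mm)
    aff[:3, 3] = vol.grid.origin_mm
    nib.save(nib.Nifti1Image(data, aff), str(path))


def read_field(path: str | Path):
    """Read a 4D NIfTI displacement field (vector components in mm)."""
    from .transform import DisplacementField

    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention (t axis of 1)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a (nx, ny, nz, 3) field, got {data.shape}")
    grid, oblique = _grid_from_nifti(img)
    if oblique:
        raise ValueError(f"{path}: oblique displacement fields are not supported")
    return DisplacementField(grid, data)


def write_field(path: str | Path, fld) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(fld.grid.spacing_mm)
    aff[:3, 3] = fld.grid.origin_mm
    nib.save(nib.Nifti1Image(fld.vectors.astype(np.float32), aff), str(path))


def read_affine_json(path: str | Path):
    from .transform import AffineTransform

    with open(path) as fh:
        doc = json.load(fh)
    return AffineTransform(np.asarray(doc["matrix"], float), np.asarray(doc["translation"], float))


def write_affine_json(path: str | Path, affine) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"matrix": np.asarray(affine.matrix).tolist(),
           "translation": np.asarray(affine.translation).tolist()}
    path.write_text(json.dumps(doc, indent=2))


def resample_to_grid(
    vol: Image3D | LabelMap3D,
    target_grid: VolumeGrid,
    interpolation: str = "linear",
    fill_value: float = 0.0,
) -> Image3D | LabelMap3D:
    """Sample a volume at the voxel centers of another axis-aligned grid.

    ``interpolation`` is "linear" or "nearest"; label maps require nearest
    (linear blending of label codes is meaningless).  Positions outside the
    source support take ``fill_value``.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    is_label = isinstance(vol, LabelMap3D)
    if is_label and interpolation == "linear":
        raise ValueError("linear interpolation is not valid for label maps; use nearest")
    data = vol.labels if is_label else vol.values
    src = vol.grid
    idx = [
        (np.asarray(c) - src.origin_mm[a]) / src.spacing_mm[a]
        for a, c in enumerate(target_grid.world_coordinates())
    ]
    coords = np.meshgrid(*idx, indexing="ij")
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(
        np.asarray(data, float), np.stack([c.ravel() for c in coords]),
        order=order, mode="constant", cval=fill_value,
    ).reshape(target_grid.shape)
    if is_label:
        return LabelMap3D(target_grid, np.rint(out).astype(np.int32))
    return Image3D(target_grid, out)
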