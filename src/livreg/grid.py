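"""Axis-aligned volume grids and the image/label containers built on them.

All geometry is world millimeters: a grid places voxel index ``i`` (0-based)
at world position ``origin + i * spacing``.  Every image, mask, displacement
field and uptake map in the package lives on such a grid, and operations that
combine two volumes require their grids to match (or resample explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "Image3D", "LabelMap3D", "BinaryMask"]


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned 3D sampling grid in world millimeters."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        origin = tuple(float(o) for o in self.origin_mm)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("VolumeGrid is strictly three-dimensional")
        if any(s <= 0 for s in shape):
            raise ValueError(f"non-positive grid shape {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"non-positive voxel spacing {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D world coordinates of the voxel centers."""
        return tuple(
            self.origin_mm[a] + np.arange(self.shape[a]) * self.spacing_mm[a]
            for a in range(3)
        )

    def world_points(self) -> np.ndarray:
        """Dense (nx, ny, nz, 3) array of voxel-center world positions."""
        xs, ys, zs = self.world_coordinates()
        pts = np.empty(self.shape + (3,), dtype=float)
        pts[..., 0] = xs[:, None, None]
        pts[..., 1] = ys[None, :, None]
        pts[..., 2] = zs[None, None, :]
        return pts

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points (inverse of the placement rule)."""
        points_mm = np.asarray(points_mm, dtype=float)
        return (points_mm - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        indices = np.asarray(indices, dtype=float)
        return np.asarray(self.origin_mm) + indices * np.asarray(self.spacing_mm)


def _check_values(grid: VolumeGrid, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"{name} must be a 3D array, got ndim={values.ndim}")
    if tuple(values.shape) != grid.shape:
        raise ValueError(
            f"{name} shape {tuple(values.shape)} does not match grid shape {grid.shape}"
        )
    return values


@dataclass
class Image3D:
    """A scalar 3D image: float values on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = _check_values(self.grid, self.values, "values").astype(float, copy=False)
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))
            raise ValueError(
                f"non-finite voxels at indices {bad[:5].tolist()}"
                + ("..." if len(bad) > 5 else "")
            )
        self.values = values

    def copy(self) -> "Image3D":
        return Image3D(self.grid, self.values.copy())


@dataclass
class LabelMap3D:
    """Integer label volume; 0 is background.

    A binary mask is a LabelMap3D restricted to {0, 1}; the two-class
    guidance map used for joint liver + landmark registration uses
    {0: background, 1: liver, 2: landmark}.
    """

    grid: VolumeGrid
    labels: np.ndarray = field(repr=False)

    def __post_init__(self):
        labels = _check_values(self.grid, self.labels, "labels")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded):
                raise ValueError("label map contains non-integer values")
            labels = rounded.astype(np.int16)
        self.labels = labels

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.labels, (0, 1)).all())

    def foreground_indices(self) -> np.ndarray:
        return np.argwhere(self.labels > 0)

    def as_binary(self, label: int | None = None) -> "LabelMap3D":
        """Binary mask of one label (or of all foreground if label is None)."""
        if label is None:
            fg = self.labels > 0
        else:
            fg = self.labels == label
        return LabelMap3D(self.grid, fg.astype(np.uint8))

    def channels(self) -> dict[int, np.ndarray]:
        """One float binary channel per foreground class, ordered by label value."""
        out: dict[int, np.ndarray] = {}
        for lab in np.unique(self.labels):
            if lab == 0:
                continue
            out[int(lab)] = (self.labels == lab).astype(float)
        return out

    def copy(self) -> "LabelMap3D":
        return LabelMap3D(self.grid, self.labels.copy())


# A binary mask is just a constrained label map; the alias documents intent.
BinaryMask = LabelMap3D
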