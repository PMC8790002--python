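"""Registration evaluation metrics and weight tuning.

A liver registration is scored by the root mean squared distance (RMSD)
combining the mean surface distance (MSD) between liver contours with the
mass center distances (MCD) of the paired landmarks:

    RMSD = sqrt( (MSD^2 + sum_i MCD_i^2) / (1 + N_landmarks) )

and a batch of registrations by the root mean square of its RMSDs (RRMSD).
The Dice similarity coefficient (DSC) scores segmentation overlap.  Loss
weights (w_I, w_S) are tuned by grid search minimizing the batch RRMSD,
mirroring how the registration hyper-parameters are selected on training
cases; the 1D search (w_S = 0) covers the purely image-based setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import LabelMap3D

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "GridSearchTable",
    "dsc",
    "mean_surface_distance",
    "mass_center_distance",
    "rmsd",
    "rrmsd",
    "evaluate_registration",
    "grid_search_weights",
]


@dataclass
class EvaluationReport:
    """MSD, per-landmark MCDs and their RMSD combination for one registration."""

    msd_mm: float
    mcd_mm: list[float]
    rmsd_mm: float

    @property
    def n_landmarks(self) -> int:
        return len(self.mcd_mm)

    def to_dict(self) -> dict:
        return {
            "msd_mm": self.msd_mm,
            "mcd_mm": list(self.mcd_mm),
            "rmsd_mm": self.rmsd_mm,
            "n_landmarks": self.n_landmarks,
        }


def dsc(a: LabelMap3D, b: LabelMap3D) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|); both empty -> 1."""
    if a.grid != b.grid:
        raise ValueError("DSC requires masks on the same grid")
    fa = a.labels > 0
    fb = b.labels > 0
    denom = int(fa.sum()) + int(fb.sum())
    if denom == 0:
        logger.warning("DSC of two empty masks defined as 1.0")
        return 1.0
    return 2.0 * int((fa & fb).sum()) / denom


def _surface_points(mask: LabelMap3D) -> np.ndarray:
    """World coordinates (mm) of foreground voxels with a face-adjacent background."""
    fg = mask.labels > 0
    interior = ndimage.binary_erosion(
        fg, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    surf = np.argwhere(fg & ~interior)
    return mask.grid.index_to_world(surf)


def mean_surface_distance(a: LabelMap3D, b: LabelMap3D) -> float:
    """Symmetric mean surface distance between two masks, world mm.

    Surfaces are the foreground voxels with at least one 6-connected
    background neighbor; the metric averages nearest-surface distances in
    both directions (voxel-center to voxel-center).
    """
    if a.grid != b.grid:
        raise ValueError("MSD requires masks on the same grid")
    pa, pb = _surface_points(a), _surface_points(b)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("MSD is undefined for an empty mask")
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))


def mass_center_distance(a: LabelMap3D, b: LabelMap3D) -> float:
    """Euclidean distance between foreground centroids in world mm."""
    ca = _centroid(a)
    cb = _centroid(b)
    return float(np.linalg.norm(ca - cb))


def _centroid(mask: LabelMap3D) -> np.ndarray:
    idx = np.argwhere(mask.labels > 0)
    if idx.size == 0:
        raise ValueError("centroid of an empty mask")
    return mask.grid.index_to_world(idx.mean(axis=0))


def rmsd(msd_mm: float, mcds_mm) -> float:
    """Root mean squared distance of MSD and per-landmark MCDs."""
    mcds = np.asarray(list(mcds_mm), dtype=float)
    if msd_mm < 0 or (mcds < 0).any():
        raise ValueError("distances must be nonnegative")
    return float(np.sqrt((msd_mm**2 + np.sum(mcds**2)) / (1 + mcds.size)))


def rrmsd(rmsds_mm) -> float:
    """Root mean square of a batch of RMSDs."""
    vals = np.asarray(list(rmsds_mm), dtype=float)
    if vals.size == 0:
        raise ValueError("RRMSD of an empty batch")
    return float(np.sqrt(np.mean(vals**2)))


def evaluate_registration(
    warped_liver: LabelMap3D,
    ref_liver: LabelMap3D,
    warped_landmarks: list[LabelMap3D] | None = None,
    ref_landmarks: list[LabelMap3D] | None = None,
) -> EvaluationReport:
    """MSD + landmark MCDs + RMSD for one registered pair (landmarks by index)."""
    warped_landmarks = warped_landmarks or []
    ref_landmarks = ref_landmarks or []
    if len(warped_landmarks) != len(ref_landmarks):
        raise ValueError("landmark lists must pair by index")
    msd = mean_surface_distance(warped_liver, ref_liver)
    mcds = [mass_center_distance(w, r) for w, r in zip(warped_landmarks, ref_landmarks)]
    return EvaluationReport(msd, mcds, rmsd(msd, mcds))


@dataclass
class GridSearchTable:
    """Per-(w_I, w_S) RRMSD table and the optimum row."""

    table: pd.DataFrame  # columns: w_I, w_S, rigidity_k, rrmsd_mm, rmsds, failed
    optimum: pd.Series

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["rmsds"] = out["rmsds"].map(lambda v: ";".join(f"{x:.6g}" for x in v))
        out.to_csv(path, index=False)


def grid_search_weights(
    cases,
    grid_wI,
    grid_wS,
    mode: str = "seg",
    rigidity_k: float = 0.05,
    config=None,
) -> GridSearchTable:
    """Exhaustive (w_I, w_S) search minimizing batch RRMSD over the cases.

    Each case is a mapping with the pipeline inputs (see
    :func:`livreg.registration.run_pipeline`) plus the reference/floating
    liver masks and landmark lists used for scoring.  A failing case marks
    the row failed and excludes it from the optimum.  Ties break toward the
    smallest w_S, then the smallest w_I (prefer less guidance).
    """
    from .registration import LossWeights, run_pipeline

    grid_wI = list(grid_wI)
    grid_wS = list(grid_wS)
    if not cases or not grid_wI or not grid_wS:
        raise ValueError("grid search needs at least one case and a nonempty grid")
    rows = []
    for w_s in grid_wS:
        for w_i in grid_wI:
            weights = LossWeights(w_I=float(w_i), w_S=float(w_s), rigidity_k=rigidity_k)
            rmsds, failed = [], False
            for case in cases:
                try:
                    out = run_pipeline(
                        case["reference"], case["floating"], mode=mode,
                        weights=weights, config=config,
                        ref_labels=case.get("ref_labels"),
                        flo_labels=case.get("flo_labels"),
                    )
                    report = evaluate_registration(
                        out.warp_mask(case["flo_liver"]), case["ref_liver"],
                        [out.warp_mask(m) for m in case.get("flo_landmarks", [])],
                        case.get("ref_landmarks", []),
                    )
                    rmsds.append(report.rmsd_mm)
                except Exception:  # noqa: BLE001 - a failed cell must not kill the scan
                    logger.warning("grid cell (w_I=%g, w_S=%g) failed", w_i, w_s, exc_info=True)
                    failed = True
                    break
            rows.append({
                "w_I": float(w_i), "w_S": float(w_s), "rigidity_k": rigidity_k,
                "rrmsd_mm": rrmsd(rmsds) if not failed else np.nan,
                "rmsds": rmsds, "failed": failed,
            })
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise RuntimeError("every grid cell failed")
    # stable tie-break: sort by (rrmsd, w_S, w_I) and take the head
    optimum = ok.sort_values(["rrmsd_mm", "w_S", "w_I"], kind="mergesort").iloc[0]
    return GridSearchTable(table, optimum)
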