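"""Similarity losses for registration.

Two losses drive the registrations:

* the image similarity loss ``L_I = -MI``, with mutual information estimated
  from a dense joint intensity histogram (hard binning, default 32x32 bins),
  optionally restricted to a region of interest;
* the segmentation similarity loss ``L_S``, the sum of squared differences
  between reference and warped segmentations, with each foreground class
  represented as its own binary channel (soft values in [0, 1] after linear
  warping keep the loss continuous in the displacement field).

MI is reported in nats.  Both losses are "lower is better" so the non-rigid
objective is a plain weighted sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import Image3D, LabelMap3D

logger = logging.getLogger(__name__)

__all__ = [
    "JointHistogram",
    "joint_histogram",
    "mutual_information",
    "image_loss",
    "segmentation_loss",
]


@dataclass
class JointHistogram:
    """Dense joint intensity histogram of a reference/floating voxel pairing."""

    counts: np.ndarray
    edges_ref: np.ndarray
    edges_flo: np.ndarray
    n_samples: int


def _edges(values: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        # Degenerate (constant) image: a single bin still defines a valid
        # distribution; MI against anything is then 0.
        logger.warning("constant image in joint histogram; using a single bin")
        return np.array([lo - 0.5, lo + 0.5])
    return np.linspace(lo, hi, bins + 1)


def joint_histogram(
    ref: Image3D,
    flo_warped: Image3D,
    bins: int = 32,
    region: LabelMap3D | None = None,
) -> JointHistogram:
    """Joint histogram of paired voxels, optionally within a binary region."""
    if ref.grid != flo_warped.grid:
        raise ValueError("joint histogram requires images on the same grid")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    a = ref.values
    b = flo_warped.values
    if region is not None:
        if region.grid != ref.grid:
            raise ValueError("region grid mismatch")
        sel = region.labels > 0
        if not sel.any():
            raise ValueError("empty histogram region")
        a, b = a[sel], b[sel]
    else:
        a, b = a.ravel(), b.ravel()
    ea, eb = _edges(a, bins), _edges(b, bins)
    counts, _, _ = np.histogram2d(a, b, bins=(ea, eb))
    return JointHistogram(counts, ea, eb, int(a.size))


def mutual_information(h: JointHistogram) -> float:
    """MI in nats from a joint histogram; 0·ln 0 := 0."""
    if h.n_samples <= 0:
        raise ValueError("empty histogram")
    p = h.counts / h.counts.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (pa @ pb)[nz])))
    return max(mi, 0.0)  # clip tiny negative rounding residue


def image_loss(
    ref: Image3D,
    flo_warped: Image3D,
    bins: int = 32,
    region: LabelMap3D | None = None,
) -> float:
    """L_I = -MI(ref, warped floating); minimized by the registrations."""
    return -mutual_information(joint_histogram(ref, flo_warped, bins, region))


def segmentation_loss(
    ref_labels: LabelMap3D,
    warped_channels: dict[int, np.ndarray],
) -> float:
    """L_S: sum of squared channel differences between segmentations.

    ``warped_channels`` maps each foreground class to its (soft) warped
    binary channel; the reference label map is expanded to matching binary
    channels.  Classes must agree between the two sides.
    """
    ref_channels = ref_labels.channels()
    if set(ref_channels) != set(warped_channels):
        raise ValueError(
            f"segmentation channel mismatch: reference {sorted(ref_channels)} "
            f"vs warped {sorted(warped_channels)}"
        )
    total = 0.0
    for lab, ref_chan in ref_channels.items():
        w = np.asarray(warped_channels[lab], dtype=float)
        if w.shape != ref_chan.shape:
            raise ValueError("warped channel shape mismatch")
        total += float(np.sum((ref_chan - w) ** 2))
    return total


# ---------------------------------------------------------------------------
# Smoothed MI machinery for gradient-based non-rigid optimization.  The hard
# histogram above is what traces and reports use; the non-rigid optimizer
# needs a differentiable surrogate, built here as a Gaussian-smoothed joint
# density whose log-likelihood-ratio table is sampled per voxel.
# ---------------------------------------------------------------------------


def mi_voxel_weights(
    ref_vals: np.ndarray,
    flo_vals: np.ndarray,
    mask: np.ndarray,
    bins: int = 32,
    sigma_bins: float = 1.0,
) -> np.ndarray:
    """Per-voxel d(MI)/d(floating intensity) on the masked voxels.

    Writes MI as the sample mean of L(a, b) = ln p(a,b) - ln pa(a) - ln pb(b)
    over voxel pairs, smooths the joint density with a Gaussian of
    ``sigma_bins`` so L is effectively differentiable in b, and returns the
    derivative of L along the floating-intensity axis at each voxel (per
    intensity unit, already divided by the sample count).  Zero where the
    floating range is degenerate.
    """
    from scipy.ndimage import gaussian_filter

    a = ref_vals[mask]
    b = flo_vals[mask]
    n = a.size
    lo_a, hi_a = float(a.min()), float(a.max())
    lo_b, hi_b = float(b.min()), float(b.max())
    if hi_a <= lo_a or hi_b <= lo_b:
        return np.zeros(ref_vals.shape)
    ia = np.clip(((a - lo_a) / (hi_a - lo_a) * bins).astype(int), 0, bins - 1)
    ib = np.clip(((b - lo_b) / (hi_b - lo_b) * bins).astype(int), 0, bins - 1)
    counts = np.zeros((bins, bins))
    np.add.at(counts, (ia, ib), 1.0)
    p = gaussian_filter(counts / n, sigma_bins, mode="constant")
    p = np.maximum(p, 1e-12)
    p /= p.sum()
    table = np.log(p) - np.log(p.sum(axis=1, keepdims=True)) - np.log(p.sum(axis=0, keepdims=True))
    # dL/db in bin units, converted to intensity units
    dtable = np.gradient(table, axis=1) * (bins / (hi_b - lo_b))
    out = np.zeros(ref_vals.shape)
    out[mask] = dtable[ia, ib] / n
    return out
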