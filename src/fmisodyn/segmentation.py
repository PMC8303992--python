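"""Hypoxic sub-volume (HSV) segmentation by target-to-background ratio.

A voxel inside the clinician-drawn boost volume belongs to the HSV when its
SUV is at least ``tbr`` times the mean SUV of a background reference region
(TBR threshold, default 1.4).  The background is supplied as a user-drawn ROI
mask; its mean SUV defines BG.  An optional helper builds a simple automatic
ROI far from the boost volume for synthetic or exploratory use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, PETVolume, check_same_grid


@dataclass(frozen=True)
class BackgroundEstimate:
    """Summary of the background reference region (BG)."""

    mean_suv: float
    sd_suv: float
    n_voxels: int
    roi_role: str = "background"

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("background ROI must contain at least one voxel")
        if self.mean_suv <= 0:
            raise ValueError("background mean SUV must be > 0 (TBR undefined otherwise)")


def estimate_background(volume: PETVolume, roi: BinaryMask) -> BackgroundEstimate:
    """Mean and sample standard deviation of SUV over the background ROI."""
    check_same_grid(volume, roi, what="background ROI")
    vals = volume.values[roi.values]
    if vals.size == 0:
        raise ValueError("background ROI is empty")
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError("background ROI mean SUV is 0; TBR is undefined")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return BackgroundEstimate(mean, sd, int(vals.size), roi.role)


def segment_hsv(
    volume: PETVolume,
    boost: BinaryMask,
    bg: BackgroundEstimate,
    tbr: float = 1.4,
    inclusive_threshold: bool = True,
    min_component_voxels: int = 0,
) -> BinaryMask:
    """Threshold the boost volume at ``tbr × bg.mean_suv``.

    The comparison is inclusive (>=) by default.  An empty result is a valid
    outcome — it marks a patient without hypoxic volume at that time-point.
    ``min_component_voxels > 0`` drops 26-connected components smaller than
    the given size (off by default; no such step in the standard procedure).
    """
    if tbr <= 1:
        raise ValueError(f"tbr must be > 1, got {tbr}")
    check_same_grid(volume, boost, what="boost mask")
    cutoff = tbr * bg.mean_suv
    if inclusive_threshold:
        hsv = boost.values & (volume.values >= cutoff)
    else:
        hsv = boost.values & (volume.values > cutoff)
    if min_component_voxels > 0 and hsv.any():
        labels, n = ndimage.label(hsv, structure=np.ones((3, 3, 3), dtype=bool))
        if n:
            sizes = ndimage.sum_labels(hsv, labels, index=np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= min_component_voxels) + 1
            hsv = np.isin(labels, keep)
    return BinaryMask(hsv, volume.spacing, volume.origin, role="HSV")


def transfer_contour(mask_w0: BinaryMask, target: PETVolume) -> BinaryMask:
    """Re-bind the baseline HSV voxel set to a co-registered later time-point.

    Radiomic features at W2/W5 are always computed inside the transferred
    baseline contour, so the voxel set is copied verbatim after the grids are
    verified to match.
    """
    check_same_grid(mask_w0, target, what="contour transfer")
    return BinaryMask(mask_w0.values.copy(), target.spacing, target.origin, mask_w0.role)


def suggest_background_roi(
    volume: PETVolume,
    boost: BinaryMask,
    margin_mm: float = 20.0,
    max_voxels: int = 4000,
) -> BinaryMask:
    """Build a crude automatic background ROI away from the boost volume.

    Dilates the boost by ``margin_mm``, then keeps a central block of the
    remaining voxels (eroded once to avoid grid edges).  Intended for synthetic
    data and exploration; clinical use should supply an expert-drawn ROI.
    """
    check_same_grid(volume, boost, what="background ROI suggestion")
    iter_vox = max(1, int(np.ceil(margin_mm / min(volume.spacing))))
    far = ~ndimage.binary_dilation(boost.values, iterations=iter_vox)
    far &= ndimage.binary_erosion(np.ones_like(far), iterations=2, border_value=0)
    if not far.any():
        raise ValueError("no voxels left outside the dilated boost volume")
    idx = np.flatnonzero(far.ravel())
    if idx.size > max_voxels:
        keep = np.zeros(far.size, dtype=bool)
        keep[idx[: max_voxels]] = True
        far = keep.reshape(far.shape)
    return BinaryMask(far, volume.spacing, volume.origin, role="background")
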