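"""Image-quality measures on CBCT volumes: ROI statistics, CNR, line profiles.

The contrast-to-noise ratio between two circular tissue ROIs is

    CNR = |mean_x - mean_y| / sqrt((sd_x^2 + sd_y^2) / 2)

and applicator visibility is quantified by lateral/vertical CT-number line
profiles through each applicator tip in its axial slice: the profile peak is
compared with the mean background (excluding adjacent applicators and bone),
and the peak-minus-background deltas are tested with a one-sided one-sample
t-test (H1: mean delta > 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .grids import VoxelGrid
from .stats import one_sample_t

ROI_LABELS = ("uterus", "bladder", "fat")


@dataclass
class ROISpec:
    """Circular in-slice region of interest."""

    slice_index: int
    center_mm: tuple  # (x, y) world mm within the axial slice
    radius_mm: float
    label: str = "uterus"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("ROI radius must be positive")


@dataclass
class ProfileResult:
    """One CT-number line profile through an applicator tip."""

    positions_mm: np.ndarray  # signed offset from the tip along the profile
    values_hu: np.ndarray
    peak_hu: float
    background_mean_hu: float
    background_sd_hu: float
    delta_hu: float
    excluded: np.ndarray  # True where a sample was excluded from background
    axis: str = "lateral"

    def __post_init__(self) -> None:
        assert np.isclose(self.delta_hu, self.peak_hu - self.background_mean_hu)


def roi_stats(volume: VoxelGrid, roi: ROISpec) -> tuple[float, float, int]:
    """Mean HU, sample SD, and voxel count of a circular ROI.

    Membership is by voxel centre inside the disk; no partial voxels.
    """
    k = int(roi.slice_index)
    if not 0 <= k < volume.shape[2]:
        raise ValueError(f"slice index {k} outside volume of shape {volume.shape}")
    nx, ny = volume.shape[0], volume.shape[1]
    x = volume.origin[0] + np.arange(nx) * volume.spacing[0]
    y = volume.origin[1] + np.arange(ny) * volume.spacing[1]
    cx, cy = roi.center_mm
    rr = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
    inside = rr <= roi.radius_mm**2
    lo_x = cx - roi.radius_mm < x[0] - volume.spacing[0] / 2
    hi_x = cx + roi.radius_mm > x[-1] + volume.spacing[0] / 2
    lo_y = cy - roi.radius_mm < y[0] - volume.spacing[1] / 2
    hi_y = cy + roi.radius_mm > y[-1] + volume.spacing[1] / 2
    if lo_x or hi_x or lo_y or hi_y:
        raise ValueError("ROI extends outside the volume")
    n = int(inside.sum())
    if n < 2:
        raise ValueError(f"ROI contains {n} voxel(s); need at least 2")
    vals = volume.data[:, :, k][inside].astype(float)
    return float(vals.mean()), float(vals.std(ddof=1)), n


def cnr(stats_x: Sequence[float], stats_y: Sequence[float]) -> float:
    """Contrast-to-noise ratio between two ROIs given (mean, sd[, n]) each."""
    mx, sx = float(stats_x[0]), float(stats_x[1])
    my, sy = float(stats_y[0]), float(stats_y[1])
    if not (np.isfinite(sx) and np.isfinite(sy)):
        raise ValueError("ROI standard deviations must be finite")
    if sx == 0.0 and sy == 0.0:
        if mx == my:
            return 0.0
        raise ValueError("both SDs are zero with unequal means: CNR is infinite")
    return abs(mx - my) / np.sqrt((sx**2 + sy**2) / 2.0)


def extract_line_profile(
    volume: VoxelGrid,
    tip_mm: Sequence[float],
    axis: str = "lateral",
    length_mm: float = 40.0,
    exclusion_masks: Iterable[VoxelGrid] = (),
    peak_halfwidth_mm: float = 2.0,
) -> ProfileResult:
    """CT-number line profile through an applicator tip in its axial slice.

    ``lateral`` runs along world x, ``vertical`` along world y. Samples are
    taken at voxel-spacing steps centred on the tip. The peak is the maximum
    HU within ``peak_halfwidth_mm`` of the tip; the background statistics use
    all remaining samples not covered by an exclusion mask (adjacent
    applicators, bone).
    """
    if axis not in ("lateral", "vertical"):
        raise ValueError("axis must be 'lateral' or 'vertical'")
    tip = np.asarray(tip_mm, dtype=float).reshape(3)
    ax = 0 if axis == "lateral" else 1
    step = float(volume.spacing[ax])
    half = int(np.floor(length_mm / 2.0 / step))
    offsets = np.arange(-half, half + 1) * step
    k = int(np.rint((tip[2] - volume.origin[2]) / volume.spacing[2]))
    if not 0 <= k < volume.shape[2]:
        raise ValueError("tip axial slice outside the volume")
    z = volume.origin[2] + k * volume.spacing[2]
    pts = np.tile(np.array([tip[0], tip[1], z]), (offsets.size, 1))
    pts[:, ax] = tip[ax] + offsets
    fidx = (pts - volume.origin) / volume.spacing
    if np.any(fidx < 0) or np.any(fidx > np.asarray(volume.shape) - 1):
        raise ValueError("line profile extends outside the volume")
    values = volume.sample_linear(pts)

    in_peak = np.abs(offsets) <= peak_halfwidth_mm + 1e-9
    excluded = np.zeros(offsets.size, dtype=bool)
    for mask in exclusion_masks:
        excluded |= mask.sample_nearest(pts) > 0.5
    bg = ~in_peak & ~excluded
    if bg.sum() < 3:
        raise ValueError(
            f"only {int(bg.sum())} background samples remain; need at least 3"
        )
    peak = float(values[in_peak].max())
    bg_mean = float(values[bg].mean())
    bg_sd = float(values[bg].std(ddof=1))
    return ProfileResult(
        positions_mm=offsets,
        values_hu=values,
        peak_hu=peak,
        background_mean_hu=bg_mean,
        background_sd_hu=bg_sd,
        delta_hu=peak - bg_mean,
        excluded=excluded,
        axis=axis,
    )


def peak_significance(deltas: Sequence[float], alpha: float = 0.05):
    """One-sided one-sample t-test of H0: mean peak delta <= 0.

    Returns ``(t, p)``; a zero-variance sample uses the documented convention
    p = 0 if the mean is positive, else p = 1.
    """
    res = one_sample_t(np.asarray(deltas, dtype=float), popmean=0.0,
                       alternative="greater", alpha=alpha)
    return res.statistic, res.pvalue
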