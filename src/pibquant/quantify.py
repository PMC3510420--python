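"""Retention-ratio quantification: frame integration, cerebellar-median
scaling, regional/composite readouts, FOV QC and template averaging.

Scaling by the *median* cerebellar grey-matter voxel value (rather than the
mean) makes the reference insensitive to outlier voxels in low count-rate
slices; everything downstream is therefore a unitless retention ratio with
the scaled cerebellar median identically 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maskbuild import RoiSet
from .synthcohort import FrameSeries

#: Default integration window in minutes (maximal window common to centres).
DEFAULT_WINDOW = (40.0, 60.0)

#: A subject is excluded when more than this fraction of the cerebellar
#: reference lies outside the axial field of view (strict inequality).
FOV_EXCLUSION_FRACTION = 0.25


@dataclass
class RegionalRetention:
    """Per-subject scaled regional retention values and QC state."""

    subject_id: str
    centre: str
    cereb_median: float
    regional: dict[str, float]           # label -> mean scaled ratio
    composite: float | None              # neocortical composite
    qc_excluded: bool = False
    qc_reason: str | None = None
    missing_rois: tuple[str, ...] = field(default=())


def integrate_frames(frames: FrameSeries,
                     window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    """Voxelwise sum of the frames lying entirely within ``window``.

    A frame contributes only when [start, end] is contained in the window;
    partially overlapping frames are ignored.
    """
    lo, hi = window
    idx = [i for i, (s, e) in enumerate(frames.schedule) if s >= lo and e <= hi]
    if not idx:
        raise ValueError(f"no frames fully inside window {window}")
    return frames.data[idx].sum(axis=0)


def cerebellar_median(volume: np.ndarray, cerebellum: np.ndarray) -> float:
    """Median voxel value under the cerebellar mask (even count: mean of the
    two central order statistics)."""
    if not cerebellum.any():
        raise ValueError("empty cerebellar mask")
    return float(np.median(volume[cerebellum]))


def check_fov(cerebellum: np.ndarray,
              fov_z_range: tuple[int, int] | None) -> tuple[float, bool]:
    """Fraction of cerebellar reference voxels outside the axial FOV slab and
    the exclusion decision (excluded iff fraction > 0.25, strictly)."""
    n = int(cerebellum.sum())
    if n == 0 or fov_z_range is None:
        return 0.0, False
    z0, z1 = fov_z_range
    inside = cerebellum.copy()
    inside[..., :z0] = False
    inside[..., z1:] = False
    fraction_outside = 1.0 - int(inside.sum()) / n
    return fraction_outside, fraction_outside > FOV_EXCLUSION_FRACTION


def ratio_image(volume: np.ndarray, cereb_median: float) -> np.ndarray:
    """Voxelwise division by the subject's cerebellar median."""
    if not cereb_median > 0:
        raise ValueError("cerebellar median must be > 0")
    return volume / cereb_median


def regional_means(ratio: np.ndarray, rois: RoiSet) -> tuple[dict[str, float],
                                                             tuple[str, ...]]:
    """Arithmetic mean of ratio voxels per ROI; empty ROIs are reported as
    missing rather than raising."""
    values: dict[str, float] = {}
    missing: list[str] = []
    for name, mask in rois.rois.items():
        if mask.any():
            values[name] = float(ratio[mask].mean())
        else:
            missing.append(name)
    return values, tuple(missing)


def neocortical_composite(regional: dict[str, float],
                          labels: tuple[str, ...] | None = None) -> float:
    """Unweighted mean of the neocortical constituent ROI values."""
    from .templates import NEOCORTICAL_LABELS
    labels = labels or NEOCORTICAL_LABELS
    try:
        return float(np.mean([regional[name] for name in labels]))
    except KeyError as err:
        raise ValueError(f"composite constituent missing: {err}") from err


def build_template(ratio_volumes: list[np.ndarray]) -> np.ndarray:
    """Voxelwise average of scaled ratio images (sample-based template)."""
    if not ratio_volumes:
        raise ValueError("need at least one volume")
    shape = ratio_volumes[0].shape
    if any(v.shape != shape for v in ratio_volumes):
        raise ValueError("grid mismatch between volumes")
    return np.mean(ratio_volumes, axis=0)


def quantify_subject(subject_id: str, centre: str, frames: FrameSeries,
                     rois: RoiSet,
                     window: tuple[float, float] = DEFAULT_WINDOW
                     ) -> RegionalRetention:
    """Full single-subject quantification with FOV QC.

    The FOV check uses the eroded cerebellar reference in template space; an
    excluded subject carries no regional values.
    """
    fraction_outside, excluded = check_fov(rois.cerebellum, frames.fov_z_range)
    if excluded:
        return RegionalRetention(
            subject_id=subject_id, centre=centre, cereb_median=np.nan,
            regional={}, composite=None, qc_excluded=True,
            qc_reason=f"fov:{fraction_outside:.3f}")
    integral = integrate_frames(frames, window)
    # restrict the reference to in-FOV voxels (<=25 % may be truncated)
    cereb = rois.cerebellum
    if frames.fov_z_range is not None:
        z0, z1 = frames.fov_z_range
        cereb = cereb.copy()
        cereb[..., :z0] = False
        cereb[..., z1:] = False
    median = cerebellar_median(integral, cereb)
    ratio = ratio_image(integral, median)
    regional, missing = regional_means(ratio, rois)
    try:
        composite = neocortical_composite(regional, rois.neocortical_labels)
    except ValueError:
        composite = None
    return RegionalRetention(
        subject_id=subject_id, centre=centre, cereb_median=median,
        regional=regional, composite=composite, missing_rois=missing)
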