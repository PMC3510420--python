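"""Grey-matter mask construction and atlas ROI extraction.

The mask recipe mirrors the study pipeline: average the individual
grey-matter probability maps, threshold at 50 %, erode by two voxels, then
intersect with the label atlas to obtain the 23 cortical/subcortical ROIs and
the cerebellar reference region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .templates import Atlas, CEREBELLUM, NEOCORTICAL_LABELS, ROI_NAMES

log = logging.getLogger(__name__)


class MaskQCError(ValueError):
    """Raised when mask construction produces an unusable result."""


@dataclass
class RoiSet:
    """Binarized eroded grey-matter mask intersected with the atlas."""

    gm_mask: np.ndarray
    rois: dict[str, np.ndarray]
    cerebellum: np.ndarray
    neocortical_labels: tuple[str, ...] = NEOCORTICAL_LABELS
    empty_rois: tuple[str, ...] = field(default=())

    def validate(self) -> None:
        shape = self.gm_mask.shape
        total = np.zeros(shape, dtype=int)
        for name, roi in self.rois.items():
            if roi.shape != shape:
                raise MaskQCError(f"ROI {name} grid mismatch")
            if np.any(roi & ~self.gm_mask):
                raise MaskQCError(f"ROI {name} not contained in gm_mask")
            total += roi.astype(int)
        total += self.cerebellum.astype(int)
        if total.max() > 1:
            raise MaskQCError("ROIs/cerebellum not pairwise disjoint")


def build_gm_mask(prob_maps: list[np.ndarray], threshold: float = 0.5) -> np.ndarray:
    """Voxel included iff the mean probability across maps >= threshold.

    Equivalent to summing the maps and thresholding at half their count;
    the boundary is inclusive.
    """
    if len(prob_maps) == 0:
        raise ValueError("need at least one probability map")
    shape = prob_maps[0].shape
    for m in prob_maps:
        if m.shape != shape:
            raise MaskQCError("probability maps on different grids")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("probability values outside [0, 1]")
    mask = np.mean(prob_maps, axis=0) >= threshold
    if not mask.any():
        raise MaskQCError("thresholded grey-matter mask is empty")
    return mask


def erode_mask(mask: np.ndarray, iterations: int = 2,
               connectivity: str = "face") -> np.ndarray:
    """Iterated one-voxel binary erosion.

    ``connectivity="face"`` uses the 6-connected structuring element (the
    default reading of eroding "by two voxels in all dimensions");
    ``"full"`` uses the 26-connected element.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mask.copy()
    structure = ndimage.generate_binary_structure(
        3, 1 if connectivity == "face" else 3)
    out = ndimage.binary_erosion(mask, structure, iterations=iterations)
    if not out.any():
        log.warning("erosion produced an empty mask")
    return out


def intersect_atlas(gm_mask: np.ndarray, atlas: Atlas,
                    strict: bool = False) -> RoiSet:
    """Intersect the (eroded) grey-matter mask with the atlas labels.

    Empty ROIs are flagged in ``RoiSet.empty_rois`` (or raise when
    ``strict``). An all-empty result raises ``MaskQCError``.
    """
    if gm_mask.shape != atlas.shape:
        raise MaskQCError("grid mismatch between mask and atlas")
    name_to_label = atlas.name_to_label
    for name in list(ROI_NAMES) + [CEREBELLUM]:
        if name not in name_to_label:
            raise MaskQCError(f"atlas missing expected label {name!r}")
    rois = {name: (atlas.labels == name_to_label[name]) & gm_mask
            for name in ROI_NAMES}
    cereb = atlas.mask(CEREBELLUM) & gm_mask
    empty = tuple(n for n, m in rois.items() if not m.any())
    if not cereb.any():
        empty = empty + (CEREBELLUM,)
    if len(empty) == len(rois) + 1:
        raise MaskQCError("all ROIs empty after intersection")
    if empty:
        msg = f"empty ROIs after intersection: {empty}"
        if strict:
            raise MaskQCError(msg)
        log.warning(msg)
    roi_set = RoiSet(gm_mask=gm_mask, rois=rois, cerebellum=cereb,
                     empty_rois=empty)
    roi_set.validate()
    return roi_set


def build_roi_set(prob_maps: list[np.ndarray], atlas: Atlas,
                  erode_iterations: int = 2,
                  connectivity: str = "face") -> RoiSet:
    """Full mask pipeline: threshold, erode, intersect."""
    mask = erode_mask(build_gm_mask(prob_maps), erode_iterations, connectivity)
    return intersect_atlas(mask, atlas)
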