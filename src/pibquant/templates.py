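"""Synthetic template-space geometry: label atlas and image grid.

The package operates entirely in a fixed "MNI-like" template grid. The real
study's anatomical atlas is replaced by a programmatically drawn parcellation:
a cerebral ellipsoid whose grey-matter shell is divided into 19 cortical
sectors, four subcortical nuclei embedded in the white-matter core, a separate
cerebellar ellipsoid (the reference region) and a white-matter core. All
downstream code addresses regions by name, never by geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

# Region names. Order defines the integer label (1-based).
CORTICAL_MIDDLE = [
    "frontal",
    "anterior_cingulate",
    "insula",
    "temporal_lateral_basal",
    "occipital_lateral",
    "angular",
    "posterior_cingulate",
    "parietal",
]
CORTICAL_SUPERIOR = [
    "frontal_superior",
    "sensorimotor",
    "paracentral",
    "parietal_superior",
    "precuneus",
    "supramarginal",
]
CORTICAL_INFERIOR = [
    "orbitofrontal",
    "temporal_pole",
    "fusiform",
    "lingual",
    "occipital_inferior",
]
SUBCORTICAL = ["caudate", "putamen", "thalamus", "hippocampus"]

ROI_NAMES = CORTICAL_MIDDLE + CORTICAL_SUPERIOR + CORTICAL_INFERIOR + SUBCORTICAL
assert len(ROI_NAMES) == 23

CEREBELLUM = "cerebellum"
WHITE_MATTER = "white_matter"

#: Regions averaged into the neocortical composite readout.
NEOCORTICAL_LABELS = ("frontal", "parietal", "temporal_lateral_basal")

CEREBELLUM_LABEL = 24
WHITE_MATTER_LABEL = 25

DEFAULT_SHAPE = (64, 64, 48)
DEFAULT_VOXEL_MM = 3.0

# Normalized ([0,1] per axis) ellipsoid geometry.
_CEREBRUM_CENTRE = (0.50, 0.52, 0.62)
_CEREBRUM_SEMI = (0.40, 0.44, 0.30)
_CORE_SEMI = (0.26, 0.29, 0.19)
_CEREBELLUM_CENTRE = (0.50, 0.40, 0.15)
_CEREBELLUM_SEMI = (0.22, 0.18, 0.12)
# Subcortical nuclei: (dx, dy) offsets from the cerebrum centre, shared semi-axes.
_NUCLEUS_OFFSETS = {
    "caudate": (-0.13, +0.09),
    "putamen": (+0.13, +0.09),
    "thalamus": (-0.13, -0.09),
    "hippocampus": (+0.13, -0.09),
}
_NUCLEUS_SEMI = (0.09, 0.09, 0.13)
# Elevation-angle band edges (radians) separating inferior/middle/superior cortex.
_BAND_INferior = -0.45
_BAND_SUPERIOR = 0.55


@dataclass(frozen=True)
class Atlas:
    """A label volume plus its naming and geometry metadata."""

    labels: np.ndarray  # int16, shape (nx, ny, nz)
    voxel_mm: float
    label_names: dict[int, str] = field(repr=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_mm] * 3 + [1.0])
        return aff

    @property
    def name_to_label(self) -> dict[str, int]:
        return {v: k for k, v in self.label_names.items()}

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.name_to_label[name]

    @property
    def gm_indicator(self) -> np.ndarray:
        """Grey matter = the 23 ROIs plus cerebellar grey."""
        return (self.labels >= 1) & (self.labels <= CEREBELLUM_LABEL)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.labels.astype(np.int16), self.affine)


def _ellipsoid(grid, centre, semi, shape):
    x, y, z = grid
    cx, cy, cz = (c * s for c, s in zip(centre, shape))
    ax, ay, az = (a * s for a, s in zip(semi, shape))
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def build_atlas(shape: tuple[int, int, int] = DEFAULT_SHAPE,
                voxel_mm: float = DEFAULT_VOXEL_MM) -> Atlas:
    """Draw the synthetic 23-ROI + cerebellum + white-matter label volume.

    ``shape`` scales the same normalized geometry, so a reduced grid (e.g.
    ``(32, 32, 24)`` at 6 mm) yields the same parcellation topology at lower
    resolution.
    """
    nx, ny, nz = shape
    grid = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    labels = np.zeros(shape, dtype=np.int16)

    cerebrum = _ellipsoid(grid, _CEREBRUM_CENTRE, _CEREBRUM_SEMI, shape)
    core = _ellipsoid(grid, _CEREBRUM_CENTRE, _CORE_SEMI, shape)
    shell = cerebrum & ~core

    name_to_label = {name: i + 1 for i, name in enumerate(ROI_NAMES)}

    # Cortical sectors: elevation band then azimuth bin around the centre.
    x, y, z = grid
    cx, cy, cz = (c * s for c, s in zip(_CEREBRUM_CENTRE, shape))
    ax, ay, az = (a * s for a, s in zip(_CEREBRUM_SEMI, shape))
    dx, dy, dz = (x - cx) / ax, (y - cy) / ay, (z - cz) / az
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        elev = np.arcsin(np.clip(np.where(r > 0, dz / r, 0.0), -1, 1))
    azim = np.arctan2(dx, dy)  # 0 = anterior (+y), range (-pi, pi]

    bands = {
        "inferior": (shell & (elev < _BAND_INferior), CORTICAL_INFERIOR, 0.3),
        "middle": (shell & (elev >= _BAND_INferior) & (elev <= _BAND_SUPERIOR),
                   CORTICAL_MIDDLE, 0.0),
        "superior": (shell & (elev > _BAND_SUPERIOR), CORTICAL_SUPERIOR, 0.5),
    }
    for band_mask, names, offset in bands.values():
        k = len(names)
        sector = np.floor((azim + np.pi + offset) / (2 * np.pi) * k).astype(int) % k
        for i, name in enumerate(names):
            labels[band_mask & (sector == i)] = name_to_label[name]

    # White matter core (subcortical nuclei carved out below).
    labels[core] = WHITE_MATTER_LABEL

    inner_core = _ellipsoid(grid, _CEREBRUM_CENTRE,
                            tuple(0.93 * s for s in _CORE_SEMI), shape)
    for name, (ox, oy) in _NUCLEUS_OFFSETS.items():
        centre = (_CEREBRUM_CENTRE[0] + ox, _CEREBRUM_CENTRE[1] + oy,
                  _CEREBRUM_CENTRE[2])
        blob = _ellipsoid(grid, centre, _NUCLEUS_SEMI, shape) & inner_core
        labels[blob & (labels == WHITE_MATTER_LABEL)] = name_to_label[name]

    cereb = _ellipsoid(grid, _CEREBELLUM_CENTRE, _CEREBELLUM_SEMI, shape)
    labels[cereb & (labels == 0)] = CEREBELLUM_LABEL

    label_names = dict(sorted({v: k for k, v in name_to_label.items()}.items()))
    label_names[CEREBELLUM_LABEL] = CEREBELLUM
    label_names[WHITE_MATTER_LABEL] = WHITE_MATTER
    return Atlas(labels=labels, voxel_mm=voxel_mm, label_names=label_names)
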