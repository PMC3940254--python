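"""SUV computation and tumor VOI delineation for small-animal uptake volumes.

The tumor volume of interest is auto-delineated at a fixed fraction (default
40%) of the maximum SUV inside a user-supplied search region, keeping the
26-connected component that contains the maximum voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "UptakeVolume",
    "VOI",
    "to_suv",
    "delineate_tumor",
    "suv_stats",
    "tumor_to_muscle",
    "percent_id_per_gram",
]

#: default in-plane voxel size / plane separation in mm
DEFAULT_VOXEL_SIZE_MM = (0.43, 0.43, 0.8)


@dataclass
class UptakeVolume:
    """A 3-D activity-concentration grid plus injection metadata.

    Attributes
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Activity concentration in MBq/mL, decay-corrected to scan start.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    injected_activity : float
        Injected activity in MBq, decay-corrected to scan start.
    body_weight : float
        Animal body weight in g.
    sample_id : str
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM
    injected_activity: float = 10.0
    body_weight: float = 20.0
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("uptake volume must be 3-D")
        if np.any(self.voxels < 0):
            raise ValueError("activity concentrations must be non-negative")
        if self.injected_activity <= 0:
            raise ValueError("injected_activity must be positive")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz / 1000.0  # mm^3 -> mL


@dataclass
class VOI:
    """A binary volume of interest."""

    mask: np.ndarray
    kind: str = "tumor"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("VOI mask must be 3-D")
        if not self.mask.any():
            raise ValueError("VOI mask is empty")
        if self.kind not in ("tumor", "muscle"):
            raise ValueError(f"unknown VOI kind {self.kind!r}")


def to_suv(volume: UptakeVolume, decay_factor: float = 1.0) -> np.ndarray:
    """Convert an activity-concentration grid to standardized uptake values.

    ``SUV = C * decay_factor / (injected_activity / body_weight)`` with a
    tissue density of 1 g/mL assumed, so that a concentration equal to the
    injected activity per gram of body weight maps to SUV 1.

    Parameters
    ----------
    decay_factor : float
        Residual decay correction; 1.0 if the inputs are already corrected
        to scan start.
    """
    if decay_factor <= 0:
        raise ValueError("decay_factor must be positive")
    return volume.voxels * decay_factor / (volume.injected_activity / volume.body_weight)


def delineate_tumor(suv: np.ndarray, search_region: VOI, frac: float = 0.40) -> VOI:
    """Auto-delineate the tumor VOI at ``frac`` of the maximum SUV.

    Candidate voxels are those inside ``search_region`` with
    ``SUV >= frac * SUVmax`` (SUVmax taken within the search region).  The
    returned VOI is the 26-connected component of the candidate set that
    contains the maximum voxel; when several voxels tie at the maximum, all
    of their components are included.
    """
    suv = np.asarray(suv, dtype=float)
    if suv.shape != search_region.mask.shape:
        raise ValueError("SUV grid and search region shapes differ")
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    region = search_region.mask
    suv_max = suv[region].max()
    candidates = region & (suv >= frac * suv_max)
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, _ = ndimage.label(candidates, structure=structure)
    max_labels = np.unique(labels[region & (suv == suv_max)])
    return VOI(np.isin(labels, max_labels) & (labels > 0), kind="tumor")


def suv_stats(suv: np.ndarray, voi: VOI) -> tuple[float, float]:
    """Maximum and mean SUV over a VOI."""
    suv = np.asarray(suv, dtype=float)
    if suv.shape != voi.mask.shape:
        raise ValueError("SUV grid and VOI shapes differ")
    values = suv[voi.mask]
    return float(values.max()), float(values.mean())


def tumor_to_muscle(tumor_mean: float, muscle_mean: float) -> float:
    """Tumor-to-muscle uptake ratio."""
    if muscle_mean <= 0:
        raise ValueError("muscle mean uptake must be positive")
    return tumor_mean / muscle_mean


def percent_id_per_gram(tissue_activity: float, injected_activity: float,
                        tissue_weight: float) -> float:
    """Percent of the injected dose per gram of tissue.

    ``100 * (tissue_activity / injected_activity) / tissue_weight``; both
    activities must share units and be decay-corrected consistently.
    """
    if injected_activity <= 0:
        raise ValueError("injected_activity must be positive")
    if tissue_weight <= 0:
        raise ValueError("tissue_weight must be positive")
    if tissue_activity < 0:
        raise ValueError("tissue_activity must be non-negative")
    return 100.0 * (tissue_activity / injected_activity) / tissue_weight
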