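"""Quantification of grayscale IHC marker images.

Converts a single-marker grayscale scan plus viable-tumor / necrosis masks
into scalar parameters: staining fraction, labeling index, vascular density
and perfused vessel fraction.  All area computations exclude necrotic
regions; connected structures use 8-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

__all__ = [
    "MarkerImage",
    "BinaryMask",
    "NucleusSet",
    "segment",
    "staining_fraction",
    "labeling_index",
    "vascular_density",
    "perfused_fraction",
]

#: default micrometres per pixel of the digitised sections
DEFAULT_PIXEL_SIZE_UM = 2.59

#: default grey-value dynamic range (12 bit)
DEFAULT_DYNAMIC_RANGE = 4095


@dataclass
class BinaryMask:
    """A boolean pixel mask with physical pixel size.

    Parameters
    ----------
    pixels : ndarray of bool, shape (H, W)
    pixel_size : float
        Edge length of one pixel in micrometres.
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def area_pixels(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_mm2(self) -> float:
        """Mask area in mm^2 (pixel count times pixel_size^2)."""
        return self.area_pixels * (self.pixel_size / 1000.0) ** 2


@dataclass
class MarkerImage:
    """One grayscale IHC marker scan with its masks and segmentation threshold.

    Attributes
    ----------
    pixels : ndarray, shape (H, W)
        Grey values in ``[0, dynamic_range]``.
    pixel_size : float
        Micrometres per pixel.
    marker_name : str
    threshold : float
        Grey value separating signal from background; pixels with value
        greater than or equal to the threshold are positive.
    viable_mask : ndarray of bool
        Viable tumor area.
    necrosis_mask : ndarray of bool
        Necrotic area, excluded from all analyses.
    dynamic_range : float
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    marker_name: str = "marker"
    threshold: float | None = None
    viable_mask: np.ndarray | None = None
    necrosis_mask: np.ndarray | None = None
    dynamic_range: float = DEFAULT_DYNAMIC_RANGE

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2-D")
        if self.viable_mask is None:
            self.viable_mask = np.ones(self.pixels.shape, dtype=bool)
        self.viable_mask = np.asarray(self.viable_mask, dtype=bool)
        if self.necrosis_mask is None:
            self.necrosis_mask = np.zeros(self.pixels.shape, dtype=bool)
        self.necrosis_mask = np.asarray(self.necrosis_mask, dtype=bool)
        for name, mask in (("viable_mask", self.viable_mask),
                           ("necrosis_mask", self.necrosis_mask)):
            if mask.shape != self.pixels.shape:
                raise ValueError(f"{name} shape {mask.shape} does not match "
                                 f"image shape {self.pixels.shape}")
        if self.threshold is not None and not 0 < self.threshold <= self.dynamic_range:
            raise ValueError("threshold must lie in (0, dynamic_range]")

    @property
    def analysis_mask(self) -> np.ndarray:
        """Viable area with necrosis excluded."""
        return self.viable_mask & ~self.necrosis_mask


@dataclass
class NucleusSet:
    """Point set of nuclei with per-nucleus positivity flags.

    Coordinates are ``(row, col)`` pixel positions.
    """

    coordinates: np.ndarray
    positive_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if self.positive_flags is None:
            self.positive_flags = np.zeros(len(self.coordinates), dtype=bool)
        self.positive_flags = np.asarray(self.positive_flags, dtype=bool)
        if len(self.positive_flags) != len(self.coordinates):
            raise ValueError("positive_flags length must match coordinates")

    def __len__(self) -> int:
        return len(self.coordinates)


def _require_congruent(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def segment(image: MarkerImage) -> BinaryMask:
    """Threshold a marker image into a binary positivity mask.

    A pixel is positive iff its grey value is >= ``image.threshold`` and it
    lies inside the viable area with necrosis excluded.

    Raises
    ------
    ValueError
        If the image has no threshold set.
    """
    if image.threshold is None:
        raise ValueError("image has no segmentation threshold set")
    positive = (image.pixels >= image.threshold) & image.analysis_mask
    return BinaryMask(positive, pixel_size=image.pixel_size)


def staining_fraction(positive: BinaryMask, viable: BinaryMask) -> float:
    """Fraction of the viable tumor area that stains positive.

    Returns ``|positive & viable| / |viable|``, a value in [0, 1].

    Raises
    ------
    ValueError
        If the viable mask is empty.
    """
    _require_congruent(positive.pixels, viable.pixels)
    denom = viable.area_pixels
    if denom == 0:
        raise ValueError("viable mask is empty")
    return float((positive.pixels & viable.pixels).sum()) / denom


def labeling_index(nuclei: NucleusSet, viable: BinaryMask) -> float:
    """Fraction of nuclei inside the viable area that are positive.

    Raises
    ------
    ValueError
        If no nucleus falls inside the viable area.
    """
    if len(nuclei) == 0:
        raise ValueError("no nuclei supplied")
    rows = np.clip(np.round(nuclei.coordinates[:, 0]).astype(int), 0,
                   viable.pixels.shape[0] - 1)
    cols = np.clip(np.round(nuclei.coordinates[:, 1]).astype(int), 0,
                   viable.pixels.shape[1] - 1)
    inside = viable.pixels[rows, cols]
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise ValueError("no nuclei inside the viable area")
    return float(nuclei.positive_flags[inside].sum()) / n_inside


def _count_structures(mask: np.ndarray) -> int:
    # 8-connectivity, the 2-D microscopy convention
    return int(measure.label(mask, connectivity=2).max())


def vascular_density(vessel_mask: BinaryMask, viable: BinaryMask) -> float:
    """Number of vascular structures per mm^2 of viable tumor.

    Structures are 8-connected components of ``vessel_mask & viable``.

    Raises
    ------
    ValueError
        If the viable mask is empty.
    """
    _require_congruent(vessel_mask.pixels, viable.pixels)
    area = viable.area_mm2
    if area == 0:
        raise ValueError("viable mask is empty")
    n = _count_structures(vessel_mask.pixels & viable.pixels)
    return n / area


def perfused_fraction(vessel_mask: BinaryMask, perfusion_mask: BinaryMask) -> float:
    """Fraction of vascular structures overlapping the perfusion signal.

    A structure counts as perfused when at least one of its pixels is set in
    ``perfusion_mask``.

    Raises
    ------
    ValueError
        If the vessel mask contains no structure.
    """
    _require_congruent(vessel_mask.pixels, perfusion_mask.pixels)
    labels = measure.label(vessel_mask.pixels, connectivity=2)
    n = int(labels.max())
    if n == 0:
        raise ValueError("no vascular structures in vessel mask")
    perfused_labels = np.unique(labels[perfusion_mask.pixels & (labels > 0)])
    return len(perfused_labels) / n
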