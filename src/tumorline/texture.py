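"""Global (first-order histogram) texture features.

Features are the mean (IHC only), skewness and Shannon entropy of the
intensity distribution inside a region: the tumor VOI for PET volumes, the
positively stained area for IHC images.  IHC intensities are linearly
rescaled by the segmentation threshold before analysis so that images of one
marker acquired at different gains become comparable; discretization uses
fixed bin widths (0.5 SUV for PET, 25 rescaled units for IHC), half-open
bins anchored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ihc import MarkerImage, segment
from .pet import VOI

__all__ = [
    "IntensitySample",
    "Histogram",
    "AREA_MARKERS",
    "RESCALE_REFERENCE",
    "PET_BIN_WIDTH",
    "IHC_BIN_WIDTH",
    "rescale_by_threshold",
    "discretize",
    "entropy",
    "skewness",
    "mean_intensity",
    "ihc_features",
    "pet_features",
    "extract_feature_block",
]

#: markers whose staining covers an area, eligible for texture features
AREA_MARKERS = ("PIMO", "BrdU", "pAKT", "EGFR", "MCT4", "CA9", "GLUT1")

#: rescaled grey value that the segmentation threshold is mapped onto
RESCALE_REFERENCE = 1000.0

PET_BIN_WIDTH = 0.5
IHC_BIN_WIDTH = 25.0


@dataclass
class IntensitySample:
    """Intensity values drawn from one region of one image or volume."""

    values: np.ndarray
    source: str = "IHC"
    region: str = "positive"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("intensity sample is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity sample contains non-finite values")


@dataclass
class Histogram:
    """First-order histogram over fixed-width bins anchored at zero.

    ``probabilities`` only lists occupied bins; ``n_levels`` is their count.
    """

    bin_width: float
    bin_indices: np.ndarray
    probabilities: np.ndarray
    n_levels: int = field(init=False)

    def __post_init__(self) -> None:
        self.bin_indices = np.asarray(self.bin_indices, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if np.any(self.probabilities <= 0):
            raise ValueError("only occupied bins may be listed")
        if not np.isclose(self.probabilities.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")
        self.n_levels = len(self.probabilities)


def rescale_by_threshold(image: MarkerImage, reference: float = RESCALE_REFERENCE) -> IntensitySample:
    """Rescale an IHC image by its segmentation threshold and sample the
    positively stained area.

    Every grey value is multiplied by ``reference / threshold`` so the
    threshold itself maps to ``reference`` for all images of one marker;
    only pixels in the positive (segmented) area are kept.
    """
    if image.threshold is None or image.threshold <= 0:
        raise ValueError("image needs a positive segmentation threshold")
    positive = segment(image)
    values = image.pixels[positive.pixels] * (reference / image.threshold)
    return IntensitySample(values, source=f"IHC:{image.marker_name}", region="positive")


def discretize(sample: IntensitySample | np.ndarray, bin_width: float) -> Histogram:
    """Bin intensities into half-open intervals ``[i*w, (i+1)*w)``."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = sample.values if isinstance(sample, IntensitySample) else np.asarray(sample, float)
    idx = np.floor(values / bin_width).astype(int)
    bins, counts = np.unique(idx, return_counts=True)
    return Histogram(bin_width=bin_width, bin_indices=bins,
                     probabilities=counts / counts.sum())


def entropy(hist: Histogram) -> float:
    """Shannon entropy of the histogram in bits: ``-sum P(i) log2 P(i)``."""
    p = hist.probabilities
    return float(-np.sum(p * np.log2(p)) + 0.0)  # +0.0 normalizes -0.0


def skewness(sample: IntensitySample | np.ndarray) -> float:
    """Population moment skewness ``m3 / m2**1.5``.

    Returns NaN (undefined) for samples with fewer than three values or zero
    variance; downstream code treats NaN as a missing feature.
    """
    values = sample.values if isinstance(sample, IntensitySample) else np.asarray(sample, float)
    if values.size < 3 or np.ptp(values) == 0:  # ptp: exact constant check
        return float("nan")
    return float(stats.skew(values, bias=True))


def mean_intensity(sample: IntensitySample | np.ndarray) -> float:
    """Arithmetic mean of the sampled intensities."""
    values = sample.values if isinstance(sample, IntensitySample) else np.asarray(sample, float)
    if values.size == 0:
        raise ValueError("empty sample")
    return float(values.mean())


def ihc_features(image: MarkerImage, bin_width: float = IHC_BIN_WIDTH,
                 reference: float = RESCALE_REFERENCE) -> dict[str, float]:
    """Mean / entropy / skewness of one marker image's positive area.

    All three are NaN when the positive area is empty.
    """
    try:
        sample = rescale_by_threshold(image, reference=reference)
    except ValueError:
        nan = float("nan")
        return {"mean": nan, "entropy": nan, "skewness": nan}
    return {
        "mean": mean_intensity(sample),
        "entropy": entropy(discretize(sample, bin_width)),
        "skewness": skewness(sample),
    }


def pet_features(suv: np.ndarray, voi: VOI, bin_width: float = PET_BIN_WIDTH) -> dict[str, float]:
    """Entropy and skewness of the SUV distribution inside the tumor VOI."""
    sample = IntensitySample(np.asarray(suv, float)[voi.mask], source="PET", region="tumor VOI")
    return {
        "entropy": entropy(discretize(sample, bin_width)),
        "skewness": skewness(sample),
    }


def extract_feature_block(
    ihc_images: Mapping[str, Mapping[str, MarkerImage]],
    pet_volumes: Mapping[str, tuple[np.ndarray, VOI]] | None = None,
    markers: tuple[str, ...] = AREA_MARKERS,
    ihc_bin_width: float = IHC_BIN_WIDTH,
    pet_bin_width: float = PET_BIN_WIDTH,
) -> pd.DataFrame:
    """Assemble the texture-feature columns for a set of samples.

    Parameters
    ----------
    ihc_images : mapping sample_id -> {marker_name -> MarkerImage}
        Only markers listed in ``markers`` (the area stains) contribute;
        ribbon-like stains (vessels, perfusion) yield no texture features.
    pet_volumes : mapping sample_id -> (suv grid, tumor VOI), optional

    Returns
    -------
    DataFrame indexed by sample_id with columns ``<marker>_mean``,
    ``<marker>_entropy``, ``<marker>_skewness`` per area marker and
    ``PET_entropy``, ``PET_skewness`` when PET data is supplied.  Missing
    images or undefined statistics appear as NaN.
    """
    columns: list[str] = []
    for marker in markers:
        columns += [f"{marker}_mean", f"{marker}_entropy", f"{marker}_skewness"]
    if pet_volumes is not None:
        columns += ["PET_entropy", "PET_skewness"]

    sample_ids = sorted(set(ihc_images) | set(pet_volumes or {}))
    rows = []
    for sid in sample_ids:
        row: dict[str, float] = {}
        per_marker = ihc_images.get(sid, {})
        for marker in markers:
            if marker in per_marker:
                feats = ihc_features(per_marker[marker], bin_width=ihc_bin_width)
            else:
                feats = {"mean": np.nan, "entropy": np.nan, "skewness": np.nan}
            for key, value in feats.items():
                row[f"{marker}_{key}"] = value
        if pet_volumes is not None:
            if sid in pet_volumes:
                suv, voi = pet_volumes[sid]
                feats = pet_features(suv, voi, bin_width=pet_bin_width)
            else:
                feats = {"entropy": np.nan, "skewness": np.nan}
            row["PET_entropy"] = feats["entropy"]
            row["PET_skewness"] = feats["skewness"]
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"),
                        columns=columns)
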