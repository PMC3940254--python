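"""Synthetic cohorts, marker-image phantoms and uptake-volume phantoms.

Every generator returns the realized ground truth alongside the data: the
true staining fraction is the rasterized pixel count, the true heterogeneity
ratio is the one implied by the requested variance components, and so on.
This makes exact oracle tests possible for the whole downstream pipeline,
which matters because the original animal dataset is not available.

Cohort values are drawn from a Gaussian random-intercept hierarchy on a
latent scale and then optionally transformed (logistic for fractions,
exponential for positive-valued parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .ihc import (
    DEFAULT_DYNAMIC_RANGE,
    DEFAULT_PIXEL_SIZE_UM,
    BinaryMask,
    MarkerImage,
    NucleusSet,
)
from .pet import DEFAULT_VOXEL_SIZE_MM, UptakeVolume

__all__ = [
    "ParameterSpec",
    "CohortSpec",
    "CohortTruth",
    "ImagePhantomSpec",
    "ImageGroundTruth",
    "VolumePhantomSpec",
    "VolumeGroundTruth",
    "generate_cohort",
    "generate_marker_image",
    "generate_uptake_volume",
    "paper_like_parameter_specs",
    "paper_like_cohort_spec",
]

TRANSFORMS = ("identity", "logistic", "exp")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSpec:
    """Generative description of one parameter column.

    ``var_between`` is the variance of the per-line random intercepts and
    ``var_within`` the residual variance, both on the latent (pre-transform)
    scale.  The implied heterogeneity ratio is
    ``var_within / (var_within + var_between)``.
    """

    name: str
    grand_mean: float = 0.0
    var_between: float = 0.5
    var_within: float = 0.5
    transform: str = "identity"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("parameter name must be non-empty")
        if self.var_between < 0 or self.var_within < 0:
            raise ValueError("variances must be non-negative")
        if self.var_between + self.var_within <= 0:
            raise ValueError("total variance must be positive")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}; "
                             f"expected one of {TRANSFORMS}")

    @property
    def true_ratio(self) -> float:
        """Within-line variance over total variance, on the latent scale."""
        return self.var_within / (self.var_within + self.var_between)


@dataclass(frozen=True)
class CohortSpec:
    """Description of a synthetic multi-line cohort."""

    n_lines: int = 14
    n_per_line: int = 5
    parameter_specs: tuple[ParameterSpec, ...] = ()
    missingness: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.n_per_line < 2:
            raise ValueError("n_per_line must be >= 2")
        if not self.parameter_specs:
            raise ValueError("at least one parameter spec is required")
        names = [p.name for p in self.parameter_specs]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        n_samples = self.n_lines * self.n_per_line
        for name, n_missing in self.missingness:
            if n_missing < 0 or n_missing > n_samples:
                raise ValueError(f"invalid missing count for {name!r}")

    @property
    def n_samples(self) -> int:
        return self.n_lines * self.n_per_line


@dataclass
class CohortTruth:
    """Ground truth for a generated cohort."""

    ratios: dict[str, float]
    line_effects: dict[str, np.ndarray]
    missing_rows: dict[str, np.ndarray]


def _apply_transform(latent: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return latent
    if transform == "logistic":
        return 1.0 / (1.0 + np.exp(-latent))
    if transform == "exp":
        return np.exp(latent)
    raise ValueError(f"unknown transform {transform!r}")


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw a feature table from the hierarchical Gaussian model.

    For each parameter, line effects are N(0, var_between), residuals
    N(0, var_within); the sum plus the grand mean is pushed through the
    parameter's transform.  Missing cells (chosen completely at random,
    shared across all columns matching one missingness entry by name or
    ``name_`` prefix) are set to NaN.

    Returns
    -------
    (table, truth)
        ``table`` has columns ``sample_id``, ``line`` then one column per
        parameter; ``truth`` records the true per-parameter heterogeneity
        ratio, the latent line effects and the blanked row indices.
    """
    rng = np.random.default_rng(spec.seed)
    lines = [f"L{i + 1:02d}" for i in range(spec.n_lines)]
    line_col = np.repeat(lines, spec.n_per_line)
    sample_ids = [f"{line}_T{j + 1}" for line in lines
                  for j in range(spec.n_per_line)]
    line_index = np.repeat(np.arange(spec.n_lines), spec.n_per_line)

    data: dict[str, np.ndarray] = {}
    ratios: dict[str, float] = {}
    effects: dict[str, np.ndarray] = {}
    for pspec in spec.parameter_specs:
        b = rng.normal(0.0, np.sqrt(pspec.var_between), size=spec.n_lines)
        e = rng.normal(0.0, np.sqrt(pspec.var_within), size=spec.n_samples)
        latent = pspec.grand_mean + b[line_index] + e
        data[pspec.name] = _apply_transform(latent, pspec.transform)
        ratios[pspec.name] = pspec.true_ratio
        effects[pspec.name] = b

    table = pd.DataFrame({"sample_id": sample_ids, "line": line_col, **data})

    missing_rows: dict[str, np.ndarray] = {}
    param_names = [p.name for p in spec.parameter_specs]
    for name, n_missing in spec.missingness:
        targets = [c for c in param_names
                   if c == name or c.startswith(name + "_")]
        if not targets:
            raise ValueError(f"missingness entry {name!r} matches no parameter")
        rows = rng.choice(spec.n_samples, size=n_missing, replace=False)
        for col in targets:
            table.loc[rows, col] = np.nan
        missing_rows[name] = np.sort(rows)

    return table, CohortTruth(ratios=ratios, line_effects=effects,
                              missing_rows=missing_rows)


# -- defaults emulating the study's cohort ----------------------------------

#: published within/total heterogeneity ratios used to scale the default
#: synthetic cohort (parameter name, latent grand mean, total latent
#: variance, heterogeneity ratio, transform)
_DEFAULT_PARAMS: tuple[tuple[str, float, float, float, str], ...] = (
    ("PIMO", -1.7, 1.0, 0.77, "logistic"),
    ("BrdU", -2.2, 1.0, 0.78, "logistic"),
    ("pAKT", -1.4, 1.0, 0.34, "logistic"),
    ("EGFR", -0.85, 1.0, 0.29, "logistic"),
    ("MCT4", -1.1, 1.0, 0.12, "logistic"),
    ("CA9", -1.4, 1.0, 0.08, "logistic"),
    ("GLUT1", -0.85, 1.0, 0.47, "logistic"),
    ("VD", 3.9, 0.25, 0.40, "exp"),
    ("PF", 0.85, 0.8, 0.55, "logistic"),
    ("PET_SUVmax", 0.18, 0.09, 0.41, "exp"),
    ("PET_SUVmean", -0.1, 0.09, 0.33, "exp"),
    ("PET_TM", 0.7, 0.16, 0.70, "exp"),
    ("PET_entropy", 2.5, 0.25, 0.39, "identity"),
    ("PET_skewness", 0.4, 0.2, 0.58, "identity"),
    ("PIMO_mean", 1500.0, 9e4, 0.77, "identity"),
    ("PIMO_entropy", 3.0, 0.2, 0.80, "identity"),
    ("PIMO_skewness", 0.5, 0.25, 0.82, "identity"),
    ("BrdU_mean", 1400.0, 9e4, 0.52, "identity"),
    ("BrdU_entropy", 3.1, 0.2, 0.58, "identity"),
    ("BrdU_skewness", 0.6, 0.25, 0.63, "identity"),
    ("pAKT_mean", 1300.0, 9e4, 0.31, "identity"),
    ("pAKT_entropy", 2.9, 0.2, 0.36, "identity"),
    ("pAKT_skewness", 0.4, 0.25, 0.47, "identity"),
    ("EGFR_mean", 1600.0, 9e4, 0.15, "identity"),
    ("EGFR_entropy", 3.2, 0.2, 0.16, "identity"),
    ("EGFR_skewness", 0.3, 0.25, 0.67, "identity"),
    ("MCT4_mean", 1350.0, 9e4, 0.23, "identity"),
    ("MCT4_entropy", 3.0, 0.2, 0.20, "identity"),
    ("MCT4_skewness", 0.5, 0.25, 0.48, "identity"),
    ("CA9_mean", 1550.0, 9e4, 0.24, "identity"),
    ("CA9_entropy", 3.1, 0.2, 0.28, "identity"),
    ("CA9_skewness", 0.45, 0.25, 0.71, "identity"),
    ("GLUT1_mean", 1450.0, 9e4, 0.92, "identity"),
    ("GLUT1_entropy", 3.0, 0.2, 0.83, "identity"),
    ("GLUT1_skewness", 0.55, 0.25, 0.92, "identity"),
)

#: observed missing-sample counts: PET for 4 tumors, MCT4 for 5, BrdU for 3
DEFAULT_MISSINGNESS: tuple[tuple[str, int], ...] = (
    ("PET", 4), ("MCT4", 5), ("BrdU", 3),
)


def paper_like_parameter_specs() -> tuple[ParameterSpec, ...]:
    """Parameter specs emulating the study: 9 IHC + 3 PET parameters and
    21 IHC + 2 PET texture features, with published heterogeneity ratios."""
    specs = []
    for name, mean, total_var, ratio, transform in _DEFAULT_PARAMS:
        specs.append(ParameterSpec(name=name, grand_mean=mean,
                                   var_between=(1.0 - ratio) * total_var,
                                   var_within=ratio * total_var,
                                   transform=transform))
    return tuple(specs)


def paper_like_cohort_spec(seed: int = 0, n_lines: int = 14, n_per_line: int = 5,
                           with_missingness: bool = True) -> CohortSpec:
    """Cohort spec shaped like the study (14 lines, ~5 tumors per line)."""
    params = paper_like_parameter_specs()
    n_samples = n_lines * n_per_line
    missing: tuple[tuple[str, int], ...] = ()
    if with_missingness:
        missing = tuple((name, min(n, n_samples)) for name, n in DEFAULT_MISSINGNESS)
    return CohortSpec(n_lines=n_lines, n_per_line=n_per_line,
                      parameter_specs=params, missingness=missing, seed=seed)


# ---------------------------------------------------------------------------
# marker-image phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagePhantomSpec:
    """Layout of one synthetic marker image.

    The phantom holds blob-shaped positive staining at an exact pixel
    fraction of the viable area, thin ribbon-like vessels (a subset flagged
    perfused), non-overlapping nuclei with an exact positive count, and an
    optional disk of necrosis.
    """

    width: int = 256
    height: int = 256
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    dynamic_range: float = DEFAULT_DYNAMIC_RANGE
    stain_fraction_target: float = 0.3
    n_vessels: int = 0
    perfused_fraction_target: float = 0.7
    n_nuclei: int = 0
    labeling_index_target: float = 0.2
    necrosis_fraction: float = 0.0
    background_level: float = 200.0
    signal_level: float = 1200.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("phantom must be at least 32x32 pixels")
        for name in ("stain_fraction_target", "perfused_fraction_target",
                     "labeling_index_target", "necrosis_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.signal_level <= self.background_level:
            raise ValueError("signal_level must exceed background_level")
        if self.signal_level > self.dynamic_range:
            raise ValueError("signal_level exceeds the dynamic range")
        if self.n_vessels < 0 or self.n_nuclei < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.necrosis_fraction > 0.5:
            raise ValueError("necrosis_fraction above 0.5 is not supported")


@dataclass
class ImageGroundTruth:
    """Exact, rasterized ground truth of one marker-image phantom."""

    stain_mask: np.ndarray
    stain_fraction: float
    viable_mask: np.ndarray
    necrosis_mask: np.ndarray
    necrosis_fraction: float
    vessel_mask: np.ndarray
    perfusion_mask: np.ndarray
    n_vessels: int
    n_perfused: int
    perfused_flags: np.ndarray
    nuclei: NucleusSet = field(default=None)  # type: ignore[assignment]

    @property
    def labeling_index(self) -> float:
        if self.nuclei is None or len(self.nuclei) == 0:
            return float("nan")
        return float(self.nuclei.positive_flags.sum()) / len(self.nuclei)

    @property
    def perfused_fraction(self) -> float:
        return self.n_perfused / self.n_vessels if self.n_vessels else float("nan")


def _necrosis_disk(shape: tuple[int, int], fraction: float,
                   rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if fraction <= 0:
        return mask
    h, w = shape
    radius = np.sqrt(fraction * h * w / np.pi)
    if 2 * radius + 4 > min(h, w):
        raise ValueError("necrosis_fraction infeasible for this image size")
    cy = rng.uniform(radius + 1, h - radius - 1)
    cx = rng.uniform(radius + 1, w - radius - 1)
    yy, xx = np.ogrid[:h, :w]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return mask


def _rasterize_stain(viable: np.ndarray, target_count: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Union of random disks clipped to the viable area, trimmed to hit the
    target pixel count exactly."""
    stain = np.zeros(viable.shape, dtype=bool)
    if target_count == 0:
        return stain
    h, w = viable.shape
    viable_rows, viable_cols = np.nonzero(viable)
    yy, xx = np.ogrid[:h, :w]
    for _ in range(5000):
        if stain.sum() >= target_count:
            break
        pick = rng.integers(len(viable_rows))
        cy, cx = viable_rows[pick], viable_cols[pick]
        radius = rng.uniform(3.0, 10.0)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        stain |= disk & viable
    else:  # dense targets: fill the remainder pixel-wise
        deficit = target_count - int(stain.sum())
        free = np.flatnonzero(viable & ~stain)
        fill = rng.choice(free, size=deficit, replace=False)
        stain.ravel()[fill] = True
    excess = int(stain.sum()) - target_count
    if excess > 0:
        on = np.flatnonzero(stain)
        off = rng.choice(on, size=excess, replace=False)
        stain.ravel()[off] = False
    return stain


def _trace_vessel(viable: np.ndarray, rng: np.random.Generator) -> np.ndarray | None:
    """One thin ribbon: a jittered random walk dilated to ~3 px width."""
    h, w = viable.shape
    margin = 6
    r = rng.uniform(margin, h - margin)
    c = rng.uniform(margin, w - margin)
    angle = rng.uniform(0, 2 * np.pi)
    n_steps = int(rng.integers(25, 60))
    path = np.zeros(viable.shape, dtype=bool)
    for _ in range(n_steps):
        rr, cc = int(round(r)), int(round(c))
        if not (margin <= rr < h - margin and margin <= cc < w - margin):
            break
        path[rr, cc] = True
        angle += rng.normal(0.0, 0.25)
        r += np.sin(angle)
        c += np.cos(angle)
    if path.sum() < 8:
        return None
    ribbon = ndimage.binary_dilation(path, structure=np.ones((3, 3), bool))
    if np.any(ribbon & ~viable):
        return None
    return ribbon


def _place_vessels(viable: np.ndarray, n_vessels: int, n_perfused: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place mutually non-adjacent ribbons; the first ``n_perfused`` of the
    (shuffled) placement order are flagged perfused and dilated into the
    perfusion mask."""
    vessel = np.zeros(viable.shape, dtype=bool)
    perfusion = np.zeros(viable.shape, dtype=bool)
    flags = np.zeros(n_vessels, dtype=bool)
    flags[:n_perfused] = True
    rng.shuffle(flags)
    # keep-out zone: existing vessels dilated so ribbons stay 8-disconnected
    # and perfusion halos (radius 2) cannot touch a neighbouring vessel
    keepout = np.zeros(viable.shape, dtype=bool)
    halo = np.ones((9, 9), dtype=bool)
    for i in range(n_vessels):
        for _ in range(400):
            ribbon = _trace_vessel(viable, rng)
            if ribbon is None or np.any(ribbon & keepout):
                continue
            vessel |= ribbon
            if flags[i]:
                perfusion |= ndimage.binary_dilation(ribbon, np.ones((5, 5), bool))
            keepout |= ndimage.binary_dilation(ribbon, halo)
            break
        else:
            raise ValueError("could not place all vessels; reduce n_vessels "
                             "or enlarge the image")
    return vessel, perfusion, flags


def _place_nuclei(viable: np.ndarray, n_nuclei: int, n_positive: int,
                  rng: np.random.Generator) -> NucleusSet:
    h, w = viable.shape
    min_sep = 3  # Chebyshev spacing between nucleus centres
    capacity = int(viable.sum() / ((2 * min_sep) ** 2))
    if n_nuclei > capacity:
        raise ValueError(f"n_nuclei={n_nuclei} exceeds phantom capacity "
                         f"(~{capacity} at spacing {min_sep})")
    blocked = np.zeros((h, w), dtype=bool)
    rows_v, cols_v = np.nonzero(viable)
    coords = []
    attempts = 0
    while len(coords) < n_nuclei:
        attempts += 1
        if attempts > 200 * n_nuclei + 1000:
            raise ValueError("could not place all nuclei without overlap")
        pick = rng.integers(len(rows_v))
        r, c = int(rows_v[pick]), int(cols_v[pick])
        if blocked[r, c]:
            continue
        coords.append((r, c))
        r0, r1 = max(0, r - min_sep), min(h, r + min_sep + 1)
        c0, c1 = max(0, c - min_sep), min(w, c + min_sep + 1)
        blocked[r0:r1, c0:c1] = True
    flags = np.zeros(n_nuclei, dtype=bool)
    flags[:n_positive] = True
    rng.shuffle(flags)
    return NucleusSet(np.array(coords, dtype=float), flags)


def generate_marker_image(spec: ImagePhantomSpec) -> tuple[MarkerImage, ImageGroundTruth]:
    """Rasterize one synthetic marker image with exact ground truth.

    The positive-stain pixel count equals ``round(target * viable_area)``
    exactly; the segmentation threshold is set midway between background and
    signal level, so on a noiseless phantom thresholding recovers the stain
    mask bit-for-bit.  Perfused-vessel and positive-nucleus counts realize
    their targets exactly (rounded to whole structures).
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)

    necrosis = _necrosis_disk(shape, spec.necrosis_fraction, rng)
    viable = ~necrosis
    viable_count = int(viable.sum())

    target_count = int(round(spec.stain_fraction_target * viable_count))
    stain = _rasterize_stain(viable, target_count, rng)

    n_perfused = int(round(spec.perfused_fraction_target * spec.n_vessels))
    if spec.n_vessels > 0:
        vessel, perfusion, flags = _place_vessels(viable, spec.n_vessels,
                                                  n_perfused, rng)
    else:
        vessel = np.zeros(shape, dtype=bool)
        perfusion = np.zeros(shape, dtype=bool)
        flags = np.zeros(0, dtype=bool)

    nuclei = None
    if spec.n_nuclei > 0:
        n_positive = int(round(spec.labeling_index_target * spec.n_nuclei))
        nuclei = _place_nuclei(viable, spec.n_nuclei, n_positive, rng)

    pixels = np.full(shape, spec.background_level, dtype=float)
    pixels[stain] = spec.signal_level
    if spec.noise_sd > 0:
        pixels += rng.normal(0.0, spec.noise_sd, size=shape)
        pixels = np.clip(pixels, 0.0, spec.dynamic_range)

    image = MarkerImage(
        pixels=pixels,
        pixel_size=spec.pixel_size,
        threshold=(spec.background_level + spec.signal_level) / 2.0,
        viable_mask=np.ones(shape, dtype=bool),
        necrosis_mask=necrosis,
        dynamic_range=spec.dynamic_range,
    )
    truth = ImageGroundTruth(
        stain_mask=stain,
        stain_fraction=int(stain.sum()) / viable_count,
        viable_mask=viable,
        necrosis_mask=necrosis,
        necrosis_fraction=int(necrosis.sum()) / necrosis.size,
        vessel_mask=vessel,
        perfusion_mask=perfusion,
        n_vessels=spec.n_vessels,
        n_perfused=n_perfused,
        perfused_flags=flags,
        nuclei=nuclei,
    )
    return image, truth


def vessel_masks(truth: ImageGroundTruth,
                 pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> tuple[BinaryMask, BinaryMask]:
    """Package a phantom's vessel and perfusion masks as BinaryMasks."""
    return (BinaryMask(truth.vessel_mask, pixel_size=pixel_size),
            BinaryMask(truth.perfusion_mask, pixel_size=pixel_size))


# ---------------------------------------------------------------------------
# uptake-volume phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumePhantomSpec:
    """An ellipsoidal hot region on a uniform background."""

    dims: tuple[int, int, int] = (48, 48, 24)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM
    semi_axes: tuple[float, float, float] = (8.0, 8.0, 5.0)
    plateau_suv: float = 2.0
    background_suv: float = 0.1
    injected_activity: float = 10.0
    body_weight: float = 20.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 8 for d in self.dims):
            raise ValueError("volume must be at least 8 voxels per axis")
        if not self.plateau_suv > self.background_suv > 0:
            raise ValueError("require plateau_suv > background_suv > 0")
        if self.injected_activity <= 0:
            raise ValueError("injected_activity must be positive")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if any(2 * a >= d for a, d in zip(self.semi_axes, self.dims)):
            raise ValueError("hot region does not fit inside the volume")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class VolumeGroundTruth:
    """Noise-free ground truth of one uptake-volume phantom."""

    voi_mask: np.ndarray
    suv_max: float
    suv_mean: float
    suv_grid: np.ndarray


def generate_uptake_volume(spec: VolumePhantomSpec) -> tuple[UptakeVolume, VolumeGroundTruth]:
    """Build an uptake volume whose noise-free SUV equals the spec exactly.

    The stored voxel values are activity concentrations (MBq/mL) chosen so
    that ``C / (injected_activity / body_weight)`` reproduces the requested
    SUV field; Gaussian noise (in SUV units) is added on top when requested.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.dims
    center = ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0)
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    az, ay, ax = spec.semi_axes
    hot = (((zz - center[0]) / az) ** 2 + ((yy - center[1]) / ay) ** 2
           + ((xx - center[2]) / ax) ** 2) <= 1.0

    suv = np.full(spec.dims, spec.background_suv, dtype=float)
    suv[hot] = spec.plateau_suv
    truth = VolumeGroundTruth(voi_mask=hot, suv_max=spec.plateau_suv,
                              suv_mean=spec.plateau_suv, suv_grid=suv.copy())

    noisy = suv
    if spec.noise_sd > 0:
        noisy = np.clip(suv + rng.normal(0.0, spec.noise_sd, size=spec.dims), 0.0, None)
    concentration = noisy * (spec.injected_activity / spec.body_weight)
    volume = UptakeVolume(voxels=concentration, voxel_size=spec.voxel_size,
                          injected_activity=spec.injected_activity,
                          body_weight=spec.body_weight)
    return volume, truth
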