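"""Robust-threshold amyloid-plaque detection in fluorescence micrographs.

The detector binarizes each region-of-interest image at a robust intensity
threshold M + k * D, where M is the median pixel intensity and D the average
absolute deviation of the pixel intensities (about the median by default),
with k = 2.8.  The binary mask is cleaned with a median filter, connected
components are extracted, components inside a pre-determined size gate are
counted as plaques, and plaque density is the count divided by the ROI area.

The whole chain is invariant under positive affine rescaling of the image
intensities (a*I + b, a > 0): median and AAD are equivariant, so the mask,
particle set and density are unchanged.  Counts are non-increasing in k and
non-decreasing as the size gate widens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .exceptions import AnalysisError, ParameterError

GENOTYPE_CONTROL = "ChR2-"
GENOTYPE_TREATED = "ChR2+"


@dataclass
class MicrographROI:
    """Single-channel intensity image for one brain region of one animal."""

    image: np.ndarray
    region: str = ""
    animal_id: str = ""
    genotype: str = ""
    roi_area_px: float | None = None  # defaults to the full image area
    mm2_per_px: float | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2 or self.image.size == 0:
            raise ParameterError("image must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.image)) or self.image.min() < 0:
            raise ParameterError("image intensities must be finite and >= 0")
        if self.roi_area_px is None:
            self.roi_area_px = float(self.image.size)
        if self.roi_area_px <= 0:
            raise ParameterError("roi_area_px must be positive")


@dataclass(frozen=True)
class DetectionParams:
    """Tunable detector parameters.

    ``min_area_px``/``max_area_px`` (the "pre-determined range of sizes") have
    defaults matched to the synthetic image scale; any real dataset must set
    its own gate.  ``aad_center`` selects the centering of the deviation D
    (median, the default pairing with M; or mean).  ``median_even`` selects the
    even-count median convention (lower of the two middle values by default,
    integer-friendly; or the usual midpoint interpolation).
    ``filter_before_threshold`` applies the median filter to the grayscale
    image before thresholding instead of to the binary mask after.
    """

    k_threshold: float = 2.8
    median_filter_size_px: int = 3
    min_area_px: float = 10.0
    max_area_px: float = 2500.0
    connectivity: int = 8
    aad_center: str = "median"  # "median" | "mean"
    median_even: str = "lower"  # "lower" | "midpoint"
    filter_before_threshold: bool = False

    def __post_init__(self) -> None:
        if self.k_threshold <= 0:
            raise ParameterError("k_threshold must be positive")
        if self.median_filter_size_px < 1 or self.median_filter_size_px % 2 == 0:
            raise ParameterError("median_filter_size_px must be odd and >= 1")
        if not 0 < self.min_area_px < self.max_area_px:
            raise ParameterError("require 0 < min_area_px < max_area_px")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if self.aad_center not in ("median", "mean"):
            raise ParameterError("aad_center must be 'median' or 'mean'")
        if self.median_even not in ("lower", "midpoint"):
            raise ParameterError("median_even must be 'lower' or 'midpoint'")


@dataclass
class Particle:
    centroid_rc: tuple[float, float]
    area_px: float


@dataclass
class PlaqueDetectionResult:
    threshold_value: float
    particles: list[Particle]
    n_plaques: int
    density: float  # plaques per unit ROI area (px^-2, or mm^-2 if scaled)
    density_units: str = "per_px2"


def _median(values: np.ndarray, convention: str) -> float:
    v = np.sort(values, axis=None)
    n = len(v)
    if convention == "lower" and n % 2 == 0:
        return float(v[(n - 1) // 2])
    return float(np.median(v))


def robust_threshold(
    image: np.ndarray,
    k: float = 2.8,
    aad_center: str = "median",
    median_even: str = "lower",
) -> float:
    """Threshold = M + k * D over the ROI pixels.

    M is the median intensity (lower-of-two-middle for even counts by
    default) and D the mean absolute deviation about ``aad_center``
    ("median" or "mean").  A constant image has D = 0 and threshold equal
    to the constant; the threshold is exactly equivariant under positive
    affine intensity maps.
    """
    values = np.asarray(image, dtype=float).ravel()
    if values.size == 0:
        raise ParameterError("cannot threshold an empty image")
    if k <= 0:
        raise ParameterError("k must be positive")
    m = _median(values, median_even)
    center = m if aad_center == "median" else float(values.mean())
    d = float(np.abs(values - center).mean())
    return m + k * d


def binarize(image: np.ndarray, threshold: float) -> np.ndarray:
    """Strictly-above-threshold foreground mask (constant image -> empty mask)."""
    return np.asarray(image, dtype=float) > threshold


def clean_mask(mask: np.ndarray, median_filter_size_px: int = 3) -> np.ndarray:
    """Binary median filter (majority vote in the window); size 1 is identity.

    Windows at the image border use edge replication.
    """
    if median_filter_size_px < 1 or median_filter_size_px % 2 == 0:
        raise ParameterError("median filter size must be odd and >= 1")
    mask = np.asarray(mask, dtype=bool)
    if median_filter_size_px == 1:
        return mask.copy()
    filtered = ndimage.median_filter(
        mask.astype(np.uint8), size=median_filter_size_px, mode="nearest"
    )
    return filtered.astype(bool)


def find_particles(
    mask: np.ndarray,
    connectivity: int = 8,
    min_area_px: float = 10.0,
    max_area_px: float = 2500.0,
) -> list[Particle]:
    """Connected components of the mask with area inside [min, max], inclusive."""
    if not 0 < min_area_px < max_area_px:
        raise ParameterError("require 0 < min_area_px < max_area_px")
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    labels = measure.label(
        np.asarray(mask, dtype=bool), connectivity=1 if connectivity == 4 else 2
    )
    particles = []
    for region in measure.regionprops(labels):
        if min_area_px <= region.area <= max_area_px:
            particles.append(
                Particle(centroid_rc=tuple(region.centroid), area_px=float(region.area))
            )
    return particles


def detect_plaques(
    roi: MicrographROI, params: DetectionParams = DetectionParams()
) -> PlaqueDetectionResult:
    """Full detection chain on one ROI.

    robust_threshold -> binarize -> clean_mask -> find_particles ->
    density = n / roi_area.  With ``filter_before_threshold`` the grayscale
    image is median-filtered first and the threshold computed on the filtered
    image (alternative reading of the processing order).
    """
    image = roi.image
    if params.filter_before_threshold and params.median_filter_size_px > 1:
        image = ndimage.median_filter(
            image, size=params.median_filter_size_px, mode="nearest"
        )
    threshold = robust_threshold(
        image,
        k=params.k_threshold,
        aad_center=params.aad_center,
        median_even=params.median_even,
    )
    mask = binarize(image, threshold)
    if not params.filter_before_threshold:
        mask = clean_mask(mask, params.median_filter_size_px)
    particles = find_particles(
        mask, params.connectivity, params.min_area_px, params.max_area_px
    )
    if roi.mm2_per_px is not None:
        density = len(particles) / (roi.roi_area_px * roi.mm2_per_px)
        units = "per_mm2"
    else:
        density = len(particles) / roi.roi_area_px
        units = "per_px2"
    return PlaqueDetectionResult(
        threshold_value=threshold,
        particles=particles,
        n_plaques=len(particles),
        density=density,
        density_units=units,
    )


def normalize_densities(
    table: pd.DataFrame,
    value_col: str = "density",
    region_col: str = "region",
    genotype_col: str = "genotype",
    control_label: str = GENOTYPE_CONTROL,
) -> pd.DataFrame:
    """Normalize densities by the per-region mean density of the control group.

    Returns a copy of the table with a ``normalized`` column; the per-region
    mean of normalized control values is exactly 1.
    """
    out = table.copy()
    out["normalized"] = np.nan
    for region, sub in table.groupby(region_col):
        ctrl = sub.loc[sub[genotype_col] == control_label, value_col]
        if len(ctrl) == 0:
            raise AnalysisError(f"region {region!r} has no {control_label} observations")
        mean = float(ctrl.mean())
        if mean <= 0:
            raise AnalysisError(
                f"region {region!r}: control mean density is not positive ({mean})"
            )
        out.loc[sub.index, "normalized"] = sub[value_col] / mean
    return out
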