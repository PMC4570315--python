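"""Well detection and 24-channel colour-difference feature extraction.

The sensor chip carries eight dye-bead wells imaged before and five
minutes after sample loading.  Features are the after-minus-before mean
RGB per well, flattened dye-major: ``(dye1 R, dye1 G, dye1 B, ...,
dye8 R, dye8 G, dye8 B)`` — 24 values per sample.  Wells are located by
background-colour thresholding, connected components, and a circularity
filter, then ordered top-to-bottom, left-to-right.

Also here: band-averaged absorbance over the red (620-780 nm), green
(500-580 nm), and blue (450-500 nm) wavelength windows, and the
coefficient of determination of band absorbance against analyte
concentration used to characterise individual dyes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure

from .synthetic import DYE_NAMES

__all__ = [
    "Well",
    "ColorFeatureVector",
    "WellDetectionError",
    "BANDS",
    "detect_wells",
    "extract_features",
    "band_average",
    "concentration_response_r2",
    "feature_columns",
]

#: Wavelength windows (inclusive, nm) mapped to the camera's RGB channels.
BANDS: dict[str, tuple[float, float]] = {
    "red": (620.0, 780.0),
    "green": (500.0, 580.0),
    "blue": (450.0, 500.0),
}


class WellDetectionError(RuntimeError):
    """Raised when the detector cannot resolve the expected well count."""


@dataclass(frozen=True)
class Well:
    center: tuple[float, float]  # (row, col)
    radius: float


@dataclass
class ColorFeatureVector:
    """One sample's 24 after-minus-before RGB values, dye-major order."""

    sample_id: str
    values: np.ndarray
    dye_order: tuple[str, ...] = DYE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != 3 * len(self.dye_order):
            raise ValueError(
                f"expected {3 * len(self.dye_order)} values, got {self.values.size}"
            )


def feature_columns(dye_order: tuple[str, ...] = DYE_NAMES) -> list[str]:
    """CSV column names: alizarin_R, alizarin_G, alizarin_B, ..."""
    return [f"{dye}_{ch}" for dye in dye_order for ch in "RGB"]


# ---------------------------------------------------------------------------
# well detection
# ---------------------------------------------------------------------------

def _background_color(image: np.ndarray) -> np.ndarray:
    border = np.concatenate(
        [image[0], image[-1], image[:, 0], image[:, -1]], axis=0
    )
    return np.median(border, axis=0)


def detect_wells(
    image: np.ndarray,
    n_wells: int = 8,
    color_tol: float = 30.0,
    min_area: int = 40,
    min_circularity: float = 0.55,
) -> list[Well]:
    """Locate ``n_wells`` circular wells, canonical row-major order.

    Pixels further than ``color_tol`` (Euclidean RGB distance) from the
    border-estimated background are grouped into connected components;
    components that are too small or insufficiently circular
    (4*pi*A/P^2 below ``min_circularity``) are discarded.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    bg = _background_color(image)
    dist = np.linalg.norm(image - bg, axis=2)
    mask = dist > color_tol
    labels = measure.label(mask, connectivity=2)
    candidates = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        perimeter = region.perimeter
        if perimeter == 0:
            continue
        circularity = 4 * np.pi * region.area / perimeter**2
        if circularity < min_circularity:
            continue
        radius = float(np.sqrt(region.area / np.pi))
        candidates.append(Well(center=tuple(region.centroid), radius=radius))
    if len(candidates) != n_wells:
        raise WellDetectionError(
            f"expected {n_wells} wells, found {len(candidates)} candidate regions"
        )
    # group into rows: sort by y, break rows where the vertical gap
    # exceeds the mean radius, then sort left-to-right within each row
    mean_r = float(np.mean([w.radius for w in candidates]))
    by_y = sorted(candidates, key=lambda w: w.center[0])
    rows: list[list[Well]] = [[by_y[0]]]
    for w in by_y[1:]:
        if w.center[0] - rows[-1][-1].center[0] > mean_r:
            rows.append([w])
        else:
            rows[-1].append(w)
    ordered: list[Well] = []
    for row in rows:
        ordered.extend(sorted(row, key=lambda w: w.center[1]))
    return ordered


def extract_features(
    before: np.ndarray,
    after: np.ndarray,
    wells: list[Well],
    sample_id: str = "",
    dye_order: tuple[str, ...] = DYE_NAMES,
    inner_fraction: float = 0.8,
) -> ColorFeatureVector:
    """After-minus-before mean RGB per well, flattened dye-major.

    Only pixels within ``inner_fraction`` of each well's radius are
    averaged, keeping edge/anti-aliasing artefacts out of the mean.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after images must share dimensions")
    h, w = before.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    values = np.empty((len(wells), 3))
    for i, well in enumerate(wells):
        cy, cx = well.center
        r = well.radius * inner_fraction
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if not mask.any():
            raise ValueError(f"well {i} region contains no pixels")
        values[i] = after[mask].mean(axis=0) - before[mask].mean(axis=0)
    return ColorFeatureVector(sample_id=sample_id, values=values.ravel(), dye_order=dye_order)


# ---------------------------------------------------------------------------
# spectral band analysis
# ---------------------------------------------------------------------------

def band_average(
    wavelengths: np.ndarray, absorbance: np.ndarray, band: tuple[float, float]
) -> float:
    """Arithmetic mean absorbance over an inclusive wavelength window."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    absorbance = np.asarray(absorbance, dtype=float)
    lo, hi = band
    if lo > hi:
        raise ValueError("band lower bound exceeds upper bound")
    if lo < wavelengths.min() or hi > wavelengths.max():
        raise ValueError(
            f"band ({lo}, {hi}) outside spectrum support "
            f"({wavelengths.min()}, {wavelengths.max()})"
        )
    sel = (wavelengths >= lo) & (wavelengths <= hi)
    return float(absorbance[sel].mean())


def concentration_response_r2(concs, band_absorbances) -> float:
    """R² of a simple linear fit of band absorbance on concentration."""
    x = np.asarray(concs, dtype=float)
    y = np.asarray(band_absorbances, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in input; R² defined as 0", stacklevel=2)
        return 0.0
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2)
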