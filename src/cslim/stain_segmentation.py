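"""Myelin segmentation from the stained brightfield frame.

Luxol Fast Blue stains myelin blue; cell bodies counterstained with cresyl
violet and the unstained background must be excluded. Segmentation is a
color threshold in HSV space — a pixel belongs to the mask iff its hue falls
in the LFB blue window (default 170–280°) and its saturation clears a
minimum — followed by morphological cleanup (closing, then removal of small
8-connected components).

The saturation minimum can be chosen per frame from the saturation histogram
of the hue-window pixels: if that histogram is bimodal (weakly colored
background vs strongly colored stain), the threshold is placed at the valley
between the two dominant peaks; a unimodal histogram falls back to a fixed
floor of 0.15.

The stain is used only to locate myelin; quantitation happens on the phase
map after multiplication by the binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from skimage.color import rgb2hsv
from skimage.morphology import closing, disk, remove_small_objects

from .errors import ShapeError, ValidationError
from .image_io import QuantMap, RgbFrame
from .phase_reconstruction import ChannelWeights

DEFAULT_HUE_WINDOW = (170.0, 280.0)
FALLBACK_SAT_MIN = 0.15


@dataclass(frozen=True)
class MaskParams:
    hue_min_deg: float
    hue_max_deg: float
    sat_min: float
    min_area_px: int = 0
    closing_radius_px: int = 0


@dataclass(frozen=True)
class StainMask:
    """Binary myelin mask plus the threshold settings that produced it."""

    mask: np.ndarray  # (H, W) bool
    params: MaskParams

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ShapeError("mask must be 2D")
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def masked_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class StainFeatures:
    """Mask area (μm²) and mean stain intensity (0 = unstained, 1 = black)."""

    mask_area_um2: float
    mean_stain_intensity: float


def auto_sat_min(saturation: np.ndarray, n_bins: int = 64, max_valley: float = 0.25) -> float:
    """Saturation threshold at the valley of a bimodal histogram.

    The two modes being separated are weakly colored background haze (low
    saturation) and dye-saturated myelin; a valley found above ``max_valley``
    means the histogram structure is within-stain (e.g. fiber crossings),
    not a background/stain split, and the fixed floor is used instead.
    Returns :data:`FALLBACK_SAT_MIN` when fewer than two peaks are found.
    """
    sat = np.asarray(saturation).ravel()
    if sat.size < n_bins:
        return FALLBACK_SAT_MIN
    counts, edges = np.histogram(sat, bins=n_bins, range=(0.0, 1.0))
    smooth = gaussian_filter1d(counts.astype(float), sigma=1.5)
    peaks, props = find_peaks(smooth, prominence=0.02 * smooth.max())
    if len(peaks) < 2:
        return FALLBACK_SAT_MIN
    # valley between the two most prominent peaks
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    lo, hi = sorted(top2)
    valley = lo + int(np.argmin(smooth[lo : hi + 1]))
    threshold = float(0.5 * (edges[valley] + edges[valley + 1]))
    return threshold if threshold <= max_valley else FALLBACK_SAT_MIN


def myelin_mask(
    brightfield: RgbFrame,
    hue_window: tuple[float, float] = DEFAULT_HUE_WINDOW,
    sat_min: float | None = None,
) -> StainMask:
    """Threshold the brightfield frame to the LFB-blue hue/saturation region.

    ``sat_min=None`` selects the per-frame bimodal threshold (see
    :func:`auto_sat_min`).
    """
    hsv = rgb2hsv(brightfield.pixels)
    hue_deg = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    lo, hi = hue_window
    if not (0 <= lo < hi <= 360):
        raise ValidationError("hue window must satisfy 0 <= lo < hi <= 360 degrees")
    in_hue = (hue_deg >= lo) & (hue_deg <= hi)
    if sat_min is None:
        sat_min = auto_sat_min(sat[in_hue]) if in_hue.any() else FALLBACK_SAT_MIN
    mask = in_hue & (sat >= sat_min)
    return StainMask(mask, MaskParams(lo, hi, float(sat_min)))


def filter_mask(
    stain_mask: StainMask, min_area_px: int = 50, closing_radius_px: int = 1
) -> StainMask:
    """Morphological closing, then drop 8-connected components < min_area_px.

    Components with exactly ``min_area_px`` pixels are kept. Idempotent.
    """
    if min_area_px < 0 or closing_radius_px < 0:
        raise ValidationError("filter parameters must be non-negative")
    m = stain_mask.mask
    if closing_radius_px > 0:
        m = closing(m, disk(closing_radius_px))
    if min_area_px > 1:
        # components with exactly min_area_px pixels are kept
        m = remove_small_objects(m, max_size=min_area_px - 1, connectivity=2)
    params = MaskParams(
        stain_mask.params.hue_min_deg,
        stain_mask.params.hue_max_deg,
        stain_mask.params.sat_min,
        min_area_px,
        closing_radius_px,
    )
    return StainMask(m, params)


def apply_mask(qmap: QuantMap, stain_mask: StainMask) -> QuantMap:
    """Pixelwise product of a map with the binary mask (units preserved)."""
    if stain_mask.mask.shape != qmap.shape:
        raise ShapeError(f"mask shape {stain_mask.mask.shape} != map shape {qmap.shape}")
    return qmap.with_values(qmap.values * stain_mask.mask)


def stain_features(brightfield: RgbFrame, stain_mask: StainMask) -> StainFeatures:
    """Mask area and mean darkness of the stained pixels.

    Intensity is 1 − equal-weight grayscale, so darker stain scores higher;
    an empty mask yields (0, 0).
    """
    if stain_mask.mask.shape != brightfield.pixels.shape[:2]:
        raise ShapeError("mask and frame dimensions differ")
    n = int(np.count_nonzero(stain_mask.mask))
    area = n / brightfield.pixel_pitch**2
    if n == 0:
        return StainFeatures(0.0, 0.0)
    equal = ChannelWeights(1 / 3, 1 / 3, 1 / 3)
    gray = brightfield.pixels @ equal.as_array()
    intensity = float(np.mean(1.0 - gray[stain_mask.mask]))
    return StainFeatures(area, intensity)


def hyperstain_flag(stain_mask: StainMask, max_fraction: float = 0.9) -> bool:
    """QC flag: mask covers so much of the frame that hyper-staining is likely."""
    return stain_mask.masked_fraction > max_fraction
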