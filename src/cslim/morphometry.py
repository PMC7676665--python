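"""Myelin sheath diameter from the spectrum of cross-section profiles.

A line profile traced across a bundle of myelinated axons oscillates with
the characteristic center-to-center fiber spacing. The amplitude-weighted
mean spatial frequency of the mean-subtracted profile,

    f̄ = Σ f·|A(f)| / Σ |A(f)|     over 0 < f ≤ f_Nyquist,

is a robust single-number summary of that oscillation, and its reciprocal
d = 1/f̄ estimates the average external sheath diameter. The measured
f̄ = 0.36 μm⁻¹ in internal-capsule profiles corresponds to d = 2.7 μm.

The profile is Hann-windowed before the DFT by default: for tones whose
period does not divide the profile length, rectangular-window leakage
biases the amplitude-weighted mean by many DFT bins, while the Hann window
keeps single-tone recovery within a fraction of a bin. A rectangular
window and power (|A|²) weighting remain available as options.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DegenerateDataError, ShapeError, ValidationError
from .image_io import QuantMap


@dataclass(frozen=True)
class LineProfile:
    """Values sampled along a segment, with physical sample spacing in μm."""

    endpoints: tuple[tuple[float, float], tuple[float, float]]
    samples: np.ndarray
    spacing_um: float

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.size < 16:
            raise ValidationError(f"profile needs >= 16 samples, got {s.size}")
        if not np.isfinite(s).all():
            raise ValidationError("profile contains non-finite samples")
        if not self.spacing_um > 0:
            raise ValidationError("sample spacing must be positive")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class SpectrumSummary:
    mean_frequency_per_um: float
    diameter_um: float
    n_freq_bins: int

    def __post_init__(self) -> None:
        if abs(self.diameter_um - 1.0 / self.mean_frequency_per_um) > 1e-9:
            raise ValidationError("diameter must be the reciprocal of mean frequency")


def sample_profile(
    image: QuantMap | np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    pixel_pitch: float | None = None,
) -> LineProfile:
    """Bilinear samples at ≈unit-pixel steps along the segment p0 → p1.

    Coordinates are (row, col). ``pixel_pitch`` is taken from the map when a
    :class:`QuantMap` is given.
    """
    if isinstance(image, QuantMap):
        arr = image.values
        pitch = image.pixel_pitch
    else:
        arr = np.asarray(image, dtype=np.float64)
        if pixel_pitch is None:
            raise ValidationError("pixel_pitch required when sampling a bare array")
        pitch = pixel_pitch
    if arr.ndim != 2:
        raise ShapeError("profiles are sampled from 2D maps")
    h, w = arr.shape
    for r, c in (p0, p1):
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValidationError(f"endpoint ({r}, {c}) outside image of shape {arr.shape}")
    length_px = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
    n = int(round(length_px)) + 1
    if n < 16:
        raise ValidationError(f"segment too short: {length_px:.1f} px gives {n} samples (< 16)")
    rows = np.linspace(p0[0], p1[0], n)
    cols = np.linspace(p0[1], p1[1], n)
    samples = map_coordinates(arr, [rows, cols], order=1, mode="nearest")
    spacing_um = (length_px / (n - 1)) / pitch
    return LineProfile(endpoints=(tuple(p0), tuple(p1)), samples=samples, spacing_um=spacing_um)


def mean_spatial_frequency(
    profile: LineProfile,
    window: str = "hann",
    weighting: str = "amplitude",
) -> float:
    """Amplitude-weighted mean frequency (μm⁻¹) of the mean-subtracted profile.

    DC is excluded; the one-sided spectrum runs to Nyquist.
    """
    x = profile.samples - profile.samples.mean()
    if np.allclose(x, 0):
        raise DegenerateDataError("constant profile has no spatial frequency content")
    n = x.size
    if window == "hann":
        x = x * np.hanning(n)
        x = x - x.mean()
    elif window != "none":
        raise ValidationError("window must be 'hann' or 'none'")
    amp = np.abs(np.fft.rfft(x))
    freq = np.fft.rfftfreq(n, d=profile.spacing_um)
    pos = freq > 0
    if weighting == "amplitude":
        wgt = amp[pos]
    elif weighting == "power":
        wgt = amp[pos] ** 2
    else:
        raise ValidationError("weighting must be 'amplitude' or 'power'")
    total = wgt.sum()
    if total <= 0:
        raise DegenerateDataError("profile spectrum is identically zero")
    return float((freq[pos] * wgt).sum() / total)


def sheath_diameter(mean_frequency_per_um: float) -> float:
    """Average external sheath diameter (μm) = 1 / mean spatial frequency."""
    if not mean_frequency_per_um > 0:
        raise ValidationError("mean frequency must be positive")
    return 1.0 / mean_frequency_per_um


def format_diameter(diameter_um: float) -> str:
    """Report a diameter truncated (not rounded) to one decimal, e.g. 2.77 → '2.7'."""
    if diameter_um < 0:
        raise ValidationError("diameter must be non-negative")
    return f"{math.floor(diameter_um * 10.0) / 10.0:.1f}"


def profile_spectrum_summary(
    profile: LineProfile, window: str = "hann", weighting: str = "amplitude"
) -> SpectrumSummary:
    """Convenience wrapper: mean frequency and diameter of one profile."""
    fbar = mean_spatial_frequency(profile, window=window, weighting=weighting)
    n_bins = profile.samples.size // 2
    return SpectrumSummary(
        mean_frequency_per_um=fbar, diameter_um=1.0 / fbar, n_freq_bins=n_bins
    )
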