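"""Quantitative phase reconstruction from 4-frame RGB interferograms.

Each RGB frame is first collapsed to a grayscale intensity

    I(x, y; m) = r·R + g·G + b·B,        r + g + b = 1,

with empirically calibrated weights (defaults r=0.1, g=0.6, b=0.3). The four
intensities at phase shifts m·π/2 follow the phase-shifting interferometry
model

    I_m = |U_i|² + |U_s|² + 2|U_i||U_s| cos(Δφ + m·π/2),

where U_i and U_s are the incident and scattered fields and Δφ their phase
difference. Per pixel the standard four-frame solution gives

    Δφ    = atan2(I₃ − I₁, I₀ − I₂)
    S     = (I₀ + I₁ + I₂ + I₃)/4 = |U_i|² + |U_s|²
    G     = √((I₀ − I₂)² + (I₃ − I₁)²)/4 = |U_i||U_s|
    |U_i|² = (S + √(S² − 4G²))/2          (root choice |U_i| ≥ |U_s|)
    β     = |U_s|/|U_i| = G/|U_i|²
    φ     = atan2(β sin Δφ, 1 + β cos Δφ),

taking the unscattered field as dominant, as it is in transmission phase
microscopy of thin sections. φ is the measurable phase of the total field
relative to the incident field; no unwrapping is applied (4 μm sections stay
well below 2π).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .image_io import InterferogramStack, QuantMap, RgbFrame

logger = logging.getLogger(__name__)

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class ChannelWeights:
    """RGB-to-grayscale weighting; must be non-negative and sum to 1."""

    r: float = 0.1
    g: float = 0.6
    b: float = 0.3

    def __post_init__(self) -> None:
        if min(self.r, self.g, self.b) < 0:
            raise ValidationError("channel weights must be non-negative")
        if abs(self.r + self.g + self.b - 1.0) > _WEIGHT_TOL:
            raise ValidationError(
                f"channel weights must sum to 1, got {self.r + self.g + self.b!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=np.float64)


DEFAULT_WEIGHTS = ChannelWeights()


@dataclass(frozen=True)
class ReconResult:
    """Reconstructed maps of one field: φ, Δφ (radians) and β = |U_s|/|U_i|."""

    phase: QuantMap
    delta_phi: QuantMap
    beta: QuantMap
    n_degenerate: int = 0
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if not (self.phase.shape == self.delta_phi.shape == self.beta.shape):
            raise ValidationError("result maps must share dimensions")


def rgb_to_gray(frame: RgbFrame | np.ndarray, w: ChannelWeights = DEFAULT_WEIGHTS) -> np.ndarray:
    """Weighted channel sum; output stays in [0, 1] because weights sum to 1."""
    px = frame.pixels if isinstance(frame, RgbFrame) else np.asarray(frame, dtype=np.float64)
    return px @ w.as_array()


def reconstruct_phase(
    stack: InterferogramStack, w: ChannelWeights = DEFAULT_WEIGHTS
) -> ReconResult:
    """Solve the four-frame interferometry model for φ, Δφ and β per pixel.

    Degenerate pixels (no modulation, G = 0) get Δφ = φ = 0 and are counted;
    pixels where S² < 4G² beyond numerical tolerance are clipped and counted.
    """
    intensity = [rgb_to_gray(f, w) for f in stack.frames]
    i0, i1, i2, i3 = intensity
    num = i3 - i1
    den = i0 - i2
    delta_phi = np.arctan2(num, den)
    s = (i0 + i1 + i2 + i3) / 4.0
    g = np.hypot(den, num) / 4.0

    disc = s * s - 4.0 * g * g
    n_clipped = int(np.count_nonzero(disc < -1e-9))
    disc = np.clip(disc, 0.0, None)

    ui2 = (s + np.sqrt(disc)) / 2.0  # |U_i|², dominant root
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ui2 > 0, g / ui2, 0.0)
    beta = np.clip(beta, 0.0, 1.0)

    degenerate = g <= 1e-15
    n_degenerate = int(np.count_nonzero(degenerate))
    delta_phi = np.where(degenerate, 0.0, delta_phi)
    beta = np.where(degenerate, 0.0, beta)

    phase = np.arctan2(beta * np.sin(delta_phi), 1.0 + beta * np.cos(delta_phi))
    phase = np.where(degenerate, 0.0, phase)

    if n_degenerate or n_clipped:
        logger.info(
            "field %s: %d degenerate pixels, %d clipped discriminants",
            stack.field_id or "<unnamed>",
            n_degenerate,
            n_clipped,
        )
    pitch = stack.pixel_pitch
    return ReconResult(
        phase=QuantMap(phase, units="radians", pixel_pitch=pitch),
        delta_phi=QuantMap(delta_phi, units="radians", pixel_pitch=pitch),
        beta=QuantMap(beta, units="dimensionless", pixel_pitch=pitch),
        n_degenerate=n_degenerate,
        n_clipped=n_clipped,
    )


def normalize_background(phase: QuantMap, n_bins: int = 256) -> QuantMap:
    """Shift the phase map so the tissue-free background sits at zero.

    The offset is estimated as the mode of the phase histogram (``n_bins``
    bins spanning the observed range), which is dominated by background as
    long as tissue covers a minority of the field. A stand-in for full
    stain-aware normalization; swap in a custom callable upstream if needed.
    """
    if phase.units != "radians":
        raise ValidationError("normalize_background expects a phase map in radians")
    v = phase.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return phase.with_values(np.zeros_like(v))
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    k = int(np.argmax(counts))
    mode = 0.5 * (edges[k] + edges[k + 1])
    return phase.with_values(v - mode)
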