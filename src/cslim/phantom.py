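"""Synthetic tissue phantoms and the interferogram forward model.

The phantom emulates an LFB-stained white-matter field: curved fibrous
myelin strokes (blue, high phase), elliptical cell bodies (violet, lower
phase) and a pale background. It carries full ground truth — phase map,
fiber/cell masks, β map and the rendered stain image — so every pipeline
stage can be tested without microscope data.

The forward model is the exact algebraic inverse of the reconstruction:
given target φ and β per pixel, the incident-to-scattered phase difference
is Δφ = φ + asin(sin φ / β) (feasible only when |sin φ| ≤ β), and the four
intensities are

    I_m = a²(1 + β² + 2β cos(Δφ + m·π/2)),

with a global incident amplitude a chosen so every rendered channel stays
in [0, 1]. Intensities are distributed to R, G, B proportionally to a
per-pixel stain chromaticity, so the weighted channel sum reproduces I_m
exactly and the unshifted frame is the stained brightfield image. Detector
noise is i.i.d. Gaussian on each channel of each frame.

Stain darkness grows with the number of overlapping fiber strokes
(Beer–Lambert-like transmission per stroke pass), so dry mass, mask area
and stain intensity rise together across fiber counts, as they do in real
sections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import ellipse
from skimage.morphology import dilation, disk

from .errors import FeasibilityError, ValidationError
from .image_io import (
    DEFAULT_PIXEL_PITCH,
    InterferogramStack,
    QuantMap,
    RgbFrame,
    write_quant_map,
    write_rgb_frame,
)
from .phase_reconstruction import DEFAULT_WEIGHTS, ChannelWeights

# Class colors (fully stained chromaticity, before blending with background).
FIBER_RGB = (0.20, 0.45, 0.85)  # LFB blue, hue ≈ 217°
CELL_RGB = (0.60, 0.20, 0.75)  # cresyl violet, hue ≈ 284°
BACKGROUND_RGB = (0.98, 0.97, 0.95)  # pale, saturation ≈ 0.03

#: Transmission per fiber-stroke pass; stain darkness = 1 − T^n_crossings.
STROKE_TRANSMISSION = 0.45
CELL_STAIN_ALPHA = 0.80
#: Fraction of full scale left as headroom for additive noise.
INTENSITY_HEADROOM = 0.90


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, optics and noise settings of one synthetic field."""

    height_px: int = 512
    width_px: int = 512
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    n_fibers: int = 12
    fiber_period_um: float = 2.7  # stroke width / center-to-center scale
    fiber_phase_amp: float = 1.0  # radians
    n_cells: int = 10
    cell_phase_amp: float = 0.5  # radians
    background_phase: float = 0.0
    beta: float = 0.95  # |U_s|/|U_i|, uniform over the field
    noise_sigma: float = 0.0  # fraction of full-scale intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValidationError("phantom dimensions must be positive")
        if self.n_fibers < 0 or self.n_cells < 0:
            raise ValidationError("object counts must be >= 0")
        if self.fiber_phase_amp < 0 or self.cell_phase_amp < 0:
            raise ValidationError("phase amplitudes must be >= 0")
        if not 0.0 <= self.noise_sigma <= 0.2:
            raise ValidationError("noise_sigma must lie in [0, 0.2]")
        if not 0.0 < self.beta <= 1.0:
            raise ValidationError("beta must lie in (0, 1]")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of one phantom field."""

    phase: QuantMap  # radians
    stain_rgb: RgbFrame  # the noise-free brightfield rendering
    fiber_mask: np.ndarray  # bool
    cell_mask: np.ndarray  # bool, disjoint from fiber_mask
    beta: QuantMap  # dimensionless, in (0, 1]
    stroke_areas_px: tuple[int, ...] = ()


def _draw_stroke(rng: np.random.Generator, h: int, w: int, radius_px: float) -> np.ndarray:
    """One smooth curved stroke: a random-curvature walk dilated to width."""
    center = np.zeros((h, w), dtype=bool)
    r = rng.uniform(0.15 * h, 0.85 * h)
    c = rng.uniform(0.15 * w, 0.85 * w)
    heading = rng.uniform(0, 2 * np.pi)
    curvature = rng.uniform(-0.02, 0.02)
    length = int(rng.uniform(0.45, 0.75) * min(h, w))
    for _ in range(length):
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < h and 0 <= ci < w:
            center[ri, ci] = True
        heading += curvature + rng.normal(0, 0.03)
        r += np.sin(heading)
        c += np.cos(heading)
    return dilation(center, disk(max(1, int(round(radius_px)))))


def make_phantom(spec: PhantomSpec, w: ChannelWeights = DEFAULT_WEIGHTS) -> PhantomTruth:
    """Generate one phantom field, reproducible from ``spec.seed``.

    The stain rendering depends on the channel weights because the
    brightfield frame *is* the unshifted interferogram: its grayscale under
    ``w`` must equal I₀ of the forward model.
    """
    rng = np.random.default_rng(spec.seed)
    h, width = spec.height_px, spec.width_px
    stroke_radius = 0.5 * spec.fiber_period_um * spec.pixel_pitch

    crossings = np.zeros((h, width), dtype=np.int32)
    stroke_areas = []
    for _ in range(spec.n_fibers):
        stroke = _draw_stroke(rng, h, width, stroke_radius)
        stroke_areas.append(int(stroke.sum()))
        crossings += stroke
    fiber_mask = crossings > 0

    cell_mask = np.zeros((h, width), dtype=bool)
    for _ in range(spec.n_cells):
        rr, cc = ellipse(
            rng.uniform(0.1 * h, 0.9 * h),
            rng.uniform(0.1 * width, 0.9 * width),
            rng.uniform(2.0, 4.0) * spec.pixel_pitch / 2,
            rng.uniform(2.0, 4.0) * spec.pixel_pitch / 2,
            shape=(h, width),
            rotation=rng.uniform(0, np.pi),
        )
        cell_mask[rr, cc] = True
    cell_mask &= ~fiber_mask  # cell bodies never overwrite myelin

    occupied = float((fiber_mask | cell_mask).mean())
    if occupied > 0.9:
        raise ValidationError(
            f"phantom overcrowded: objects cover {occupied:.0%} of the field (> 90%)"
        )

    phase = np.full((h, width), spec.background_phase, dtype=np.float64)
    phase[cell_mask] = spec.background_phase + spec.cell_phase_amp
    phase[fiber_mask] = spec.background_phase + spec.fiber_phase_amp

    # Stain chromaticity: blend white toward the class color by stain density.
    alpha = np.zeros((h, width), dtype=np.float64)
    alpha[fiber_mask] = 1.0 - STROKE_TRANSMISSION ** crossings[fiber_mask]
    alpha[cell_mask] = CELL_STAIN_ALPHA
    base = np.empty((h, width, 3), dtype=np.float64)
    base[:] = BACKGROUND_RGB
    base[fiber_mask] = FIBER_RGB
    base[cell_mask] = CELL_RGB
    white = np.ones(3)
    chroma = (1.0 - alpha[..., None]) * white + alpha[..., None] * base

    beta = np.full((h, width), spec.beta, dtype=np.float64)
    i0 = _forward_intensities(phase, beta, chroma, w)[1][0]
    gray0 = chroma @ w.as_array()
    stain_rgb = RgbFrame(
        np.clip(chroma * (i0 / gray0)[..., None], 0.0, 1.0), spec.pixel_pitch
    )
    return PhantomTruth(
        phase=QuantMap(phase, units="radians", pixel_pitch=spec.pixel_pitch),
        stain_rgb=stain_rgb,
        fiber_mask=fiber_mask,
        cell_mask=cell_mask,
        beta=QuantMap(beta, units="dimensionless", pixel_pitch=spec.pixel_pitch),
        stroke_areas_px=tuple(stroke_areas),
    )


def delta_phi_for_phase(phase: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Invert φ = atan2(β sin Δφ, 1 + β cos Δφ) for Δφ at given β.

    Raises :class:`FeasibilityError` where |sin φ| > β (phase unreachable).
    """
    ratio = np.sin(phase) / beta
    bad = np.abs(ratio) > 1.0 + 1e-12
    if bad.any():
        idx = np.argwhere(bad)[:5].tolist()
        raise FeasibilityError(
            f"{int(bad.sum())} pixels request |sin φ| > β "
            f"(unreachable phase); first offenders at {idx}"
        )
    return phase + np.arcsin(np.clip(ratio, -1.0, 1.0))


def _modulations(phase: np.ndarray, beta: np.ndarray) -> list[np.ndarray]:
    """M_m = 1 + β² + 2β cos(Δφ + m·π/2): interference modulation per shift."""
    dphi = delta_phi_for_phase(phase, beta)
    shifts = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
    return [1.0 + beta**2 + 2.0 * beta * np.cos(dphi + s) for s in shifts]


def _forward_intensities(
    phase: np.ndarray, beta: np.ndarray, chroma: np.ndarray, w: ChannelWeights
) -> tuple[float, list[np.ndarray]]:
    """Four intensity grids for target (φ, β), plus the amplitude scale a².

    The stain absorbs: each pixel's intensity carries a transmission factor
    equal to the weighted gray of its chromaticity, so darker stain renders
    as a darker brightfield. Per-pixel transmission leaves phase
    reconstruction untouched (the four-frame solution is scale invariant).
    """
    gray0 = chroma @ w.as_array()
    a2 = INTENSITY_HEADROOM / float(((1.0 + beta) ** 2 * chroma.max(axis=2)).max())
    return a2, [a2 * gray0 * m for m in _modulations(phase, beta)]


def forward_interferograms(
    truth: PhantomTruth,
    w: ChannelWeights = DEFAULT_WEIGHTS,
    noise_sigma: float = 0.0,
    seed: int = 0,
    field_id: str = "",
) -> InterferogramStack:
    """Render the 4 phase-shifted RGB frames consistent with the ground truth.

    Noise-free, the unshifted frame equals ``truth.stain_rgb`` and
    reconstruction recovers φ, Δφ and β to numerical precision.
    """
    rng = np.random.default_rng(seed)
    bf = truth.stain_rgb.pixels
    mods = _modulations(truth.phase.values, truth.beta.values)
    frames = []
    # channels scale with M_m / M₀ so each frame keeps the stain chromaticity
    # and the weighted gray reproduces I_m exactly
    for m_m in mods:
        px = bf * (m_m / mods[0])[..., None]
        if noise_sigma > 0:
            px = px + rng.normal(0.0, noise_sigma, px.shape)
        frames.append(RgbFrame(np.clip(px, 0.0, 1.0), truth.stain_rgb.pixel_pitch))
    return InterferogramStack(tuple(frames), field_id=field_id)


def forward_stack_from_fields(
    delta_phi: np.ndarray,
    beta: np.ndarray | float,
    w: ChannelWeights = DEFAULT_WEIGHTS,
    noise_sigma: float = 0.0,
    seed: int = 0,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    field_id: str = "",
) -> InterferogramStack:
    """Forward-model a stack directly from (Δφ, β) fields, neutral-gray color.

    Lower-level entry point for reconstruction round trips that want to
    prescribe Δφ rather than φ.
    """
    dphi = np.asarray(delta_phi, dtype=np.float64)
    beta_arr = np.broadcast_to(np.asarray(beta, dtype=np.float64), dphi.shape)
    if (beta_arr < 0).any() or (beta_arr > 1).any():
        raise ValidationError("beta must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    a2 = INTENSITY_HEADROOM / float(((1.0 + beta_arr) ** 2).max())
    shifts = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
    frames = []
    for s in shifts:
        i_m = a2 * (1.0 + beta_arr**2 + 2.0 * beta_arr * np.cos(dphi + s))
        px = np.repeat(i_m[..., None], 3, axis=2)
        if noise_sigma > 0:
            px = px + rng.normal(0.0, noise_sigma, px.shape)
        frames.append(RgbFrame(np.clip(px, 0.0, 1.0), pixel_pitch))
    return InterferogramStack(tuple(frames), field_id=field_id)


def expected_phase(delta_phi: np.ndarray, beta: np.ndarray | float) -> np.ndarray:
    """Closed-form φ for given (Δφ, β); oracle for round-trip checks."""
    b = np.asarray(beta, dtype=np.float64)
    return np.arctan2(b * np.sin(delta_phi), 1.0 + b * np.cos(delta_phi))


def sinusoidal_stripes(
    period_um: float,
    height_px: int = 128,
    width_px: int = 256,
    amplitude: float = 1.0,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
) -> QuantMap:
    """Parallel stripes with a sinusoidal profile along columns.

    A horizontal cross-section is a pure tone at 1/period_um, emulating a
    regular bundle of parallel fibers for morphometry tests.
    """
    if period_um <= 0:
        raise ValidationError("period must be positive")
    cols = np.arange(width_px) / pixel_pitch
    profile = 0.5 * amplitude * (1.0 + np.sin(2.0 * np.pi * cols / period_um))
    values = np.tile(profile, (height_px, 1))
    return QuantMap(values, units="radians", pixel_pitch=pixel_pitch)


def sample_bimodal(
    mu1: float,
    sigma1: float,
    mu2: float,
    sigma2: float,
    weight1: float,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled draws from a two-component Gaussian mixture.

    Returns ``(values, labels)`` with labels 0/1 for components 1/2.
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValidationError("sigmas must be positive")
    if not 0.0 <= weight1 <= 1.0:
        raise ValidationError("weight1 must lie in [0, 1]")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) >= weight1).astype(int)
    values = np.where(
        labels == 0,
        rng.normal(mu1, sigma1, n),
        rng.normal(mu2, sigma2, n),
    )
    return values, labels


def write_phantom_field(
    out_dir: str | Path,
    truth: PhantomTruth,
    stack: InterferogramStack,
    bit_depth: int = 16,
) -> Path:
    """Write one field's 4 frames plus ground truth to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m, frame in enumerate(stack.frames):
        write_rgb_frame(frame, out / f"frame_{m}.tif", bit_depth=bit_depth)
    write_quant_map(truth.phase, out / "truth_phase.tif")
    summary = {
        "fiber_area_px": int(truth.fiber_mask.sum()),
        "cell_area_px": int(truth.cell_mask.sum()),
        "pixel_pitch": truth.phase.pixel_pitch,
        "max_phase_rad": float(truth.phase.values.max()),
    }
    (out / "truth_summary.json").write_text(json.dumps(summary, indent=2))
    return out
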