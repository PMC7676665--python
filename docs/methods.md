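# Methods

## Phase reconstruction

The four interferogram frames of one field are modeled per pixel as

    I_m = |U_i|² + |U_s|² + 2 |U_i||U_s| cos(Δφ + m·π/2),   m = 0..3,

where U_i is the incident (unscattered) field, U_s the field scattered by
the specimen, and Δφ their phase difference. Each RGB frame is first
reduced to intensity by the weighted channel sum I = rR + gG + bB with
r + g + b = 1; the defaults (r=0.1, g=0.6, b=0.3) are the empirical
calibration of the spatial light modulator at its equivalent central
wavelength. The four-frame solution is

    Δφ = atan2(I₃ − I₁, I₀ − I₂),
    S  = ΣI_m / 4 = |U_i|² + |U_s|²,   G = √((I₀−I₂)² + (I₃−I₁)²)/4 = |U_i||U_s|,
    |U_i|² = (S + √(S² − 4G²)) / 2,    β = G / |U_i|²,
    φ  = atan2(β sin Δφ, 1 + β cos Δφ).

The quadratic in |U|² has two roots; the larger is assigned to the
incident field because in transmission microscopy of thin (≈4 μm)
sections the unscattered component dominates (β ≤ 1). φ is reported on
(−π, π] without unwrapping — thin sections stay far below 2π. Note the
geometry constrains |φ| ≤ asin(β) for β < 1: weakly scattering pixels can
only produce small total-field phases.

Degenerate pixels with no modulation (G = 0) get Δφ = φ = 0 and are
counted per field; discriminants S² − 4G² < 0 beyond 1e−9 (possible only
through noise) are clipped to zero and counted. Reconstruction is
invariant to any per-pixel positive scaling of all four intensities,
which is why stain absorption in the brightfield path does not bias φ.

Background normalization subtracts the mode of the phase histogram (256
bins over the observed range), placing tissue-free background at zero.
This assumes background is the modal population of the field; it is
exposed as a replaceable step so a stain-aware normalization can be
plugged in. The residual offset is at most one bin width (range/256).

## Dry mass

ρ = λφ/(2πη) with λ the center wavelength (default 550 nm — a required,
logged setting, chosen as the midpoint of the visible band used by the
white-light source) and η = 0.2 ml/g the refraction increment, an average
over reported values for cellular dry matter. In SI, η = 2×10⁻⁴ m³/kg and
1 kg/m² = 1000 pg/μm², giving 0.43768 pg/μm² per radian at the defaults.
Region mass is a Riemann sum over pixels of area (1/pixel_pitch)², with
the default pitch 7.2 px/μm (≈0.0193 μm²/pixel); no interpolation.

## Stain segmentation

Myelin is located, never quantified, by the stain: a pixel enters the
mask iff its HSV hue lies in the LFB-blue window [170°, 280°] and its
saturation clears a minimum. The saturation minimum defaults to the
valley between the two dominant peaks of the saturation histogram of
hue-window pixels (background haze vs dye); valleys above 0.25 indicate
within-stain structure (e.g. fiber crossings) rather than a
background/stain split and revert to the fixed floor 0.15, as does a
unimodal histogram. Cleanup is a morphological closing (disk radius 1 px)
followed by removal of 8-connected components below 50 px (≈1 μm²);
components exactly at the limit are kept. A mask covering more than 90%
of a frame raises a hyper-staining QC flag rather than a hard error,
since no numeric exclusion criterion is established.

HSV thresholding was chosen over stain-vector deconvolution because it is
parameter-transparent and separates LFB blue from cresyl-violet cell
bodies (hue ≈285°, outside the window) without a calibration step.

## Tile classification

Each field is quartered (odd dimensions give the extra row/column to the
south/east tiles; the four tiles partition the field exactly). The tile
statistic is the unmasked mean dry-mass density — classification precedes
segmentation in the pipeline order. Across a slide these means are
bimodal (myelin-rich tract vs parenchyma) and are fitted with a
two-component 1D Gaussian mixture by EM: initialization at the 25th/75th
percentiles with pooled variance and equal weights (deterministic and
affine-equivariant, so the decision threshold transforms affinely with
the data); convergence when the log-likelihood gain falls below 1e−8 or
after 500 iterations; a variance floor of 1e−9 × data range guards
against component collapse. The high/low threshold is the equal-posterior
crossing between the means (the quadratic root inside (μ_low, μ_high);
midpoint fallback if none lies inside). Fits with Δμ < max(σ_low, σ_high)
are flagged non-bimodal but still returned and usable. Ties at the
threshold classify as high, biasing toward inclusion of myelin.

EM on tile aggregates (rather than curve-fitting per-pixel histograms)
was chosen because the goal is selecting high-myelin quarter frames, and
EM is deterministic and directly testable against an independent
implementation.

## Fiber morphometry

A cross-section profile is sampled by bilinear interpolation at
approximately unit-pixel steps (n = round(length)+1 points spread evenly
over the segment), minimum 16 samples. After mean subtraction and Hann
windowing, the amplitude-weighted mean of the one-sided spectrum
(DC excluded, up to Nyquist) gives f̄ = Σf·|A|/Σ|A|, and the average
external sheath diameter is d = 1/f̄, truncated (not rounded) to one
decimal for display so that 1/0.36 = 2.77… reports as 2.7 μm.

The Hann window is the default by numerical necessity: with a rectangular
window, spectral leakage of a tone whose period does not divide the
profile length biases the amplitude-weighted mean by up to ~20 DFT bins
(the 1/|k−k₀| leakage tails are integrated over an asymmetric frequency
range), while the Hann window keeps single-tone recovery within 0.15
bins across periods of 1–10 μm. A rectangular window and power (|A|²)
weighting remain available as options.

## Phantom

The generator emulates an LFB-stained white-matter field: `n_fibers`
smooth curved strokes (random-curvature walks dilated to width ≈ the
2.7 μm fiber scale) at phase 1.0 rad, `n_cells` ellipses (3–6 μm axes) at
0.5 rad, on a zero-phase background; cells never overwrite fibers, so the
truth masks are disjoint. Phase is piecewise constant, which keeps the
ground-truth fiber mass exactly computable and mask edges sharp. β is
uniform at 0.95 — large enough that φ = 1 rad is reachable
(asin 0.95 ≈ 1.25), which a realistic tissue β must be, given the
|φ| ≤ asin β constraint above.

The forward model inverts the reconstruction exactly: Δφ = φ +
asin(sin φ / β) (raising a feasibility error where |sin φ| > β), then
I_m = a²·T·(1 + β² + 2β cos(Δφ + mπ/2)) with a per-pixel transmission T
equal to the weighted gray of the stain chromaticity — the stain absorbs,
so stained pixels render darker without touching the reconstructed phase.
Stain chromaticity blends white toward LFB blue (hue ≈217°) by a
Beer–Lambert-like factor 1 − 0.45^k in the number k of overlapping
strokes, so dry mass, mask area and mean stain darkness rise together
with fiber count, as the three features do in real sections. Intensities
are scaled globally so the brightest channel reaches 0.9, leaving
headroom for additive Gaussian detector noise (applied per channel and
frame, then clipped to [0, 1]). The unshifted frame equals the stain
rendering identically.

What the phantom does not emulate: halo/shade-off artifacts of partially
coherent illumination, spatially varying illumination, chromatic
dispersion between camera channels, staining heterogeneity within a
fiber, and tissue autofluorescence. Passing tests therefore demonstrate
the algebra, segmentation logic and bookkeeping of the pipeline — not
robustness to those instrument effects.

## Statistics

Group comparisons use the two-sided two-sample Student t-test (pooled
variance) by default, Welch's test optionally for unequal group sizes or
variances; significance at α = 0.05 on raw p-values, no multiple-testing
correction. Feature association is a Pearson correlation matrix of dry
mass, mask area and stain intensity. Group labels can be merged from a
separate key file at comparison time to support blinded measurement.

## Problem sizes and tolerances

Default phantom fields are 512×512 px (≈71×71 μm at 7.2 px/μm) with 12
fibers and 10 cells; round-trip and noise tests use 256×256 fields, and
the slide-level pipeline tests use four 256×256 fields — sizes at which
every distributional property under test is already stable. Noise-free
reconstruction round trips are exact to <1e−6 rad (measured ≈1e−15); with
1% full-scale intensity noise the phase RMSE bound is 0.02 rad (measured
≈0.005 at β = 0.5); end-to-end fiber-mass recovery is required within 5%
of truth at 1% noise (measured ≈2.7%, dominated by noise-floor pixels
admitted by the mask and the one-bin normalization offset); mask IoU ≥
0.95 (measured ≈0.998). Mixture-recovery tolerances (means ±0.02,
≥98% label agreement at Δμ = 10σ) follow from the sampling error of 500
draws per component.
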