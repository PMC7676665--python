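# cslim — myelin quantification from color SLIM interferograms

`cslim` measures the dry mass of myelin in stained brain-tissue sections
imaged by color spatial light interference microscopy (cSLIM). cSLIM
acquires four RGB interferograms per field of view at phase shifts of 0,
π/2, π and 3π/2; the unshifted frame is the ordinary brightfield image of
the Luxol-Fast-Blue-stained section, so a single scan yields both the
stain image and a quantitative phase map. The package is aimed at
quantitative-phase-imaging and neurohistology groups who want
stain-localized, label-free dry-mass measurements of white matter.

## What it computes

Each RGB frame is collapsed to a grayscale intensity `I = rR + gG + bB`
(`r + g + b = 1`, defaults `r=0.1, g=0.6, b=0.3`). The four intensities
follow the phase-shifting model
`I_m = |U_i|² + |U_s|² + 2|U_i||U_s| cos(Δφ + mπ/2)`, solved per pixel for
the incident/scattered phase difference Δφ, the amplitude ratio
β = |U_s|/|U_i| and the measured phase
`φ = atan2(β sin Δφ, 1 + β cos Δφ)`.

Phase converts to dry-mass surface density through the refraction
increment η of biological material:

    ρ(x, y) = λ / (2π η) · φ(x, y)        [pg/μm²]

with λ = 550 nm and η = 0.2 ml/g by default (0.43768 pg/μm² per radian).
Downstream, the pipeline

- segments myelin from the brightfield frame by an HSV color threshold
  (LFB-blue hue window, per-frame saturation threshold) plus morphological
  cleanup, and multiplies the density map by the binary mask;
- splits fields into quarter frames, fits a two-component Gaussian mixture
  to the tile mean densities by EM, and labels tiles high/low myelin at
  the equal-posterior threshold;
- integrates dry mass over the high- and low-myelin tile sets;
- estimates the average myelin sheath diameter as the reciprocal of the
  amplitude-weighted mean spatial frequency of cross-section profiles;
- compares groups with the two-sample Student t-test and correlates dry
  mass, mask area and stain intensity.

A built-in phantom generator renders synthetic fibrous tissue with full
ground truth (phase, masks, stain image) and forward-models the four
interferogram frames exactly, so every stage is testable without
microscope data.

## Worked example

```python
import numpy as np
from cslim import (PhantomSpec, make_phantom, forward_interferograms,
                   reconstruct_phase, normalize_background, phase_to_density,
                   myelin_mask, filter_mask, integrate_mass,
                   sheath_diameter, format_diameter)

truth = make_phantom(PhantomSpec(seed=2))
stack = forward_interferograms(truth, noise_sigma=0.01, seed=2)

recon = reconstruct_phase(stack)                 # φ, Δφ, β maps
phase = normalize_background(recon.phase)        # background → 0 rad
density = phase_to_density(phase)                # pg/μm²
mask = filter_mask(myelin_mask(stack.brightfield))
measured = integrate_mass(density, mask.mask)
expected = integrate_mass(phase_to_density(truth.phase), truth.fiber_mask)
print(f"measured {measured.total_mass_pg:.1f} pg vs true {expected.total_mass_pg:.1f} pg")
print(f"mean density {measured.mean_density_pg_per_um2:.3f} pg/um^2")
print(format_diameter(sheath_diameter(0.36)), "um")
```

prints

```
measured 526.0 pg vs true 540.3 pg
mean density 0.425 pg/um^2
2.7 um
```

i.e. the stain-masked, reconstructed dry mass of the synthetic fiber
bundle is within 3% of the generator's ground truth, the mean density is
in the range typical of compact white matter, and a measured mean spatial
frequency of 0.36 μm⁻¹ corresponds to an average sheath diameter of
2.7 μm.

A command-line interface mirrors the library:
`cslim phantom`, `cslim reconstruct`, `cslim quantify`, `cslim classify`,
`cslim diameter`, `cslim compare` (see `cslim --help`).

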