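# mcspect

Monte Carlo simulation and iterative reconstruction of ¹¹¹In SPECT/CT,
with a measurement layer for spatial resolution and lesion contrast.

¹¹¹In-octreotide SPECT images of neuroendocrine-tumour patients suffer
from poor spatial resolution and contrast: the parallel-hole collimator
blurs each projection with a distance-dependent point-spread function
(PSF), and photons are attenuated and Compton-scattered in the body.
Reconstruction algorithms differ in how much of this physics they model.
`mcspect` implements the full evaluation chain needed to compare them
without any measured data:

1. **Digital phantoms** — a ~1 mm triple-line resolution insert in a
   water-filled Jaszczak-style cylinder (or in air), and a torso/liver
   phantom with an insertable spherical lesion of prescribed
   tumour-to-normal concentration (TNC) ratio.
2. **Photon-history Monte Carlo acquisition** — isotropic ¹¹¹In emission
   (171/245 keV), Woodcock delta tracking through the attenuation map,
   Klein–Nishina Compton scattering, collimator acceptance-cone
   detection with intrinsic spatial and energy blur, and dual 20% energy
   windows; counts are genuine history-level statistics.
3. **Three OSEM reconstruction variants**
   - **AC OSEM** — ordered-subset expectation maximization with
     attenuation correction only (2 iterations × 10 subsets),
   - **ACRR OSEM** — AC plus resolution recovery: the distance-dependent
     PSF is modelled in forward and back projection,
   - **MC OSEM** — Monte Carlo forward projection (attenuation, PSF
     *and* scatter, via forced detection) with a PSF-corrected analytic
     back projection (5 iterations × 10 subsets),
   plus the clinical Butterworth post filter
   (order 10, critical frequency 0.48 cycles/cm).
4. **Measurements** — line profiles in the X (anteroposterior) and Y
   (left–right) directions fitted with a Gaussian
   (FWHM = 2√(2 ln 2)·σ), 2D elliptical-Gaussian fits quantifying the
   elliptical line-source artifact that points towards the centre of
   rotation (CoR), and TNC ratios from explicit 4-voxel tumour /
   15-voxel normal-tissue VOIs.
5. **Statistics** — means ± sample SD, paired two-sided Student
   t-tests with 95% CIs for X–Y and method-vs-method differences,
   rendered as machine-readable and text tables.

The OSEM update per subset *s* is the standard multiplicative rule

    x ← x · [Aₛᵀ (yₛ / (Aₛ x + ε))] / (Aₛᵀ 1)

where the variant determines the forward model `Aₛ` (analytic with or
without PSF, or Monte Carlo) and the back projector `Aₛᵀ`.  The analytic
back projector is the exact matrix transpose of the forward operator, so
⟨Ax, y⟩ = ⟨x, Aᵀy⟩ holds to machine precision.

## Worked example

```python
import numpy as np
from mcspect import (
    AcquisitionProtocol, SystemModel, ReconConfig,
    make_grid, make_cylinder_attenuation, make_triple_line_activity,
    DEFAULT_LINE_SPECS, simulate_projections, osem_reconstruct,
    extract_line_profile, fit_gaussian_fwhm,
)

grid = make_grid(64, 32, 4.42)                       # 64x64x32, 4.42 mm voxels
system = SystemModel(pixel_size_mm=4.42, matrix=(64, 64))
protocol = AcquisitionProtocol(n_projections=60)
mu = make_cylinder_attenuation(108.0, 186.0, grid, "water", 171.0)
activity = make_triple_line_activity(DEFAULT_LINE_SPECS, 1.0, grid)

raw = simulate_projections(activity, mu, system, protocol,
                           n_histories=2_000_000, seed=1,
                           noise="poisson", emission_band_deg=10.0)
for variant, iters in [("AC", 2), ("ACRR", 2), ("MC", 5)]:
    cfg = ReconConfig(variant, n_iterations=iters, n_subsets=10, seed=1)
    recon = osem_reconstruct(raw, mu, system, cfg, protocol=protocol)
    f = fit_gaussian_fwhm(extract_line_profile(recon, (0.0, 20.0), "y"))
    print(f"{variant:5s} line A, Y direction: FWHM = {f.fwhm_mm:.1f} mm")
```

Output from this exact script (seed 1):

```
AC    line A, Y direction: FWHM = 12.0 mm
ACRR  line A, Y direction: FWHM = 8.9 mm
MC    line A, Y direction: FWHM = 5.6 mm
```

Monte Carlo OSEM resolves the line sharpest, resolution-recovery OSEM is
intermediate, and plain attenuation-corrected OSEM is widest — the
ordering the package exists to demonstrate.  The bundled dual-camera
measurement table is summarised by `mcspect report` (overall FWHM
12.2 ± 3.7 mm for AC, 9.3 ± 2.5 mm for ACRR, 8.2 ± 2.0 mm for MC).

A command-line interface mirrors the library:
`mcspect phantom | simulate | reconstruct | evaluate | report |
run-experiment` (see `mcspect --help`).

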