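# Methods

This note documents the models inside `mcspect`, the defaults and why
they were chosen, what the synthetic studies do and do not show, and the
numerical choices a maintainer would want to know about.

## Photon interaction model

Phantom materials are air and water-equivalent soft tissue; lead appears
only in the collimator septa.  The linear attenuation coefficient is
modelled as

* incoherent (Compton) scattering on free electrons — the closed-form
  Klein–Nishina total cross section times the electron density
  (3.343×10²³ e/g for water, 3.006×10²³ e/g for air);
* photoelectric absorption — an E⁻³ power law anchored at 100 keV
  (2.8×10⁻³ cm²/g for water).

Coherent (Rayleigh) scattering is omitted; at 150–300 keV it contributes
~2% to water's total attenuation and deflects photons by angles small
compared with the energy-window acceptance.  Electron binding is also
neglected (free-electron Klein–Nishina), which overestimates the
incoherent cross section by ≲1% at these energies.  The resulting
μ_water is 0.1432 cm⁻¹ at 171 keV and 0.1272 cm⁻¹ at 245 keV.  Lead
uses a small log-log tabulation of total mass attenuation valid above
the K edge; every lead interaction is treated as absorbing.

Attenuation maps are interpreted as *water-equivalent*: voxel values
rescale water's μ at the map's reference energy, so μ(x, E) for any
photon energy follows from a single stored map.  This is exact for the
binary air/water phantoms used here and is the standard approximation
for CT-derived maps in this energy range.

## Camera and collimator

Defaults describe a NaI(Tl) camera with a medium-energy parallel-hole
collimator: 15.9 mm crystal, 3.9 mm intrinsic FWHM, 9.8% energy
resolution at 140 keV scaling as 1/√E, hole diameter D = 3.0 mm, hole
length 58 mm, septa 1.05 mm.  The effective hole length is
L_eff = L − 2/μ_Pb ≈ 56.8 mm, and the system response at distance d is

    FWHM(d) = sqrt(FWHM_int² + (D · (L_eff + d)/L_eff)²),

16.7 mm at d = 250 mm.  The Monte Carlo detector models the collimator
as an acceptance cone of half-angle atan(D/(√3·L_eff)) ≈ 1.7°: a
uniform cone projected to a plane at distance d is a disc whose 1D
profile has FWHM √3·d·tanθ = d·D/L_eff, so the analog geometric blur
slope matches the distance-dependent part of the formula above.  The
constant D term and the hole-position offset inside a single hole are
not modelled, nor is septal penetration (hard acceptance cutoff); both
are small against the ≥12 mm system FWHM at clinical orbit radii, and
the residual model/data PSF mismatch is of the same character as the
mismatch any vendor resolution-recovery algorithm faces.

¹¹¹In emits 171.28 keV (0.907/decay) and 245.35 keV (0.941/decay)
photons, acquired in two 20% windows; the two windows' counts are
summed before reconstruction (the vendor combination rule is not
public; per-window reconstruction remains available).  The orbit is
circular, 250 mm radius by default; non-circular (body-contour) orbits
are out of scope — a consequence discussed under "Limitations".

## Monte Carlo transport and detection

Emission positions are sampled proportionally to the activity map
(uniform within a voxel), directions isotropically, energies from the
two lines.  Free paths use Woodcock (delta) tracking against the map's
majorant; real collisions split into photoelectric absorption and
Klein–Nishina scattering (rejection sampling against the forward-peak
envelope).  Photons are retired below 50 keV or after 10 scatters.

Analog ("poisson") detection projects each escaped photon along its
actual flight direction onto each view's detector plane, requires the
direction inside the acceptance cone, applies intrinsic spatial blur
and Gaussian energy blur, tests the windows and bins integer counts.
Count statistics therefore arise at history level (binomial ≈ Poisson
at the small per-pixel probabilities involved).  For acquisition runs,
emission may be restricted to a polar band (default ±10°) around the
transverse plane: photons emitted far out of plane can only be detected
after a large-angle scatter into the ~1.7° cone, so the band is a
variance-reduction device; n histories then represent n/sin(band)
isotropic decays.  The band is generous (≈6× the cone) so the detected
scatter spectrum is essentially unchanged.

Expected-mode detection (the MC OSEM forward step) uses forced
detection: every sampled photon deposits, for each requested view, its
analytic probability of escaping unscattered along the detector normal
(transmission from the same midpoint-rule path integrals the analytic
projector uses, times the cone solid-angle fraction and the window
acceptance), and every Compton vertex of the analog walk deposits its
Klein–Nishina probability of scattering into the cone, escaping at the
scattered energy and passing a window.  Deposits are binned in the
detector-aligned rotated grid and the distance-dependent PSF plus depth
summation are applied analytically — the identical discretisation as
the analytic projector — so the only Monte Carlo noise left is that of
the sampled activity distribution.  This matters: an earlier design
that sampled the PSF displacement per photon left statistical zeros in
the forward estimate at pixels with measured counts, and the
multiplicative OSEM update amplified them catastrophically.  With the
final estimator, expected-mode projections of a smooth phantom agree
with the analytic projector to <1% relative RMS at 10⁶ histories, and
are bit-reproducible given the seed.

## Projector and OSEM

The analytic projector rotates each transverse slice with a bilinear
interpolation matrix (stored sparse, one per angle), weights voxels by
midpoint-rule attenuation along the depth axis, optionally convolves
each depth plane with a Gaussian of σ(d) (zero-filled boundaries), and
sums along rays.  The back projector applies the transposed sparse
matrix and the same symmetric convolutions, making the pair exactly
adjoint — the property the adjointness tests check at 10⁻⁶ relative.

OSEM starts from a uniform image inside the attenuation support (μ
above half its maximum), uses interleaved angle subsets processed in a
greedy maximal-separation order, guards empty rays with ε = 10⁻¹⁰
(pixels with neither measured nor expected counts contribute a factor
1), and preserves nonnegativity by construction.  Variants: AC (no PSF),
ACRR (PSF forward and back), MC (Monte Carlo forward, analytic
attenuation+PSF back projection).  The MC pair is unmatched
(forward ≠ backᵀ), the usual situation for Monte Carlo reconstruction;
convergence is not guaranteed by MLEM theory but is well behaved at the
5×10 iteration/subset setting used.  Clinical settings are 2 iterations
× 10 subsets for AC/ACRR and 5 × 10 for MC.  The Butterworth post
filter has gain [1 + (f/f_c)^(2n)]^(−1/2) with n = 10 and f_c = 0.48
cycles/cm (the radial spatial frequency), exact unit DC gain; the
alternative exponent convention [1 + (f/f_c)^n]^(-1/2) can be obtained
by halving the order.

Reconstruction uses the 171 keV attenuation map for both windows'
summed counts; the μ difference between 171 and 245 keV (~11%) is a
modest model mismatch of the same kind clinical AC accepts.

## Measurements

Line profiles are single-voxel-wide samples through the located
intensity peak (peak search within 15 mm of the nominal position so
centre mis-specification does not bias the width), averaged over the 5
central axial slices, truncated to ±35 mm so neighbouring lines do not
contaminate the fit, and fitted with amplitude·exp(−(x−c)²/2σ²)+offset
by least squares with moment-based initial values; FWHM = 2√(2 ln 2)·σ.
No interpolation or upsampling precedes fitting — the fit is continuous
in x.  The ellipse measurement fits a 6-parameter elliptical Gaussian
to the transverse slice average and reports the major-axis orientation
and its undirected angle to the source→CoR direction; fits with <5%
axis anisotropy are flagged degenerate.

The TNC tumour VOI is the lesion-centre voxel plus its 3
highest-intensity face neighbours (4 voxels); the normal-tissue VOI is
a fixed 15-voxel template within one voxel of the centre in each
dimension (the 12 edge-adjacent offsets of the 3×3×3 neighbourhood plus
3 corners), disjoint from any possible tumour VOI.  Both voxel lists
are returned for audit.  The clinical VOI prescription (4-voxel tumour,
"range 1 voxel … total 15 voxels") does not determine a unique voxel
set; this template is a declared choice, not an inference.

## Phantoms

Line sources are 1.0 mm discs rasterized with 16× supersampled area
weighting and renormalised so the total activity equals concentration ×
length exactly; the PMMA wall is ignored (sub-voxel, near-water μ).
Default positions relative to the CoR: A (0, +20) mm, B (−40, +45) mm,
C (+45, +50) mm — three distinct radial distances in a triangular
arrangement; the cylinder is 216 mm diameter × 186 mm, water or air.
All geometry is configurable.

The lesion phantom is an elliptical-cylinder torso (90 × 130 mm
semiaxes) of water at unit activity concentration containing an
ellipsoidal liver at twice that concentration (a typical
octreotide liver-to-body uptake contrast).  The lesion is a
radius-1-voxel sphere (the 7-voxel 3D cross) at TNC 8; its raw data are
simulated separately — with the history count scaled by the
lesion-to-background activity ratio so the count scales match — and
added to the background raw data in projection space.  Lesion centres
are drawn uniformly from liver voxels whose 5×5×5 neighbourhood lies in
the liver, so both the lesion and the measurement shell sit in normal
tissue.

## Study conditions and problem sizes

The simulation studies run on a 64×64×32 grid of 4.42 mm voxels with 60
projections — the package's desk-scale conditions, chosen so one
realization takes about a minute while every physical ingredient
(distance-dependent blur spanning ~12–20 mm FWHM across the orbit,
attenuation factors down to e⁻³, a 30–40% scatter fraction in the
photopeak windows) is at full strength:

* resolution study — 2×10⁶ histories per acquisition (~4×10⁴ counts),
  AC/ACRR/MC reconstructions, FWHM per line and direction, ellipse fits
  on the AC image; repeated for ≥3 seeds;
* lesion study — 6×10⁶ histories (~1.4×10⁵ counts, a scaled-down
  clinical count level), AC+Butterworth vs MC reconstructions of the
  same lesion-added raw data; repeated for ≥3 seeds.

The Monte Carlo OSEM forward step uses 10⁵ histories per subset here
(package default 2×10⁵); after the variance-reduction design above the
forward noise at this budget is negligible relative to the data noise.

## What the synthetic studies show — and what they do not

The generator reproduces the *mechanisms* (depth-dependent blur,
attenuation, scatter, Poisson-level noise) but not any particular
camera's calibration: absolute FWHM values in millimetres depend on the
assumed collimator geometry and orbit radius and are therefore not
asserted anywhere — only orderings and directions are.  Observed
behaviour across seeds: mean FWHM orders MC < ACRR < AC with wide
margins; the left–right (Y) profile is wider than the anteroposterior
(X) one in the large majority of (seed, variant, line) cells; line
sources far from the CoR reconstruct as ellipses whose major axes align
with the source→CoR direction (misalignment ≪ 45°), strongest without
resolution modelling; and the measured lesion TNC after MC OSEM exceeds
that after filtered AC OSEM in every realization, both lying strictly
inside (1, 8) as partial volume and residual blur demand.

Two honest caveats.  First, under a circular orbit the line nearest the
CoR elongates *tangentially* in the AC reconstruction (the X
direction for the default layout), so the Y>X direction holds as a
pooled statement rather than uniformly for every variant and line;
measured cameras show uniform Y>X, which plausibly involves
body-contour (non-circular) orbits that are out of scope here.  Second,
the single-patient TNC values that motivated the lesion study depend on
a specific clinical raw data set; the study reproduces their ordering
and magnitude range, not the two numbers.

## Numerical choices

* Rotation: bilinear, about the grid centre; back projection is the
  literal sparse transpose, so adjointness is exact by construction.
* Attenuation line integrals: reversed cumulative sums with half-voxel
  (midpoint) offset, in cm.
* ε-guard 10⁻¹⁰; zero-measured/zero-expected pixels contribute 1.
* Gaussian and ellipse fits: `scipy.optimize.curve_fit`, bounded, with
  moment-based starts; fits failing to converge or with σ exceeding the
  profile span raise with diagnostics rather than returning garbage.
* Seeds: every stochastic stage takes a seed or Generator;
  `numpy.random.SeedSequence` spawns independent substreams per
  iteration and subset, so expected-mode projections and whole
  experiments are bit-reproducible.

## Known limitations

* No septal penetration or hole-pattern modelling; no backscatter from
  behind the crystal; energy response is a single Gaussian.
* Circular orbits only.
* Water-equivalent attenuation only (adequate for the phantoms used;
  bone or contrast agents would need a material map).
* Clinical vendor implementations of AC and resolution-recovery OSEM
  are emulated by generic equivalents; exact vendor agreement is not a
  goal.
* The Monte Carlo forward / analytic back projector pair in MC OSEM is
  unmatched; no convergence proof applies at high iteration counts.
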