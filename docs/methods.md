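# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic-data tests do and do not
demonstrate about real measurements.

## Scintillator composition and bulk constants

The alcohol-based liquid scintillator (AbLS) is 2-ethoxyethanol (C₄H₁₀O₂)
and water. The 7:3 recipe ratio is interpreted as a **volume** ratio —
the common convention for solvent recipes — with component densities
0.930 and 0.998 g/cm³; this puts the 2-ethoxyethanol mass share at 0.685.
The bulk density is pinned to the measured 0.945 g/cm³ rather than the
ideal-mixing estimate (0.951), since mixing water with an alcohol is not
volume-conserving. The basis is a parameter, so a mass-basis composition
can be built for comparison (it changes Z_eff by < 0.02). The PPO and
bis-MSB fluors, present only at g/L levels, are neglected in the
composition.

The effective atomic number uses the Mayneord power law with
electron-number fraction weights and exponent m = 2.94, the standard
medical-physics convention for a single Z_eff of a tissue substitute; the
exponent is a parameter. Result: Z_eff = 6.77 (soft tissue: 6–7.5).

The mean excitation energy I uses Bragg additivity with the elemental
values recommended for condensed compounds (H 19.2, C 81.0, N 82.0,
O 106.0 eV). These reproduce the textbook water value (75.3 eV here vs the
recommended 75 eV) and give 68.9 eV for AbLS. Using gas-phase elemental
values instead would bias every compound low by several eV.

## Stopping powers and CSDA ranges

Collision stopping power is the Berger–Seltzer form of the Bethe formula
for electrons (Møller stopping number) with Sternheimer's *general*
density-effect parameterisation computed from ρ, ⟨Z/A⟩ and I. The general
parameterisation differs from exactly fitted per-material coefficients by
up to ~1% near 10 MeV; the package's water values sit within 1.5% of
standard tabulations (S_col: 1.852 vs 1.849 at 1 MeV, 1.994 vs 1.968 at
10 MeV; CSDA 4.894 vs 4.975 g/cm² at 10 MeV).

Radiative losses use the classic proportionality
S_rad = S_col·(E + m_ec²)·Z_eff/Φ with Φ = 847.4 MeV, calibrated once so
that water's radiative/collision ratio at 10 MeV equals the tabulated
0.092. Below 15 MeV in low-Z media this is a few-percent correction, and
its residual error is far below the targets' precision.

The CSDA range integrates 1/(S/ρ) by the trapezoid rule on a log grid of
200 points per decade from a 1 keV floor (the sub-keV residual range,
≲ 5·10⁻⁵ g/cm², is dropped); halving the grid spacing moves the result by
< 0.1%. Computed AbLS ranges: 2.998 / 4.431 / 5.808 g/cm² at 6/9/12 MeV
(3.17 / 4.69 / 6.15 cm at ρ = 0.945).

## Condensed-history Monte Carlo

Electrons are transported in class-I condensed-history steps without
secondary particle tracking:

- **Step length.** Each step removes 2% of the current kinetic energy
  (parameter); the path length is Δs = ΔE/(S_tot·ρ) evaluated at the
  mid-step energy.
- **Energy deposition.** The collision share of the step's loss is
  deposited at a *uniformly sampled* point along the step. (Depositing at
  the fixed midpoint aliases against the 0.5 mm scoring grid during the
  first, nearly collinear part of every track.) Radiative losses leave the
  geometry by default — bremsstrahlung photons are not tracked — or can be
  deposited on-track.
- **Collision-loss straggling.** Transfers below Δ = 100 keV stay in the
  continuous loss with a Gaussian (Bohr) fluctuation restricted to T < Δ;
  transfers Δ < T < E/2 are sampled as discrete hard collisions from the
  Rutherford 1/T² tail (Poisson count per step, inverse-CDF transfer
  sampling) and deposited at the interaction point. The split keeps the
  mean loss exactly S_col·ρ·Δs while reproducing the Landau skew: the
  *typical* electron loses less than the mean and outlives its CSDA range.
  This skew is what places the distal PDD edge correctly — with purely
  deterministic loss the extracted practical ranges come out 5–7% short,
  and the tangent-extrapolated R_p could never reach the published values,
  which at 12 MeV slightly exceed even the CSDA range.
- **Multiple scattering.** After each step the direction is deflected by
  two independent Gaussian projected angles with the Highland width
  θ₀ = (13.6 MeV/βcp)·√(t)·(1 + 0.038 ln t), t = Δs·ρ/X₀, with the
  radiation length from the standard elemental approximation
  (X₀ ≈ 39.3 g/cm² for AbLS).
- **Termination.** Below 100 keV the residual energy is deposited locally.
  Electrons (and photons) leaving the 10 × 5 × 10 cm container are booked
  as escaped energy; deposited + escaped equals launched energy to
  round-off, and a fixed seed reproduces the dose grid bit for bit.

Scoring is 2D: depth × in-plane lateral position on a 0.05 cm grid, with
the viewing axis integrated out — the same integration a camera performs.
The 6 × 6 cm field is clipped to the 5 cm container width.

Photons (used to emulate the gamma-ray irradiation) take exponential free
flights with μ = Compton (Klein–Nishina total cross-section × electron
density) plus a crude Z_eff³/E³ photoelectric term; Compton interactions
hand the sampled recoil energy to an electron started along the photon
axis. A monoenergetic 2 MeV source stands in for the clinical 6 MV
bremsstrahlung spectrum; pair production and LINAC-head modelling are out
of scope.

At 10⁵ histories per energy, the practical ranges at 6/9/12 MeV are
3.09–3.12 / 4.64–4.66 / 6.13–6.18 cm across seeds. Note the 12 MeV value
can exceed the CSDA linear range (6.145 cm) by a fraction of a percent —
expected for a tangent extrapolation of a straggled distal edge, and
consistent with published range tables.

## Photograph analysis

Camera JPGs are sRGB-encoded; the package keeps an explicit colorspace tag.
XYZ uses the IEC 61966-2-1 sRGB/D65 matrix on linear light. HSV uses the
hexcone model on the *encoded* values, matching common image-processing
practice (a flag selects linear-light V). H is stored as 0 where S = 0.

The dose map applies the V-cut on the encoded V plane — thresholds like
"30%" are chosen by eye on the displayed image — but takes the retained
dose values from the linear-light V plane, because emitted light, not its
gamma-encoded rendering, is proportional to dose. With a noise-free,
blur-free camera the rendered image then inverts to the dose grid up to
8-bit quantisation (Pearson r > 0.999).

R_p extraction: the steepest point of the distal falloff is located on a
3-sample moving average (the tangent itself is fitted to raw data over a
window defaulting to 20% of the falloff extent, measured as the 80%→20%
span / 0.6); when several samples tie for steepest — a linear falloff —
the middle one is used so the window avoids the corners. The background is
the mean over the last 10% of the depth grid. The quoted uncertainty is
half the R_p spread when the tangent window is varied ±50%; this is a
package convention, as error models for such measurements are rarely
stated. The refraction correction is a single multiplicative depth-scale
factor (default 1: off) because the appropriate value depends on the
camera/container geometry; the synthetic camera can inject a known stretch
to exercise it.

## Synthetic data

The camera model renders dose → linear RGB along a blue-dominant emission
direction (z-chromaticity ≈ 0.7, as PPO/bis-MSB fluors emit) → Gaussian
PSF → container-reflection bands → Gaussian (+ optional scaled-Poisson)
noise → sRGB encoding → 8-bit quantisation. Reflection bands are placed at
the top/bottom of the frame with a specified *encoded* V level: 0.25 for
electron scenes (just below the 0.3 cut that is supposed to remove them)
and 0.30 for the gamma scene, whose uniform signal sits near V = 0.63,
giving the characteristic double-peaked V histogram separable by a 0.6
cut. Defaults (gain 1, σ_PSF 1.5 px, σ_noise 0.01) are modest
consumer-camera levels.

The rotation rig renders transmitted backlight I = I₀·exp(−∫μ dl) through
a vial + T-bar phantom whose projections are computed **analytically**
(chords of circles and bar-fixed strips), so the frames carry no
interpolation error and serve as an independent oracle for the Radon
routines. The phantom grid is 161 px (odd, so the geometric centre lies on
a pixel, matching the projection detector-centre convention) with vial
radius 70 px — about 0.19 mm/px for the 3 cm vial. Attenuation levels
(wall 0.004, liquid 0.0012, bar 0.006 /px) keep the deepest optical depth
near 0.6, i.e. an optically thin sample as in the real rig. The refraction
non-ideality is modelled as a fixed displacement of the projections in the
camera frame; conjugate views then disagree, which is why a 360° sinogram
reconstructs better than 180° — the property the tests check. Frames per
revolution defaults to 120 (240 frames = 2 revolutions, averaged per
angle); the real acquisition (50 s revolution filmed at 30 fps = 1500
frames/rev, 6000 frames) is emulated at desk scale.

What the synthetic data does *not* contain: lens distortion, vignetting,
rolling shutter, JPEG compression artifacts, wavelength-dependent
attenuation, scattered-light halos, and any absolute light-yield
calibration. Passing tests therefore demonstrate the correctness of the
analysis chain, not the accuracy of a particular camera or scintillator
batch.

## Tomography

Forward and inverse Radon transforms are delegated to
`skimage.transform.radon/iradon` (parallel beam, linear interpolation,
frequency-domain ramp/Shepp-Logan/Hann filters), wrapped with the package's
angle and detector conventions: angle 0 at the first frame,
counter-clockwise positive, detector along image columns, reconstruction
masked to the inscribed circle. A 360° sinogram is back-projected directly
by default; `fold_360=True` averages conjugate rays onto 180° (with a
one-bin roll for even detector counts, whose centre falls between bins).
Angular coverage below 180° raises. Frames-per-revolution metadata, when
absent, is estimated from the autocorrelation of a per-frame signal.

## Problem sizes

Default runs were sized for a single CPU: 10⁵ histories per Monte Carlo
energy (statistical spread of R_p ≈ 0.02 cm, well below the 2–3% bands of
interest), 200 × 200 dose cells, 161 px phantom slices and 180–360
projection angles. All are parameters.

## Known limitations

- No delta-ray transport: hard-collision energy is deposited at the
  interaction point, slightly sharpening the lateral penumbra.
- The general Sternheimer parameterisation leaves a ~1.5% high bias in
  S_col near 10 MeV, so CSDA ranges run ~1.5% short of reference tables.
- The photon model omits pair production and coherent scattering; it is a
  qualitative stand-in, adequate only for the "no finite range" contrast
  with electron beams.
- The refraction correction is a user-supplied scale factor, not derived
  from the container optics.
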