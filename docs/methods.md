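# Methods

This note documents the models, numerical choices and limitations behind
`drslut`. The package processes multi-distance diffuse reflectance spectra
through an empirical lookup-table (LUT) inverse model and maps the fitted
optical properties to sampling depth; a diffusion-theory synthetic
laboratory replaces all physical measurements.

## Spectral processing

Raw counts are converted to absolute diffuse reflectance against a 20 %
reflectance standard, R(λ) = (I_sample − I_bg)/(I_std − I_bg) × R_std, with
R_std as a fraction (0.20), so that measuring the standard itself returns
its nominal reflectance. (The alternative convention that *divides* by the
standard's reflectance level — sometimes written ×100/R_std — would map the
standard to 5.0 and is not an absolute reflectance; both forms are noted
here, the physically consistent one is implemented.) All processing happens
on a common 450–900 nm grid at 1-nm spacing; the emulated spectrograph has
~2.1-nm optical resolution ((667 nm / 2048 px) × 6.5 px), so 1 nm is mild
oversampling. SNR is an amplitude ratio, 20·log₁₀(mean signal / sd of
background), since instrument conventions vary. Reflectance is a
dimensionless fraction internally; percent appears only at I/O.

## Synthetic laboratory

**Forward model.** Steady-state diffusion approximation for a semi-infinite
homogeneous medium: an isotropic point source at depth z₀ = 1/(μa+μs′) and
its negative image across an extrapolated boundary at z = −2AD, with the
internal-reflection parameter A evaluated for a relative refractive index of
1.4 (Groenhuis polynomial). Radial remittance at the source–detector
separation is scaled by the detector-fiber collection area (400-µm core) to
give a dimensionless reflectance fraction. An independent numerical
Hankel-transform solution of the same boundary problem verifies the closed
form to 1e-6 relative in the tests. The diffusion approximation is known to
be inaccurate in the sub-diffuse regime (short SDS, high absorption); this
is acceptable here because the same model generates calibration and test
data, keeping the inversion well-posed — accuracy claims concern the
processing chain, not radiative transport fidelity.

**Liftoff (black-layer) model.** A slab of phantom liquid bounded below by a
perfectly absorbing plane is solved with an image-source series between the
extrapolated top boundary and a zero-fluence plane at the slab bottom
(truncated at ±12 image pairs; converges to machine precision for 0–3 mm
slabs). For media thinner than one transport length the effective source
depth is capped at 0.75 × thickness so the model stays smooth, positive and
monotone in thickness; a cumulative-maximum guard removes series ripple at
the 1e-12 level (and up to ~1 % in the thin-slab transition region of
weakly scattering media, where the diffusion slab is at the edge of its
validity). In a weakly absorbing medium photons visit depths well beyond
3 mm, so no finite liftoff reaches the semi-infinite value there; the
convergence property (slab → semi-infinite within 2 % at 3 mm) holds — and
is tested — where absorption confines the sampled volume (μa ≳ 4 cm⁻¹ at
the short channel).

**Phantom designs.** Calibration: 5 × 3 recipes with μs′(630) ∈ {2.7, 3.8,
5.4, 7.6, 10.9} cm⁻¹ and absorber levels {none, peak 3.0, peak 10} cm⁻¹
near 632 nm. The wavelength dependence of scattering uses the power-law
exponent B = 0.78 obtained by least-squares fitting the Mie μs′(λ) curve of
1.00-µm polystyrene spheres in water over 450–900 nm, so the recipes span
μs′ ≈ 2–15 cm⁻¹ across the band and the power-law constraint model is
exactly representable. Validation: 3 × 3 recipes with μs′(630) ∈ {5.2, 8.5,
13.5} cm⁻¹ and bovine-hemoglobin levels with peak μa ∈ {1.8, 3.6, 8.1} cm⁻¹
built from the bundled extinction basis (oxygenated stock at 20 mg/mL; the
volume fraction C is set so the peak over the band matches the target).
Mie quantities come from a Bohren–Huffman-style series (logarithmic-
derivative downward recurrence, Wiscombe truncation n_max = x + 4x^⅓ + 2)
with pinned refractive-index dispersions (one-term Sellmeier for
polystyrene, four-term Cauchy for water).

**Extinction basis.** No hemoglobin compilation is bundled with any
dependency, so the package ships a synthetic oxy/deoxyhemoglobin basis
(`data/hb_extinction_synthetic.csv`): sums of Lorentzian Soret tails,
Gaussian visible bands and smooth NIR terms, expressed in cm⁻¹ per (mg/mL)
(molar values converted with MW 64,500 g/mol and the natural-log
convention), with amplitudes anchored to standard compilation values and
the two oxyhemoglobin Q-band maxima landing exactly at 542 and 576 nm on
the 1-nm grid. The NIR magnitudes matter: they anchor the absorber
concentration in the high-SNR 650–900 nm region and materially improve the
identifiability of C and THC at long SDS. The teal-ink stock spectrum is
likewise a pinned smooth synthetic curve peaking at 632 nm (50 cm⁻¹).

**Noise model.** Detector noise is additive, white and Gaussian per
detector pixel. Per channel, the noise magnitude is set so the *dimmest*
spectrum of the acquired set has an amplitude SNR of exactly 15 dB — the
floor interpretation of "at least 15 dB" with integration times tuned per
channel. Binning the 0.326-nm-pitch pixels to the 1-nm analysis grid
averages ~3.07 pixels (noise ×1/√3.07), and each recorded measurement is
the average of five acquisitions (×1/√5). A Cramér–Rao analysis was
decisive for this reading: with noise referenced to each spectrum's own
mean at 15 dB, the information bound alone puts the mean μs′ recovery error
at the 4-mm channel at 6 %, which would make the published-level accuracies
unreachable by *any* estimator; the floor reading is the one consistent
with the accuracy the experimental method demonstrably achieves.
Reflectance spectra are clipped at zero after noise addition (measured
effect on recovery: < 0.5 points at these noise levels).

## Lookup tables

Pooling (μs′(λᵢ), μa(λᵢ), R(λᵢ)) across the 15 calibration phantoms gives
~6,800 scattered points along 15 trajectories. The default build fits a
smooth regression surface to log R rather than interpolating the scatter
exactly: a stiff baseline polynomial in the diffusion-natural coordinates
(log μs′, μeff·ρ) (degrees 2 × 3) plus a bivariate polynomial residual in
(μs′, √μa) of total degree 8 whose ridge penalty (∝ squared total order) is
chosen by generalized cross-validation, followed by four Gauss–Newton
maximum-likelihood steps in linear reflectance space. The design follows
three measurements on the synthetic chain:

- exact interpolation (triangulation) transmits per-point noise into
  surface ripples; the single-distance inversion at 3–4 mm is nearly
  degenerate along an iso-attenuation valley, and ~1 % ripples displace the
  fitted parameters by 10–60 %;
- weighted least squares on log R (weights ∝ R/σ, capped at the 90th
  percentile) is variance-optimal to first order but biased by −σ²/2R² in
  dark regions; the Gauss–Newton refinement in linear space removes this;
- √μa as a coordinate absorbs the μeff ∝ √μa square-root behaviour near
  zero absorption that a polynomial in μa cannot capture.

A triangulation-based Clough–Tocher interpolating build (log-space, convex-
hull nearest fill) remains available as `method="interpolate"` and is exact
at the pooled points.

The LUT object materialises the regular node grid over μs′ ∈ [4, 12] ×
μa ∈ [0, 8] cm⁻¹ (0.1 cm⁻¹ default spacing) with convex-hull extrapolation
flags. The public `evaluate` is bilinear on this grid with out-of-domain
queries clamped to the boundary and flagged. The inverse model instead
evaluates the smooth surface (`smooth=True`); queries beyond the
calibration support (the validation design deliberately includes phantoms
with μs′ up to ~19 cm⁻¹ at short wavelengths) are continued along the shape
of the diffusion-dipole reference, offset-matched at the support boundary —
the level stays data-driven, only the extrapolation direction follows the
reference. With the diffusion surrogate this continuation is exact by
construction, so validation errors for out-of-support phantoms probe the
chain, not extrapolation-model error; with real instrument data it is a
physically motivated extrapolation whose error grows with distance from the
support. Hard clamping (with or without a clamp-distance penalty) was
measured to bias those phantoms by 40–56 % and was rejected.

Persistence is HDF5 (one group per SDS, format-versioned, JSON metadata
block including the calibration-set hash), with a `musp,mua,R` CSV export.

## Inverse model

Bounded damped least squares: `scipy.optimize.least_squares`
(trust-region-reflective) minimising Σ(R̂(λ) − R(λ))² under box bounds —
phantom mode μs′(630) ∈ [2, 15] cm⁻¹, B ∈ [0, 4], C ∈ [0, 1]; tissue mode
adds THC ∈ [0, 150] mg/mL, StO₂ ∈ [0, 1], r_vess ∈ [0, 100] µm. Finite
differences on the smooth LUT surface use a relative step of 1e-4;
tolerances 1e-12; the total function-evaluation budget is capped at 10⁴.

Because the long-SDS cost surface carries a shallow, elongated valley with
occasional distant near-tie minima, refinement is seeded from a
deterministic coarse lattice over the bounds box (phantom: 22 × 12 × 14
points in μs′(630) × B × C with C geometric; tissue: a 12 × 6 × 8 × 6
lattice with r_vess started at 5 µm) and the best five lattice candidates
are each polished, lowest final cost winning. Starts are deliberately
restricted to lattice candidates: free interior starts (e.g. bound
midpoints) were measured to locate spurious lower-cost basins on
near-degenerate inputs, doubling recovery errors. A user-supplied initial
guess adds one start; for well-conditioned inputs the result is independent
of it.

χ² is defined as 100 × Σ(R̂−R)²/ΣR² — scale-free, so the 5 % rejection gate
means the same for bright and dim channels. Percent-error curves are mean
absolute relative errors over wavelength; for μa, wavelengths with expected
μa < 0.05 cm⁻¹ are excluded (relative error is meaningless where the truth
passes through zero). r_vess is fitted in tissue mode but is weakly
identifiable; it is reported, not interpreted.

At the study conditions the chain recovers, across random seeds, the
validation set's μs′ with a worst-channel mean error of roughly 4–8 % and
μa within roughly 2–7 %; the Cramér–Rao floor of the surrogate at these
conditions is ≈3 % for μs′ with per-phantom floors up to 10 %, so
single-realization worst-channel values above 5 % occur for some seeds.
This is the honest operating point, not a tuning target.

## Sampling depth

The half-plateau criterion: the plateau is the mean reflectance over the
five deepest increments (2.80–3.00 mm); the sampling depth is the smallest
50-µm grid distance with R(z) ≥ 0.5 × plateau, reported on the 50-µm grid
without sub-increment interpolation. An alternative "maximum sensitivity"
criterion (the increment with the steepest rise) is available for
comparison. Liftoff simulations are noiseless — the criterion is invariant
to positive rescaling, and the monotonicity contract of the curves is then
exact.

Depth tables pool (μs′(λ), μa(λ), D(λ)) across the calibration recipes and
interpolate linearly (triangulation, nearest fill outside the hull, flags)
onto the same grid as the LUTs. Expected behaviour — depth increasing with
SDS, non-increasing in either optical property within one 50-µm increment —
holds on the absorbing part of the domain (μa ≳ 1.5 cm⁻¹). In the
near-transparent corner the liftoff curves do not plateau within the 3-mm
travel, the half-plateau depth is not a meaningful summary there, and the
surrogate's values in that corner (driven by the thin-slab source cap)
should not be over-interpreted. Depths range from ~0.7 mm (0.75-mm SDS,
high properties) to ~2.8 mm (4.00-mm SDS, low properties).

## Synthetic tissue study

The end-to-end pipeline emulates a two-group (normal/tumor) murine study:
per SDS channel, each synthetic animal gets effective one-layer parameters
drawn around per-channel anchors — scattering decreasing with SDS (≈11 →
8.5 cm⁻¹ at 630 nm), THC increasing (≈1.4 → 6.8 mg/mL), StO₂ flat for
normal tissue (~55 %) and declining with SDS for tumors (~50 → 22 %),
vessel radius ~7.5 µm, 8 % log-normal-ish jitter. The per-channel variation
encodes the volume-averaging of a one-layer model over skin and tumor, not
layer-resolved physiology. Group summaries (mean ± SD of μs′(630), THC,
StO₂ and depth at 542 nm) include only χ²-accepted fits; discarded fits are
counted. Significance testing is deliberately out of scope; per-sample
values are exported for any statistics package.

## Problem sizes and determinism

The default study uses the full 450–900 nm 1-nm grid, all four SDS
channels, 15 + 9 phantoms, and nine samples per tissue group; the test
suite exercises the same code paths with two-to-nine samples and shares one
session-scoped build of the noisy calibration/validation chain. All
generators draw from `numpy.random.default_rng` seeded per (seed, channel),
so every artifact is bit-reproducible under a fixed seed.

## Known limitations

- The diffusion surrogate under-represents sub-diffuse transport at the
  0.75-mm channel and high absorption; real probes will show different
  absolute reflectance levels and somewhat different depth magnitudes.
- Passing validation here demonstrates the correctness and conditioning of
  the processing chain under the stated noise model — not calibration
  transfer, specular-contact artifacts, probe pressure effects, or any
  chromophore beyond hemoglobin (melanin, water and lipids are excluded by
  design, matching albino-mouse tissue in the visible band).
- The extinction basis is synthetic; magnitudes are compilation-anchored
  but not a metrological reference. Absolute THC values inherit its scale.
- Sampling depth is reported as a single summary value; the collected
  signal actually originates from a broad depth distribution.
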