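# drslut

Lookup-table processing of multi-distance diffuse reflectance spectra:
extraction of tissue optical properties, hemoglobin physiology, and
wavelength-dependent sampling depth.

## The problem

Contact fiber-probe diffuse reflectance spectroscopy (DRS) records broadband
reflectance (450–900 nm) at several source–detector separations (SDS; here
0.75, 2.00, 3.00 and 4.00 mm) to interrogate increasing depths of tissue —
for example the skin layers over a subcutaneous murine tumor. Two questions
must be answered to turn raw spectra into physiology:

1. **What are the optical properties?** For each SDS channel an empirical
   lookup table (LUT) R(μs′, μa) is built from liquid calibration phantoms of
   known reduced scattering μs′ and absorption μa (covering μs′ ∈ [4, 12] cm⁻¹,
   μa ∈ [0, 8] cm⁻¹). Measured spectra are then inverted by bounded damped
   least squares under physically constrained models:

   - scattering: μs′(λ) = μs′(λ₀) (λ/λ₀)^(−B), λ₀ = 630 nm,
   - phantom absorption: μa(λ) = C · μa,stock(λ),
   - tissue absorption: μa,i(λ) = THC [α εHbO₂(λ) + (1−α) εHb(λ)], corrected
     for pigment packaging: μa,f = μa,i · (1 − e^(−2 μa,bl r_vess)) / (2 μa,bl r_vess),
     where μa,bl is whole-blood absorption at 150 mg/mL.

   Fits with χ² = 100·Σ(R̂−R)²/ΣR² above 5 % are discarded.

2. **From what depth do the photons come?** Raising the probe above a highly
   absorbing black layer in 50-µm steps yields reflectance-versus-distance
   curves; the sampling depth at each wavelength is the distance at which the
   collected signal reaches 50 % of its plateau. Pooled across phantoms this
   gives per-SDS depth surfaces D(μs′, μa), evaluated at the 542-nm
   oxyhemoglobin Q-band where sampling is shallowest.

All laboratory measurements are emulated by a diffusion-theory synthetic
laboratory (extrapolated-boundary dipole for semi-infinite media; an
image-source slab over an absorbing plane for liftoff), with per-channel
detector noise at a 15-dB amplitude SNR floor and five-spectrum averaging.
The package therefore validates the *processing chain* end to end, not any
particular instrument.

## Worked example

Build a LUT for the 2.00-mm channel from the 5×3 calibration phantom set and
invert one bovine-hemoglobin validation phantom (μs′(630) = 8.5 cm⁻¹, peak
μa = 3.6 cm⁻¹), everything at the 15-dB noise floor:

```python
import numpy as np
import drslut as d
from drslut.phantoms import (forward_reflectance, channel_noise_sigma,
                             PIXELS_PER_NM, hb_stock_mua)

cal = d.generate_calibration_set(seed=7, sds_mm=(2.0,))
clean = [forward_reflectance(r.musp, r.mua, 2.0) for r in cal.recipes]
sigma = channel_noise_sigma(clean, 15.0) / np.sqrt(5 * PIXELS_PER_NM)
lut = d.build_lut([(r, cal.spectrum(r.label, 2.0)) for r in cal.recipes],
                  2.0, noise_sigma=sigma)

val = d.generate_validation_set(seed=8, sds_mm=(2.0,))
recipe = val.recipes[4]
stock = hb_stock_mua(recipe.wavelengths_nm)
result = d.fit(val.spectrum(recipe.label, 2.0), "phantom", lut,
               stock_mua=stock)
```

printing

```
musp0 = 8.70 1/cm   (true 8.5)
B     = 0.900
C     = 0.0377  (true 0.0389)
chi2  = 0.102 %   accepted = True
```

i.e. the scattering scale is recovered within ~2 %, the absorber volume
fraction within ~3 %, and the fit passes the 5 % χ² gate.

The same workflows are available from the shell:

```
drslut simulate-phantoms --kind calibration --seed 0 --out phantoms/
drslut build-lut --seed 0 --out luts.h5
drslut validate --lut luts.h5 --report report.csv
drslut build-depth --out depth.h5
drslut fit --mode tissue --lut luts.h5 --spectrum s.csv --out fit.json
drslut report --out study/
```

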