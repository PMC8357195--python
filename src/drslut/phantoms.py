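"""Synthetic phantom laboratory: forward model, phantom sets, liftoff, noise.

This module stands in for the wet lab.  A steady-state diffusion
approximation (extrapolated-boundary dipole for a semi-infinite medium;
image-source series for a slab over a perfectly absorbing plane) generates
the reflectance that a probe would record from liquid phantoms of known
optical properties.  Everything downstream — LUT construction, inverse
fitting, sampling-depth surfaces — therefore validates the processing
chain, not any particular instrument response.

Phantom designs:

* calibration — 5 x 3: reduced scattering 2.7 / 3.8 / 5.4 / 7.6 / 10.9 1/cm
  at 630 nm (polystyrene microspheres; the power-law exponent is the Mie
  best fit for 1.00-µm spheres in water) crossed with ink levels none /
  peak 3.0 / peak 10 1/cm near 632 nm;
* validation — 3 x 3: scattering 5.2 / 8.5 / 13.5 1/cm at 630 nm crossed
  with bovine-hemoglobin levels peaking at 1.8 / 3.6 / 8.1 1/cm.

Noise model: each recorded spectrum is the average of ``n_averages``
acquisitions.  Detector noise is additive white Gaussian per detector
pixel, with a per-SDS-channel magnitude chosen so the dimmest spectrum of
the acquired set still meets the amplitude SNR floor (default 15 dB) —
integration times are tuned per channel, so the floor binds on the worst
measurement.  Binning the 2048-pixel, 667-nm-range detector readout onto
the 1-nm analysis grid averages ~3.07 pixels per sample.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .mie import MicrosphereSpec, musp_wavelength_exponent
from .optics import (
    ExtinctionTable,
    ScatteringModel,
    TissueAbsorberModel,
    hemoglobin_mua,
    load_extinction_table,
    load_ink_stock,
    pigment_packaging_factor,
    whole_blood_mua,
)
from .spectral import WAVELENGTH_GRID_NM, Spectrum

__all__ = [
    "CALIBRATION_MUSP0",
    "VALIDATION_MUSP0",
    "CALIBRATION_INK_PEAKS",
    "VALIDATION_HB_PEAKS",
    "PIXELS_PER_NM",
    "PhantomRecipe",
    "PhantomSet",
    "LiftoffCurve",
    "ForwardModelError",
    "forward_reflectance",
    "slab_reflectance",
    "generate_calibration_set",
    "generate_validation_set",
    "simulate_liftoff",
    "synthesize_tissue_spectrum",
    "add_noise",
    "scattering_exponent_1um_polystyrene",
]

CALIBRATION_MUSP0 = (2.7, 3.8, 5.4, 7.6, 10.9)
VALIDATION_MUSP0 = (5.2, 8.5, 13.5)
CALIBRATION_INK_PEAKS = (0.0, 3.0, 10.0)
VALIDATION_HB_PEAKS = (1.8, 3.6, 8.1)

#: Detector pixels per nm: 2048-element array imaging a 667-nm range.
PIXELS_PER_NM = 2048.0 / 667.0

#: Internal-reflection parameter for the extrapolated boundary, n_rel = 1.4.
_N_REL = 1.4

#: Effective collection area (cm^2) of a 400-µm-core detector fiber; turns
#: the diffusion model's radiance per area into a dimensionless fraction.
_COLLECTION_AREA_CM2 = np.pi * 0.02**2

_HB_STOCK_MG_PER_ML = 20.0  # oxygenated bovine-Hb stock concentration


class ForwardModelError(ValueError):
    """Non-physical input to the diffusion forward model."""


def _boundary_params(musp, mua):
    mutp = mua + musp
    z0 = 1.0 / mutp
    diff = 1.0 / (3.0 * mutp)
    rd = -1.440 * _N_REL**-2 + 0.710 / _N_REL + 0.668 + 0.0636 * _N_REL
    a_int = (1.0 + rd) / (1.0 - rd)
    zb = 2.0 * a_int * diff
    mueff = np.sqrt(3.0 * mua * mutp)
    return z0, zb, mueff


def _dipole_term(h, mueff, rho_cm):
    r = np.sqrt(h**2 + rho_cm**2)
    return h * (mueff + 1.0 / r) * np.exp(-mueff * r) / r**2


def forward_reflectance(musp, mua, sds_mm) -> np.ndarray:
    """Semi-infinite diffuse reflectance fraction at one radial distance.

    Extrapolated-boundary dipole solution of the steady-state diffusion
    equation, scaled by the detector-fiber collection area.  ``musp`` and
    ``mua`` in 1/cm (broadcastable arrays), ``sds_mm`` in mm.  Strictly
    decreasing in ``mua`` and in distance; positive and finite.
    """
    musp = np.asarray(musp, dtype=float)
    mua = np.asarray(mua, dtype=float)
    if np.any(musp <= 0):
        raise ForwardModelError("diffusion model requires musp > 0")
    if np.any(mua < 0):
        raise ForwardModelError("mua must be non-negative")
    if sds_mm <= 0:
        raise ForwardModelError("source-detector separation must be positive")
    rho = sds_mm / 10.0
    z0, zb, mueff = _boundary_params(musp, mua)
    flux = _dipole_term(z0, mueff, rho) + _dipole_term(z0 + 2.0 * zb, mueff, rho)
    return flux / (4.0 * np.pi) * _COLLECTION_AREA_CM2


def slab_reflectance(musp, mua, sds_mm, thickness_mm, n_images: int = 12) -> np.ndarray:
    """Reflectance from a slab bounded below by a perfectly absorbing plane.

    Image-source series between the extrapolated top boundary and a
    Dirichlet (zero-fluence) plane at the slab bottom: photons reaching the
    black layer are lost.  Converges to :func:`forward_reflectance` as the
    thickness grows.  Returns 0 when the slab is thinner than the effective
    source depth (the isotropic source would sit on the absorbing plane).
    """
    musp = np.asarray(musp, dtype=float)
    mua = np.asarray(mua, dtype=float)
    if np.any(musp <= 0):
        raise ForwardModelError("diffusion model requires musp > 0")
    if thickness_mm < 0:
        raise ForwardModelError("slab thickness must be non-negative")
    rho = sds_mm / 10.0
    length = thickness_mm / 10.0
    z0, zb, mueff = _boundary_params(musp, mua)
    # media thinner than one transport length: keep the isotropic source
    # inside the slab so the model stays smooth and positive
    z0_eff = np.minimum(z0, 0.75 * length)
    period = length + zb
    flux = np.zeros(np.broadcast(musp, mua).shape, dtype=float)
    for m in range(-n_images, n_images + 1):
        flux += _dipole_term(z0_eff + 2.0 * m * period, mueff, rho)
        flux -= _dipole_term(-2.0 * zb - z0_eff + 2.0 * m * period, mueff, rho)
    out = np.clip(flux / (4.0 * np.pi) * _COLLECTION_AREA_CM2, 0.0, None)
    return np.where(length <= 0.0, 0.0, out)


@dataclass(frozen=True, eq=False)
class PhantomRecipe:
    """A liquid phantom with known optical-property trajectories."""

    label: str
    target_musp0_at_630: float
    absorber_kind: str  # none | ink | bovine_hb
    absorber_peak_mua: float
    wavelengths_nm: np.ndarray
    musp: np.ndarray
    mua: np.ndarray

    def __post_init__(self) -> None:
        for name in ("wavelengths_nm", "musp", "mua"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if self.absorber_kind not in ("none", "ink", "bovine_hb"):
            raise ValueError(f"unknown absorber kind {self.absorber_kind!r}")
        if np.any(self.musp <= 0) or np.any(self.mua < 0):
            raise ValueError("non-physical optical-property trajectory")


@dataclass(frozen=True)
class PhantomSet:
    """Recipes plus per-(recipe, SDS) measured reflectance spectra."""

    recipes: tuple[PhantomRecipe, ...]
    sds_mm: tuple[float, ...]
    spectra: dict  # (recipe label, sds) -> Spectrum
    seed: int | None
    snr_db: float | None

    def spectrum(self, label: str, sds: float) -> Spectrum:
        return self.spectra[(label, sds)]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for r in self.recipes:
            h.update(r.label.encode())
            h.update(np.ascontiguousarray(r.musp).tobytes())
            h.update(np.ascontiguousarray(r.mua).tobytes())
        for key in sorted(self.spectra, key=str):
            h.update(np.ascontiguousarray(self.spectra[key].values).tobytes())
        return h.hexdigest()[:16]


_B_PS_CACHE: dict[float, float] = {}


def scattering_exponent_1um_polystyrene() -> float:
    """Power-law exponent fitted to the Mie mu_s' curve of 1.00-µm spheres."""
    if 1.0 not in _B_PS_CACHE:
        spec = MicrosphereSpec(diameter_um=1.00, volume_fraction=0.01)
        _B_PS_CACHE[1.0] = musp_wavelength_exponent(
            spec, np.arange(450.0, 901.0, 10.0)
        )
    return _B_PS_CACHE[1.0]


def _musp_curve(m0: float, wl: np.ndarray) -> np.ndarray:
    return m0 * (wl / 630.0) ** (-scattering_exponent_1um_polystyrene())


def add_noise(s: Spectrum, target_snr_db: float, seed: int) -> Spectrum:
    """Add zero-mean Gaussian noise at an amplitude SNR relative to the mean.

    ``sigma = mean(values) / 10^(snr/20)``.  Reflectance-role spectra are
    clipped at zero afterwards to preserve their non-negativity contract.
    """
    if not np.isfinite(target_snr_db):
        return s
    if target_snr_db <= 0:
        raise ValueError("target SNR must be positive (dB)")
    rng = np.random.default_rng(seed)
    sigma = float(np.mean(s.values)) / 10.0 ** (target_snr_db / 20.0)
    noisy = s.values + rng.normal(0.0, abs(sigma), s.values.shape)
    if s.role == "reflectance":
        noisy = np.clip(noisy, 0.0, None)
    return s.with_values(noisy)


def channel_noise_sigma(clean_values: list[np.ndarray], snr_db: float) -> float:
    """Per-channel noise level: the dimmest spectrum meets the SNR floor."""
    return min(float(np.mean(v)) for v in clean_values) / 10.0 ** (snr_db / 20.0)


def _acquire(clean: np.ndarray, sigma_channel: float, n_averages: int,
             rng: np.random.Generator) -> np.ndarray:
    """Average of n noisy pixel-binned acquisitions of one clean spectrum."""
    sigma = sigma_channel / np.sqrt(PIXELS_PER_NM)
    acq = clean[None, :] + rng.normal(0.0, sigma, (n_averages, clean.size))
    return np.clip(acq.mean(axis=0), 0.0, None)


def _ink_recipes(wl: np.ndarray) -> list[PhantomRecipe]:
    ink_wl, ink_mua = load_ink_stock()
    ink = np.interp(wl, ink_wl, ink_mua)
    ink_shape = ink / ink.max()
    recipes = []
    for m0 in CALIBRATION_MUSP0:
        for pk in CALIBRATION_INK_PEAKS:
            kind = "none" if pk == 0 else "ink"
            recipes.append(
                PhantomRecipe(
                    label=f"cal-m{m0}-a{pk}",
                    target_musp0_at_630=m0,
                    absorber_kind=kind,
                    absorber_peak_mua=pk,
                    wavelengths_nm=wl,
                    musp=_musp_curve(m0, wl),
                    mua=pk * ink_shape,
                )
            )
    return recipes


def _hb_recipes(wl: np.ndarray, ext: ExtinctionTable) -> list[PhantomRecipe]:
    eo, _ = ext.interp(wl)
    stock = _HB_STOCK_MG_PER_ML * eo  # fully oxygenated stock
    recipes = []
    for m0 in VALIDATION_MUSP0:
        for pk in VALIDATION_HB_PEAKS:
            c = pk / stock.max()
            recipes.append(
                PhantomRecipe(
                    label=f"val-m{m0}-a{pk}",
                    target_musp0_at_630=m0,
                    absorber_kind="bovine_hb",
                    absorber_peak_mua=pk,
                    wavelengths_nm=wl,
                    musp=_musp_curve(m0, wl),
                    mua=c * stock,
                )
            )
    return recipes


def hb_stock_mua(wavelengths_nm=WAVELENGTH_GRID_NM,
                 ext: ExtinctionTable | None = None) -> np.ndarray:
    """Absorption of the oxygenated bovine-Hb stock solution (20 mg/mL)."""
    ext = ext or load_extinction_table()
    eo, _ = ext.interp(wavelengths_nm)
    return _HB_STOCK_MG_PER_ML * eo


def _measure_set(recipes, sds_mm, seed, snr_db, n_averages):
    spectra = {}
    for ch, sds in enumerate(sds_mm):
        clean = [forward_reflectance(r.musp, r.mua, sds) for r in recipes]
        if snr_db is None:
            acquired = clean
        else:
            rng = np.random.default_rng([0 if seed is None else seed, ch])
            sigma = channel_noise_sigma(clean, snr_db)
            acquired = [_acquire(c, sigma, n_averages, rng) for c in clean]
        for r, vals in zip(recipes, acquired):
            spectra[(r.label, sds)] = Spectrum(
                r.wavelengths_nm, vals, "reflectance", sds
            )
    return spectra


def generate_calibration_set(
    seed: int | None = 0,
    sds_mm: tuple[float, ...] = (0.75, 2.00, 3.00, 4.00),
    snr_db: float | None = 15.0,
    n_averages: int = 5,
    wavelengths_nm: np.ndarray = WAVELENGTH_GRID_NM,
) -> PhantomSet:
    """The 5 x 3 microsphere/ink calibration set with measured spectra.

    Pass ``snr_db=None`` for noiseless spectra.
    """
    recipes = _ink_recipes(np.asarray(wavelengths_nm, float))
    spectra = _measure_set(recipes, sds_mm, seed, snr_db, n_averages)
    return PhantomSet(tuple(recipes), tuple(sds_mm), spectra, seed, snr_db)


def generate_validation_set(
    seed: int | None = 1,
    sds_mm: tuple[float, ...] = (0.75, 2.00, 3.00, 4.00),
    snr_db: float | None = 15.0,
    n_averages: int = 5,
    wavelengths_nm: np.ndarray = WAVELENGTH_GRID_NM,
    ext: ExtinctionTable | None = None,
) -> PhantomSet:
    """The 3 x 3 bovine-hemoglobin validation set with measured spectra."""
    ext = ext or load_extinction_table()
    recipes = _hb_recipes(np.asarray(wavelengths_nm, float), ext)
    spectra = _measure_set(recipes, sds_mm, seed, snr_db, n_averages)
    return PhantomSet(tuple(recipes), tuple(sds_mm), spectra, seed, snr_db)


@dataclass(frozen=True, eq=False)
class LiftoffCurve:
    """Reflectance versus probe height above an absorbing boundary."""

    sds_mm: float
    wavelengths_nm: np.ndarray
    distances_mm: np.ndarray  # 0 to 3 mm in 50-µm steps
    reflectance: np.ndarray  # (n_distances, n_wavelengths)

    def __post_init__(self) -> None:
        for name in ("wavelengths_nm", "distances_mm", "reflectance"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        expected = np.arange(0.0, 3.0 + 1e-9, 0.05)
        if self.distances_mm.shape != expected.shape or not np.allclose(
            self.distances_mm, expected
        ):
            raise ValueError("distance grid must be 0 to 3 mm in 50-um steps")
        if self.reflectance.shape != (
            self.distances_mm.size,
            self.wavelengths_nm.size,
        ):
            raise ValueError("reflectance must be (n_distances, n_wavelengths)")
        if np.any(self.reflectance < 0):
            raise ValueError("reflectance must be non-negative")
        if np.any(np.diff(self.reflectance, axis=0) < -1e-12):
            raise ValueError("reflectance must be non-decreasing with distance")


LIFTOFF_DISTANCES_MM = np.arange(0.0, 3.0 + 1e-9, 0.05)


def simulate_liftoff(recipe: PhantomRecipe, sds_mm: float) -> LiftoffCurve:
    """Liftoff experiment: raise the probe over a black layer in 50-µm steps.

    Noiseless by construction so the curves satisfy the monotonicity
    contract exactly; the depth criterion downstream is scale-invariant.
    """
    refl = np.empty((LIFTOFF_DISTANCES_MM.size, recipe.wavelengths_nm.size))
    for i, z in enumerate(LIFTOFF_DISTANCES_MM):
        refl[i] = slab_reflectance(recipe.musp, recipe.mua, sds_mm, z)
    refl = np.maximum.accumulate(refl, axis=0)  # guard 1e-16 series ripple
    return LiftoffCurve(sds_mm, recipe.wavelengths_nm, LIFTOFF_DISTANCES_MM, refl)


def synthesize_tissue_spectrum(
    scat: ScatteringModel,
    absorber: TissueAbsorberModel,
    sds_mm: float,
    seed: int | None = None,
    snr_db: float | None = 15.0,
    n_averages: int = 5,
    wavelengths_nm: np.ndarray = WAVELENGTH_GRID_NM,
    ext: ExtinctionTable | None = None,
) -> Spectrum:
    """One-layer tissue spectrum: power-law scattering + packaged Hb absorption."""
    ext = ext or load_extinction_table()
    wl = np.asarray(wavelengths_nm, float)
    musp = scat.musp0 * (wl / scat.lambda0_nm) ** (-scat.b)
    mua_i = hemoglobin_mua(absorber, ext, wl)
    mua_bl = whole_blood_mua(absorber.alpha, ext, wl)
    mua_f = mua_i * pigment_packaging_factor(mua_bl, absorber.rvess_um)
    clean = forward_reflectance(musp, mua_f, sds_mm)
    if snr_db is None:
        return Spectrum(wl, clean, "reflectance", sds_mm)
    rng = np.random.default_rng(seed)
    sigma = float(np.mean(clean)) / 10.0 ** (snr_db / 20.0)
    vals = _acquire(clean, sigma, n_averages, rng)
    return Spectrum(wl, vals, "reflectance", sds_mm)


def tissue_mua(absorber: TissueAbsorberModel, wavelengths_nm,
               ext: ExtinctionTable | None = None) -> np.ndarray:
    """Final (packaged) tissue absorption coefficient mu_a,f(lambda)."""
    ext = ext or load_extinction_table()
    mua_i = hemoglobin_mua(absorber, ext, wavelengths_nm)
    mua_bl = whole_blood_mua(absorber.alpha, ext, wavelengths_nm)
    return mua_i * pigment_packaging_factor(mua_bl, absorber.rvess_um)
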