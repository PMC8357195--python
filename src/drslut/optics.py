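"""Chromophore and scattering physics used as fit constraints.

Two constraint families reduce a full spectrum to a handful of parameters:

* scattering — a power law ``mu_s'(lambda) = mu_s'(lambda0) (lambda/lambda0)^-B``
  anchored at 630 nm, with scattering exponent ``B`` inversely related to
  scatterer size;
* absorption — either a diluted stock absorber (``mu_a = C mu_a,stock``,
  phantom work) or hemoglobin in tissue,
  ``mu_a,i = THC [alpha eps_HbO2 + (1-alpha) eps_Hb]``, corrected for
  pigment packaging: hemoglobin confined to vessels of radius ``r_vess``
  absorbs less at strong bands than the same amount distributed
  homogeneously, by the factor ``(1 - exp(-2 mu_a,bl r)) / (2 mu_a,bl r)``
  where ``mu_a,bl`` is whole-blood absorption at 150 mg/mL.

The bundled oxy/deoxyhemoglobin extinction basis is a synthetic band-sum
fixture (see ``data/hb_extinction_synthetic.csv``): magnitudes are anchored
to standard molar-extinction compilations (converted with MW 64,500 g/mol
and the natural-log convention) and the oxyhemoglobin Q-band maxima fall at
542 and 576 nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "WHOLE_BLOOD_HB_MG_PER_ML",
    "ScatteringModel",
    "PhantomAbsorberModel",
    "TissueAbsorberModel",
    "ExtinctionTable",
    "OpticsError",
    "musp_power_law",
    "phantom_mua",
    "hemoglobin_mua",
    "whole_blood_mua",
    "pigment_packaging_factor",
    "beer_lambert_mua",
    "qband_peaks",
    "load_extinction_table",
    "load_ink_stock",
]

#: Hemoglobin concentration of whole blood, mg/mL.
WHOLE_BLOOD_HB_MG_PER_ML = 150.0


class OpticsError(ValueError):
    """Invalid optical-model parameter or wavelength-coverage problem."""


@dataclass(frozen=True)
class ScatteringModel:
    """Power-law reduced scattering: ``musp0 (lambda/lambda0)^-B``."""

    musp0: float
    b: float
    lambda0_nm: float = 630.0

    def __post_init__(self) -> None:
        if self.musp0 <= 0:
            raise OpticsError("musp0 must be positive")
        if not (450.0 <= self.lambda0_nm <= 900.0):
            raise OpticsError("reference wavelength must lie in [450, 900] nm")


@dataclass(frozen=True, eq=False)
class PhantomAbsorberModel:
    """Diluted stock absorber: ``mu_a = C mu_a,stock``."""

    c: float
    stock_wavelengths_nm: np.ndarray
    stock_mua: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.stock_wavelengths_nm, dtype=float)
        mua = np.asarray(self.stock_mua, dtype=float)
        object.__setattr__(self, "stock_wavelengths_nm", wl)
        object.__setattr__(self, "stock_mua", mua)
        if not (0.0 <= self.c <= 1.0):
            raise OpticsError("volume fraction C must lie in [0, 1]")
        if np.any(mua < 0):
            raise OpticsError("stock absorption must be non-negative")


@dataclass(frozen=True)
class TissueAbsorberModel:
    """Hemoglobin absorber: total concentration, saturation, vessel radius.

    ``thc`` in mg/mL, ``alpha`` (StO2) as a fraction, ``rvess_um`` in µm.
    Bounds mirror physiology: THC cannot exceed whole blood, saturation is a
    fraction, and 100 µm far exceeds arteriole radii.
    """

    thc: float
    alpha: float
    rvess_um: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.thc <= WHOLE_BLOOD_HB_MG_PER_ML):
            raise OpticsError("THC must lie in [0, 150] mg/mL")
        if not (0.0 <= self.alpha <= 1.0):
            raise OpticsError("StO2 fraction must lie in [0, 1]")
        if not (0.0 <= self.rvess_um <= 100.0):
            raise OpticsError("vessel radius must lie in [0, 100] um")


@dataclass(frozen=True, eq=False)
class ExtinctionTable:
    """Oxy/deoxyhemoglobin absorption basis, cm^-1 per (mg/mL)."""

    wavelengths_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    whole_blood_hb_mg_per_ml: float = WHOLE_BLOOD_HB_MG_PER_ML

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        eo = np.asarray(self.eps_hbo2, dtype=float)
        eh = np.asarray(self.eps_hb, dtype=float)
        for name, arr in (("wavelengths", wl), ("eps_hbo2", eo), ("eps_hb", eh)):
            object.__setattr__(self, {"wavelengths": "wavelengths_nm",
                                      "eps_hbo2": "eps_hbo2",
                                      "eps_hb": "eps_hb"}[name], arr)
        if np.any(np.diff(wl) <= 0):
            raise OpticsError("extinction wavelengths must be ascending")
        if wl[0] > 450.0 or wl[-1] < 900.0:
            raise OpticsError("extinction table must cover 450-900 nm")
        if np.any(eo < 0) or np.any(eh < 0):
            raise OpticsError("extinction coefficients must be non-negative")

    def interp(self, wavelengths_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        wl = np.asarray(wavelengths_nm, dtype=float)
        if wl.min() < self.wavelengths_nm[0] or wl.max() > self.wavelengths_nm[-1]:
            raise OpticsError("requested wavelengths outside extinction table")
        return (
            np.interp(wl, self.wavelengths_nm, self.eps_hbo2),
            np.interp(wl, self.wavelengths_nm, self.eps_hb),
        )


def musp_power_law(m: ScatteringModel, wavelengths_nm) -> np.ndarray:
    """Reduced scattering mu_s'(lambda) in 1/cm from the power-law model."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.min() < 450.0 or wl.max() > 900.0:
        raise OpticsError("wavelengths must lie in [450, 900] nm")
    return m.musp0 * (wl / m.lambda0_nm) ** (-m.b)


def phantom_mua(a: PhantomAbsorberModel, wavelengths_nm) -> np.ndarray:
    """Absorption of a diluted stock: ``C mu_a,stock(lambda)``."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.min() < a.stock_wavelengths_nm[0] or wl.max() > a.stock_wavelengths_nm[-1]:
        raise OpticsError("stock spectrum does not cover requested wavelengths")
    return a.c * np.interp(wl, a.stock_wavelengths_nm, a.stock_mua)


def hemoglobin_mua(
    t: TissueAbsorberModel, ext: ExtinctionTable, wavelengths_nm
) -> np.ndarray:
    """Initial (unpackaged) tissue absorption from the hemoglobin basis."""
    eo, eh = ext.interp(wavelengths_nm)
    return t.thc * (t.alpha * eo + (1.0 - t.alpha) * eh)


def whole_blood_mua(alpha: float, ext: ExtinctionTable, wavelengths_nm) -> np.ndarray:
    """Whole-blood absorption at 150 mg/mL hemoglobin and saturation alpha."""
    eo, eh = ext.interp(wavelengths_nm)
    return ext.whole_blood_hb_mg_per_ml * (alpha * eo + (1.0 - alpha) * eh)


def pigment_packaging_factor(mua_bl, rvess_um) -> np.ndarray:
    """Vessel-confinement correction ``(1 - e^{-2x})/(2x)``, x = mu_a,bl r.

    ``mua_bl`` in 1/cm, ``rvess_um`` in µm (converted to cm internally).
    Continuous at x = 0 with value 1; strictly decreasing; in (0, 1].
    """
    mua_bl = np.asarray(mua_bl, dtype=float)
    if np.any(mua_bl < 0):
        raise OpticsError("whole-blood absorption must be non-negative")
    if np.any(np.asarray(rvess_um) < 0):
        raise OpticsError("vessel radius must be non-negative")
    two_x = 2.0 * mua_bl * (np.asarray(rvess_um, dtype=float) * 1e-4)
    out = np.ones_like(two_x, dtype=float)
    nz = two_x > 1e-12
    out[nz] = -np.expm1(-two_x[nz]) / two_x[nz]
    return out


def beer_lambert_mua(absorbance, pathlength_cm: float) -> np.ndarray:
    """Absorption coefficient from decadic absorbance: ``ln(10) A / L``."""
    if pathlength_cm <= 0:
        raise OpticsError("pathlength must be positive")
    absorbance = np.asarray(absorbance, dtype=float)
    if np.any(absorbance < 0):
        raise OpticsError("absorbance must be non-negative")
    return np.log(10.0) * absorbance / pathlength_cm


def qband_peaks(ext: ExtinctionTable) -> tuple[float, float]:
    """Locations (nm) of the two oxyhemoglobin Q-band maxima in 500-600 nm."""
    wl = ext.wavelengths_nm
    sel = (wl >= 500.0) & (wl <= 600.0)
    if np.max(np.diff(wl[sel])) > 2.0:
        raise OpticsError("extinction table too coarse in 500-600 nm")
    w = wl[sel]
    e = ext.eps_hbo2[sel]
    interior = np.arange(1, len(w) - 1)
    peaks = [w[i] for i in interior if e[i] > e[i - 1] and e[i] > e[i + 1]]
    if len(peaks) != 2:
        raise OpticsError(
            f"expected exactly two oxyhemoglobin maxima in 500-600 nm, found {len(peaks)}"
        )
    return float(peaks[0]), float(peaks[1])


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("drslut.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_extinction_table() -> ExtinctionTable:
    """Load the bundled synthetic hemoglobin extinction basis (450-900 nm)."""
    df = _read_packaged_csv("hb_extinction_synthetic.csv")
    return ExtinctionTable(
        df["wavelength_nm"].to_numpy(float),
        df["eps_hbo2"].to_numpy(float),
        df["eps_hb"].to_numpy(float),
    )


def load_ink_stock() -> tuple[np.ndarray, np.ndarray]:
    """Bundled synthetic teal-ink stock absorption, 1/cm, peaked near 632 nm."""
    df = _read_packaged_csv("teal_ink_synthetic.csv")
    return df["wavelength_nm"].to_numpy(float), df["mua_stock"].to_numpy(float)
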