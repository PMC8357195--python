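"""LUT inverse model: constrained least-squares extraction of optical properties.

Given a measured absolute-reflectance spectrum and a lookup table for the
same SDS channel, the inverse model finds the constraint-model parameters
whose predicted reflectance best matches the measurement in the
least-squares sense:

* phantom mode — parameters (mu_s'(630), B, C): power-law scattering and a
  diluted stock absorber;
* tissue mode — parameters (mu_s'(630), B, THC, StO2, r_vess): power-law
  scattering and pigment-packaged hemoglobin absorption.

The optimiser is a bounded damped least-squares (trust-region reflective)
polish seeded from a deterministic coarse lattice scan of the cost inside
the parameter box; the best few lattice candidates are each refined and
the lowest-cost refinement wins.  This keeps the result independent of the
user-supplied initial guess for well-conditioned inputs, while the lattice
protects against the shallow, elongated cost valleys typical of
single-distance reflectance inversion at long SDS.

Quality control follows the 5 % chi-square gate: fits with
``100 * sum((Rhat-R)^2) / sum(R^2) > 5`` are flagged as discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .lut import LookupTable, evaluate
from .optics import (
    ExtinctionTable,
    load_extinction_table,
    pigment_packaging_factor,
)
from .spectral import Spectrum

__all__ = [
    "PHANTOM_BOUNDS",
    "TISSUE_BOUNDS",
    "FitBounds",
    "FitResult",
    "FitError",
    "predict_reflectance",
    "fit",
    "chi2_percent",
    "percent_error_curve",
    "validate_luts",
]

CHI2_GATE_PERCENT = 5.0
MAX_ITERATIONS = 10_000
MUA_ERROR_FLOOR = 0.05  # exclude wavelengths with expected mu_a below this


class FitError(ValueError):
    """Invalid input to the inverse model."""


@dataclass(frozen=True)
class FitBounds:
    """Box constraints per parameter; defaults follow the published tables."""

    lower: dict
    upper: dict

    def order(self, mode: str) -> list[str]:
        return (
            ["musp0", "b", "c"]
            if mode == "phantom"
            else ["musp0", "b", "thc", "sto2", "rvess"]
        )

    def arrays(self, mode: str) -> tuple[np.ndarray, np.ndarray]:
        names = self.order(mode)
        return (
            np.array([self.lower[n] for n in names], float),
            np.array([self.upper[n] for n in names], float),
        )


#: Phantom-mode bounds: mu_s'(630) in [2, 15] 1/cm, B in [0, 4], C in [0, 1].
PHANTOM_BOUNDS = FitBounds(
    lower={"musp0": 2.0, "b": 0.0, "c": 0.0},
    upper={"musp0": 15.0, "b": 4.0, "c": 1.0},
)

#: Tissue-mode bounds add THC in [0, 150] mg/mL, StO2 in [0, 1] and
#: r_vess in [0, 100] µm.
TISSUE_BOUNDS = FitBounds(
    lower={"musp0": 2.0, "b": 0.0, "thc": 0.0, "sto2": 0.0, "rvess": 0.0},
    upper={"musp0": 15.0, "b": 4.0, "thc": 150.0, "sto2": 1.0, "rvess": 100.0},
)


@dataclass(frozen=True, eq=False)
class FitResult:
    mode: str
    params: dict
    fitted: Spectrum
    chi2_percent: float
    n_iterations: int
    converged: bool
    accepted: bool
    n_extrapolated: int
    cost: float = field(default=np.nan)

    def musp_curve(self, wavelengths_nm) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, float)
        return self.params["musp0"] * (wl / 630.0) ** (-self.params["b"])


def _mua_curve(params: dict, mode: str, wl: np.ndarray,
               stock_mua: np.ndarray | None, ext: ExtinctionTable | None,
               eo: np.ndarray | None = None, eh: np.ndarray | None = None):
    if mode == "phantom":
        return params["c"] * stock_mua
    if eo is None:
        eo, eh = ext.interp(wl)
    mua_i = params["thc"] * (params["sto2"] * eo + (1.0 - params["sto2"]) * eh)
    mua_bl = ext.whole_blood_hb_mg_per_ml * (
        params["sto2"] * eo + (1.0 - params["sto2"]) * eh
    )
    return mua_i * pigment_packaging_factor(mua_bl, params["rvess"])


def predict_reflectance(
    params: dict,
    mode: str,
    lut: LookupTable,
    wavelengths_nm,
    stock_mua=None,
    ext: ExtinctionTable | None = None,
    smooth: bool = True,
) -> Spectrum:
    """Model reflectance spectrum for a parameter set via the LUT."""
    wl = np.asarray(wavelengths_nm, float)
    if mode not in ("phantom", "tissue"):
        raise FitError(f"unknown fit mode {mode!r}")
    if mode == "phantom" and stock_mua is None:
        raise FitError("phantom mode requires the stock absorber spectrum")
    if mode == "tissue":
        ext = ext or load_extinction_table()
    musp = params["musp0"] * (wl / 630.0) ** (-params["b"])
    mua = _mua_curve(params, mode, wl, np.asarray(stock_mua, float)
                     if stock_mua is not None else None, ext)
    refl, _ = evaluate(lut, musp, np.maximum(mua, 0.0), smooth=smooth)
    return Spectrum(wl, np.clip(refl, 0.0, None), "reflectance", lut.sds_mm)


def chi2_percent(fitted: Spectrum, measured: Spectrum) -> float:
    """Residual sum of squares as a percentage of the measured power.

    ``100 * sum((Rhat - R)^2) / sum(R^2)`` — scale-free, so the 5 % gate
    means the same thing for bright and dim channels.
    """
    if not fitted.same_grid(measured):
        raise FitError("fitted and measured spectra are on different grids")
    denom = float(np.sum(measured.values**2))
    if denom == 0.0:
        raise FitError("chi-square undefined for an all-zero measured spectrum")
    return 100.0 * float(np.sum((fitted.values - measured.values) ** 2)) / denom


def percent_error_curve(expected, fitted, min_expected: float = 0.0) -> float:
    """Wavelength-averaged absolute percent error, ``mean(100 |f-e|/e)``.

    Wavelengths with ``expected < min_expected`` are excluded (used with
    ``min_expected=0.05`` 1/cm for absorption, where the true value passes
    through zero and relative error is meaningless).
    """
    expected = np.asarray(expected, float)
    fitted = np.asarray(fitted, float)
    mask = expected >= max(min_expected, 1e-300)
    if not mask.any():
        raise FitError("no wavelengths with usable expected values")
    return float(
        np.mean(100.0 * np.abs(fitted[mask] - expected[mask]) / expected[mask])
    )


def _lattice(mode: str, lo: np.ndarray, hi: np.ndarray):
    if mode == "phantom":
        m0 = np.linspace(lo[0] + 0.2, hi[0] - 0.1, 22)
        b = np.linspace(max(lo[1], 0.1), min(hi[1], 2.2), 12)
        c = np.geomspace(max(lo[2], 3e-3), min(hi[2], 0.8), 14)
        return [("musp0", m0), ("b", b), ("c", c)]
    m0 = np.linspace(lo[0] + 0.2, hi[0] - 0.1, 12)
    b = np.linspace(max(lo[1], 0.1), min(hi[1], 2.2), 6)
    thc = np.geomspace(max(lo[2], 0.3), min(hi[2], 30.0), 8)
    sto2 = np.linspace(max(lo[3], 0.05), min(hi[3], 0.95), 6)
    rvess = np.array([np.clip(5.0, lo[4], hi[4])])
    return [("musp0", m0), ("b", b), ("thc", thc), ("sto2", sto2),
            ("rvess", rvess)]


def fit(
    spectrum: Spectrum,
    mode: str,
    lut: LookupTable,
    bounds: FitBounds | None = None,
    init: dict | None = None,
    stock_mua=None,
    ext: ExtinctionTable | None = None,
    n_starts: int = 5,
) -> FitResult:
    """Invert one measured spectrum against a LUT.

    ``init`` seeds one additional refinement start (default: bound
    midpoints); for well-conditioned inputs the returned parameters do not
    depend on it.  Optimiser failure yields ``converged=False`` rather than
    an exception.
    """
    if mode not in ("phantom", "tissue"):
        raise FitError(f"unknown fit mode {mode!r}")
    if not np.all(np.isfinite(spectrum.values)):
        raise FitError("measured spectrum contains non-finite values")
    if spectrum.role != "reflectance":
        raise FitError("inverse model requires an absolute-reflectance spectrum")
    bounds = bounds or (PHANTOM_BOUNDS if mode == "phantom" else TISSUE_BOUNDS)
    lo, hi = bounds.arrays(mode)
    names = bounds.order(mode)
    wl = spectrum.wavelengths_nm
    meas = spectrum.values
    scale = 1.0 / max(float(np.abs(meas).mean()), 1e-300)
    lam_ratio = wl / 630.0

    if mode == "phantom":
        if stock_mua is None:
            raise FitError("phantom mode requires the stock absorber spectrum")
        stock = np.asarray(stock_mua, float)
        eo = eh = None
    else:
        ext = ext or load_extinction_table()
        stock = None
        eo, eh = ext.interp(wl)

    def mua_of(p: dict) -> np.ndarray:
        if mode == "phantom":
            return p["c"] * stock
        mua_i = p["thc"] * (p["sto2"] * eo + (1.0 - p["sto2"]) * eh)
        mua_bl = 150.0 * (p["sto2"] * eo + (1.0 - p["sto2"]) * eh)
        return mua_i * pigment_packaging_factor(mua_bl, p["rvess"])

    def predict(vec: np.ndarray) -> np.ndarray:
        p = dict(zip(names, vec))
        musp = p["musp0"] * lam_ratio ** (-p["b"])
        refl, _ = evaluate(lut, musp, np.maximum(mua_of(p), 0.0), smooth=True)
        return refl

    def residuals(vec: np.ndarray) -> np.ndarray:
        return (predict(vec) - meas) * scale

    # deterministic coarse scan of the box (vectorised over musp0)
    axes = _lattice(mode, lo, hi)
    m0_axis = axes[0][1]
    other_axes = axes[1:]
    candidates: list[tuple[float, np.ndarray]] = []
    from itertools import product

    for combo in product(*[a[1] for a in other_axes]):
        p = dict(zip([a[0] for a in other_axes], combo))
        musp = np.outer(m0_axis, lam_ratio ** (-p["b"]))
        mua = np.maximum(mua_of({**p, "musp0": 0.0}), 0.0)
        refl, _ = evaluate(lut, musp, np.broadcast_to(mua, musp.shape), smooth=True)
        costs = np.sum((refl - meas[None, :]) ** 2 * scale**2, axis=1)
        k = int(np.argmin(costs))
        vec = np.array([m0_axis[k]] + [p[a[0]] for a in other_axes])
        candidates.append((float(costs[k]), vec))
    candidates.sort(key=lambda t: t[0])

    starts = [c[1] for c in candidates[:n_starts]]
    init_vec = np.array(
        [init.get(n, (l + u) / 2.0) if init else (l + u) / 2.0
         for n, l, u in zip(names, lo, hi)]
    )
    if init is not None:
        # an explicit initial guess seeds one extra refinement start; the
        # deterministic lattice keeps the outcome insensitive to it
        starts.append(np.clip(init_vec, lo, hi))

    best = None
    n_iter_total = 0
    for p0 in starts:
        try:
            res = least_squares(
                residuals, p0, bounds=(lo, hi), method="trf",
                diff_step=1e-4, xtol=1e-12, ftol=1e-12, gtol=1e-12,
                max_nfev=MAX_ITERATIONS,
            )
        except Exception:
            continue
        n_iter_total += res.nfev
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        params = dict(zip(names, np.clip(init_vec, lo, hi)))
        fitted_vals = predict(np.array(list(params.values())))
        fitted = Spectrum(wl, np.clip(fitted_vals, 0, None), "reflectance",
                          spectrum.sds_mm)
        chi2 = chi2_percent(fitted, spectrum)
        return FitResult(mode, params, fitted, chi2, n_iter_total, False,
                         False, 0)

    params = dict(zip(names, best.x))
    fitted_vals = predict(best.x)
    fitted = Spectrum(wl, np.clip(fitted_vals, 0, None), "reflectance",
                      spectrum.sds_mm)
    chi2 = chi2_percent(fitted, spectrum)
    musp = params["musp0"] * lam_ratio ** (-params["b"])
    _, flags = evaluate(lut, musp, np.maximum(mua_of(params), 0.0))
    return FitResult(
        mode=mode,
        params=params,
        fitted=fitted,
        chi2_percent=chi2,
        n_iterations=min(n_iter_total, MAX_ITERATIONS),
        converged=bool(best.status > 0),
        accepted=bool(chi2 <= CHI2_GATE_PERCENT),
        n_extrapolated=int(np.count_nonzero(flags)),
        cost=float(best.cost),
    )


def validate_luts(
    validation_set,
    luts: dict[float, LookupTable],
    stock_mua=None,
) -> pd.DataFrame:
    """Fit every validation phantom and tabulate mean percent errors per SDS.

    Returns a DataFrame with one row per SDS channel: wavelength- and
    phantom-averaged absolute percent errors for mu_s' and mu_a, the number
    of fits discarded by the chi-square gate, and an ``accurate`` flag
    (both errors < 10 %).
    """
    if stock_mua is None:
        recipes = validation_set.recipes
        wl = recipes[0].wavelengths_nm
        from .phantoms import hb_stock_mua

        stock_mua = hb_stock_mua(wl)
    rows = []
    for sds in validation_set.sds_mm:
        musp_errs, mua_errs, discarded = [], [], 0
        for recipe in validation_set.recipes:
            spec = validation_set.spectrum(recipe.label, sds)
            result = fit(spec, "phantom", luts[sds], stock_mua=stock_mua)
            if not result.accepted:
                discarded += 1
                continue
            musp_fit = result.musp_curve(recipe.wavelengths_nm)
            mua_fit = result.params["c"] * np.asarray(stock_mua, float)
            musp_errs.append(percent_error_curve(recipe.musp, musp_fit))
            mua_errs.append(
                percent_error_curve(recipe.mua, mua_fit, MUA_ERROR_FLOOR)
            )
        mean_musp = float(np.mean(musp_errs)) if musp_errs else np.nan
        mean_mua = float(np.mean(mua_errs)) if mua_errs else np.nan
        rows.append(
            {
                "sds_mm": sds,
                "musp_percent_error": mean_musp,
                "mua_percent_error": mean_mua,
                "n_fits": len(musp_errs),
                "n_discarded": discarded,
                "accurate": bool(mean_musp < 10.0 and mean_mua < 10.0),
            }
        )
    return pd.DataFrame(rows)
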