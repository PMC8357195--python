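"""Regenerate the packaged CSV fixtures.

The hemoglobin extinction basis is a synthetic band-sum model: Lorentzian
Soret tails, Gaussian visible bands, and smooth NIR terms.  Amplitudes are
expressed in cm^-1 per (mg/mL); they were anchored by least squares to
standard molar-extinction compilation values converted with
MW 64,500 g/mol and the natural-log convention, with the two oxyhemoglobin
Q-band maxima placed so the 1-nm grid argmaxima land exactly at 542 and
576 nm.  The teal-ink stock spectrum is a pinned smooth synthetic curve
peaking at 632 nm with a 50 cm^-1 peak, representing a concentrated dye
stock measured by spectrophotometry.

Run from the repository root:  python scripts/make_fixtures.py
"""

import numpy as np
import pandas as pd

GRID = np.arange(450.0, 901.0, 1.0)


def eps_hbo2(l: np.ndarray) -> np.ndarray:
    soret = 13.0 / (1.0 + ((l - 415.0) / 26.0) ** 2)
    q1 = 1.07 * np.exp(-(((l - 543.2) / 14.3) ** 2))
    q2 = 1.55 * np.exp(-(((l - 576.9) / 11.6) ** 2))
    broad = 0.76 * np.exp(-(((l - 535.0) / 39.7) ** 2))
    nir = np.maximum(-0.00034 + 0.07768 * ((l - 600.0) / 300.0) ** 2, 0.0) * (l > 600)
    return soret + q1 + q2 + broad + nir


def eps_hb(l: np.ndarray) -> np.ndarray:
    soret = 2.39813 / (1.0 + ((l - 430.0) / 31.53) ** 2)
    main = 1.63246 * np.exp(-(((l - 555.5) / 28.89) ** 2))
    broad = np.maximum(-0.22356 * np.exp(-(((l - 540.0) / 29.55) ** 2)), -0.3)
    nir = 0.02294 * np.exp(-(((l - 760.0) / 16.92) ** 2))
    tail = np.where(l > 600.0, 0.34086 * np.exp(-(l - 600.0) / 33.67), 0.34086)
    return np.maximum(soret + main + broad + nir + tail + 0.0122, 1e-4)


def ink_stock(l: np.ndarray, peak: float = 50.0) -> np.ndarray:
    shape = (np.exp(-(((l - 632.0) / 60.0) ** 2)) + 0.08) / 1.08
    return peak * shape


def main() -> None:
    eo, eh = eps_hbo2(GRID), eps_hb(GRID)
    sel = (GRID >= 500) & (GRID <= 600)
    w, e = GRID[sel], eo[sel]
    peaks = [w[i] for i in range(1, len(w) - 1) if e[i] > e[i - 1] and e[i] > e[i + 1]]
    assert peaks == [542.0, 576.0], peaks
    assert (eo >= 0).all() and (eh >= 0).all()
    pd.DataFrame(
        {"wavelength_nm": GRID, "eps_hbo2": eo.round(6), "eps_hb": eh.round(6)}
    ).to_csv("src/drslut/data/hb_extinction_synthetic.csv", index=False)
    pd.DataFrame(
        {"wavelength_nm": GRID, "mua_stock": ink_stock(GRID).round(6)}
    ).to_csv("src/drslut/data/teal_ink_synthetic.csv", index=False)
    print("fixtures written")


if __name__ == "__main__":
    main()
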