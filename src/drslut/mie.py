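"""Mie theory for dilute suspensions of non-absorbing microspheres.

Used to design scattering phantoms: given a sphere diameter and the
refractive-index dispersions of polystyrene and water, the reduced
scattering coefficient of a dilute suspension is

    mu_s'(lambda) = N * pi * r^2 * Qsca(lambda) * (1 - g(lambda)),

with ``N`` the number density implied by the sphere volume fraction.  The
series is evaluated with the standard logarithmic-derivative downward
recurrence and a Wiscombe-style truncation ``n_max = x + 4 x^{1/3} + 2``.

Refractive-index dispersions are pinned empirical formulas (coefficients
below) so phantom designs are bit-reproducible:

* polystyrene: one-term Sellmeier, ``n^2 = 1 + 1.4435 L^2/(L^2 - 0.020216)``
  with ``L`` in µm;
* water: four-term Cauchy fit adequate to ~1e-4 over 450–900 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MicrosphereSpec",
    "MieError",
    "polystyrene_index",
    "water_index",
    "mie_efficiencies",
    "mie_musp",
    "solve_volume_fraction",
]


class MieError(ValueError):
    """Invalid microsphere specification or non-physical Mie input."""


def polystyrene_index(wavelengths_nm: np.ndarray) -> np.ndarray:
    lam_um = np.asarray(wavelengths_nm, dtype=float) / 1000.0
    return np.sqrt(1.0 + 1.4435 * lam_um**2 / (lam_um**2 - 0.020216))


def water_index(wavelengths_nm: np.ndarray) -> np.ndarray:
    lam = np.asarray(wavelengths_nm, dtype=float)
    return 1.3199 + 6878.0 / lam**2 - 1.132e9 / lam**4 + 1.11e14 / lam**6


@dataclass(frozen=True)
class MicrosphereSpec:
    """Dilute suspension of monodisperse spheres in a host medium."""

    diameter_um: float = 1.00
    volume_fraction: float = 0.01
    sphere_index = staticmethod(polystyrene_index)
    medium_index = staticmethod(water_index)

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise MieError("sphere diameter must be positive")
        if not (0.0 < self.volume_fraction <= 0.05):
            raise MieError(
                "volume fraction must lie in (0, 0.05]: independent-scatterer regime"
            )

    @property
    def radius_cm(self) -> float:
        return self.diameter_um * 1e-4 / 2.0

    def with_volume_fraction(self, f: float) -> "MicrosphereSpec":
        return MicrosphereSpec(self.diameter_um, f)


def _nmax(x: float) -> int:
    return int(np.round(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_efficiencies(x: float, m: float) -> tuple[float, float]:
    """Scattering efficiency Qsca and asymmetry factor g for one sphere.

    Parameters
    ----------
    x : float
        Size parameter ``2 pi r n_medium / lambda``.
    m : float
        Relative refractive index ``n_sphere / n_medium`` (real, non-absorbing).
    """
    if x <= 0:
        raise MieError("size parameter must be positive")
    if m <= 0:
        raise MieError("relative index must be positive")
    nmax = _nmax(x)
    n = np.arange(1, nmax + 1)

    # Logarithmic derivative D_n(mx) by downward recurrence.
    mx = m * x
    nmx = max(nmax, int(np.ceil(abs(mx)))) + 16
    d = np.zeros(nmx + 1)
    for k in range(nmx, 0, -1):
        d[k - 1] = k / mx - 1.0 / (d[k] + k / mx)
    dn = d[1 : nmax + 1]

    # Riccati-Bessel psi, chi by upward recurrence (stable for psi at these x).
    psi = np.empty(nmax + 1)
    chi = np.empty(nmax + 1)
    psi0, psi1 = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi0, chi1 = -np.sin(x), np.cos(x)
    psi[0], chi[0] = psi1, chi1
    pm1, pm2 = psi1, psi0
    cm1, cm2 = chi1, chi0
    for k in range(1, nmax + 1):
        pk = (2 * k - 1) / x * pm1 - pm2
        ck = (2 * k - 1) / x * cm1 - cm2
        psi[k], chi[k] = pk, ck
        pm2, pm1 = pm1, pk
        cm2, cm1 = cm1, ck
    xi = psi - 1j * chi

    psin, psin1 = psi[1:], psi[:-1]
    xin, xin1 = xi[1:], xi[:-1]
    fac = dn / m + n / x
    gac = dn * m + n / x
    an = (fac * psin - psin1) / (fac * xin - xin1)
    bn = (gac * psin - psin1) / (gac * xin - xin1)

    if not (np.all(np.isfinite(an)) and np.all(np.isfinite(bn))):
        raise MieError("Mie series did not converge to finite coefficients")

    qsca = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(an) ** 2 + np.abs(bn) ** 2))
    asym = np.sum(
        n[:-1]
        * (n[:-1] + 2)
        / (n[:-1] + 1)
        * np.real(an[:-1] * np.conj(an[1:]) + bn[:-1] * np.conj(bn[1:]))
    ) + np.sum((2 * n + 1) / (n * (n + 1)) * np.real(an * np.conj(bn)))
    g = 4.0 / (x**2 * qsca) * asym
    return float(qsca), float(g)


def mie_musp(spec: MicrosphereSpec, wavelengths_nm: np.ndarray) -> np.ndarray:
    """Reduced scattering coefficient mu_s'(lambda) in 1/cm for a suspension."""
    lam = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
    n_med = spec.medium_index(lam)
    n_sph = spec.sphere_index(lam)
    r = spec.radius_cm
    number_density = spec.volume_fraction / (4.0 / 3.0 * np.pi * r**3)
    out = np.empty_like(lam)
    for i, (L, nm_, ns_) in enumerate(zip(lam, n_med, n_sph)):
        x = 2.0 * np.pi * r * nm_ / (L * 1e-7)
        qsca, g = mie_efficiencies(x, ns_ / nm_)
        out[i] = number_density * qsca * np.pi * r**2 * (1.0 - g)
    return out if np.ndim(wavelengths_nm) else float(out[0])


def solve_volume_fraction(
    target_musp0: float, spec: MicrosphereSpec, reference_nm: float = 630.0
) -> float:
    """Volume fraction giving ``target_musp0`` (1/cm) at the reference wavelength.

    mu_s' is exactly linear in the volume fraction in the dilute regime, so a
    single evaluation yields the closed-form answer.
    """
    if target_musp0 < 0:
        raise MieError("target reduced scattering must be non-negative")
    if target_musp0 == 0.0:
        return 0.0
    per_unit = mie_musp(spec.with_volume_fraction(0.01), reference_nm) / 0.01
    return target_musp0 / per_unit


def musp_wavelength_exponent(
    spec: MicrosphereSpec,
    wavelengths_nm: np.ndarray,
    reference_nm: float = 630.0,
) -> float:
    """Best-fit power-law exponent B of the Mie mu_s'(lambda) curve.

    Least-squares slope of log mu_s' against log(lambda/reference): the
    scattering exponent that the power-law constraint model assigns to
    these spheres.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    musp = mie_musp(spec, lam)
    x = np.log(lam / reference_nm)
    a = np.vstack([np.ones_like(x), x]).T
    coef, *_ = np.linalg.lstsq(a, np.log(musp), rcond=None)
    return float(-coef[1])
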