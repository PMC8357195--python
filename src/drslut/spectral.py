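"""Spectral data containers, reflectance calibration and resampling.

A broadband fiber probe records intensity spectra at several
source–detector separations (SDS).  Raw counts are converted to absolute
diffuse reflectance against a Spectralon-style reflectance standard:

    R(lambda) = (I_sample - I_background) / (I_std - I_background) * R_std

with ``R_std`` the standard's nominal reflectance expressed as a fraction
(0.20 for a 20 % standard), so that measuring the standard itself returns
its own absolute reflectance.  Reflectance is kept as a dimensionless
fraction everywhere inside the package; percent appears only at I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WAVELENGTH_GRID_NM",
    "SpectrometerConfig",
    "ProbeGeometry",
    "ReflectanceStandard",
    "Spectrum",
    "SpectrumError",
    "GridMismatchError",
    "DegenerateCalibrationError",
    "spectral_resolution",
    "calibrate_reflectance",
    "snr_db",
    "average_spectra",
    "resample_to_grid",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

#: Common processing grid: 450–900 nm at 1-nm spacing.  The instrument
#: resolution this package targets is ~2 nm, so 1-nm sampling is a mild,
#: harmless oversampling that makes joins between spectra trivial.
WAVELENGTH_GRID_NM = np.arange(450.0, 901.0, 1.0)

VALID_ROLES = ("sample", "background", "standard", "reflectance")


class SpectrumError(ValueError):
    """Invalid spectral data or configuration."""


class GridMismatchError(SpectrumError):
    """Operands do not share a wavelength grid or SDS channel."""


class DegenerateCalibrationError(SpectrumError):
    """Standard does not exceed background somewhere: calibration undefined."""


@dataclass(frozen=True)
class SpectrometerConfig:
    """CCD spectrometer geometry determining the optical resolution.

    Parameters
    ----------
    spectral_range_nm : float
        Usable spectral range imaged onto the detector array.
    n_pixel_elements : int
        Number of pixel elements of the linear detector.
    pixel_resolution_pixels : float
        Optical resolution expressed in pixels (set by the entrance slit).
    integration_time_ms : mapping
        Integration time per SDS channel (mm -> ms), all positive.
    """

    spectral_range_nm: float
    n_pixel_elements: int
    pixel_resolution_pixels: float
    integration_time_ms: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spectral_range_nm <= 0:
            raise SpectrumError("spectral_range_nm must be positive")
        if self.n_pixel_elements <= 0:
            raise SpectrumError("n_pixel_elements must be positive")
        if self.pixel_resolution_pixels <= 0:
            raise SpectrumError("pixel_resolution_pixels must be positive")
        for sds, t in self.integration_time_ms.items():
            if t <= 0:
                raise SpectrumError(f"integration time for SDS {sds} must be positive")


@dataclass(frozen=True)
class ProbeGeometry:
    """Fiber-probe layout: source–detector separations and fiber optics.

    Defaults describe a four-channel contact probe with separations of
    0.75, 2.00, 3.00 and 4.00 mm, a 200-µm collection core on the shortest
    channel and 400-µm cores elsewhere.
    """

    sds_mm: tuple[float, ...] = (0.75, 2.00, 3.00, 4.00)
    fiber_core_um: tuple[float, ...] = (200.0, 400.0, 400.0, 400.0)
    numerical_aperture: float = 0.22

    def __post_init__(self) -> None:
        sds = np.asarray(self.sds_mm, dtype=float)
        if sds.ndim != 1 or sds.size == 0:
            raise SpectrumError("sds_mm must be a non-empty 1-D sequence")
        if np.any(sds <= 0) or np.any(np.diff(sds) <= 0):
            raise SpectrumError("sds_mm must be strictly positive and ascending")
        if len(self.fiber_core_um) != len(self.sds_mm):
            raise SpectrumError("one fiber core diameter per SDS channel required")
        if any(c <= 0 for c in self.fiber_core_um):
            raise SpectrumError("fiber core diameters must be positive")
        if not (0 < self.numerical_aperture < 1):
            raise SpectrumError("numerical aperture must lie in (0, 1)")


@dataclass(frozen=True)
class ReflectanceStandard:
    """Diffuse reflectance standard (default: 20 % Spectralon)."""

    nominal_reflectance_percent: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 < self.nominal_reflectance_percent <= 100.0):
            raise SpectrumError("nominal reflectance must lie in (0, 100] percent")

    @property
    def fraction(self) -> float:
        return self.nominal_reflectance_percent / 100.0


@dataclass(frozen=True, eq=False)
class Spectrum:
    """A wavelength-indexed trace tagged with its role and SDS channel.

    ``values`` holds raw counts for sample/background/standard roles and a
    dimensionless reflectance fraction for the ``reflectance`` role.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    role: str
    sds_mm: float

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if self.role not in VALID_ROLES:
            raise SpectrumError(f"role must be one of {VALID_ROLES}, got {self.role!r}")
        if wl.ndim != 1 or wl.size == 0:
            raise SpectrumError("wavelengths must be a non-empty 1-D array")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelengths must be strictly ascending")
        if wl[0] < 450.0 - 1e-9 or wl[-1] > 900.0 + 1e-9:
            raise SpectrumError("wavelengths must lie within [450, 900] nm")
        if vals.shape != wl.shape:
            raise SpectrumError("values and wavelengths must have equal length")
        if not np.all(np.isfinite(vals)):
            raise SpectrumError("spectrum values must be finite")
        if self.role == "reflectance" and np.any(vals < 0):
            raise SpectrumError("reflectance values must be non-negative")
        if self.sds_mm <= 0:
            raise SpectrumError("sds_mm must be positive")

    def same_grid(self, other: "Spectrum") -> bool:
        return (
            self.wavelengths_nm.shape == other.wavelengths_nm.shape
            and np.allclose(self.wavelengths_nm, other.wavelengths_nm)
        )

    def with_values(self, values: np.ndarray, role: str | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths_nm, values, role or self.role, self.sds_mm)


def spectral_resolution(config: SpectrometerConfig) -> float:
    """Optical resolution in nm: (range / pixel elements) x pixel resolution."""
    return (
        config.spectral_range_nm / config.n_pixel_elements
    ) * config.pixel_resolution_pixels


def _require_aligned(*spectra: Spectrum) -> None:
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise GridMismatchError("spectra do not share a wavelength grid")
        if s.sds_mm != first.sds_mm:
            raise GridMismatchError("spectra do not share an SDS channel")


def calibrate_reflectance(
    sample: Spectrum,
    background: Spectrum,
    standard: Spectrum,
    std: ReflectanceStandard = ReflectanceStandard(),
) -> Spectrum:
    """Convert raw counts to absolute diffuse reflectance.

    The sample and standard must be acquired with equal integration time so
    the lamp spectrum divides out.  Requires ``standard > background``
    everywhere; the result carries the ``reflectance`` role.  Negative
    ratios (sample below background, i.e. pure noise) clip to zero so the
    output satisfies the reflectance non-negativity invariant.
    """
    _require_aligned(sample, background, standard)
    denom = standard.values - background.values
    if np.any(denom <= 0):
        raise DegenerateCalibrationError(
            "standard must exceed background at every wavelength"
        )
    ratio = (sample.values - background.values) / denom
    refl = np.clip(ratio * std.fraction, 0.0, None)
    return Spectrum(sample.wavelengths_nm, refl, "reflectance", sample.sds_mm)


def snr_db(signal: Spectrum, background: Spectrum) -> float:
    """Amplitude signal-to-noise ratio in dB.

    Defined as ``20 log10(mean(signal - background) / sd(background))``,
    with the background standard deviation as the noise estimate.  Returns
    ``-inf`` when the mean net signal is non-positive.
    """
    _require_aligned(signal, background)
    noise = float(np.std(background.values))
    if noise == 0.0:
        raise SpectrumError("background has zero variance: SNR undefined")
    net = float(np.mean(signal.values - background.values))
    if net <= 0.0:
        return float("-inf")
    return 20.0 * np.log10(net / noise)


def average_spectra(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of repeated acquisitions (identical grid/role/SDS)."""
    if len(spectra) == 0:
        raise SpectrumError("cannot average an empty list of spectra")
    first = spectra[0]
    _require_aligned(*spectra)
    for s in spectra[1:]:
        if s.role != first.role:
            raise SpectrumError("cannot average spectra with mixed roles")
    mean = np.mean([s.values for s in spectra], axis=0)
    if first.role == "reflectance":
        mean = np.clip(mean, 0.0, None)
    return first.with_values(mean)


def resample_to_grid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate onto ``grid``; extrapolation is refused."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise SpectrumError("target grid must be strictly ascending")
    if grid[0] < s.wavelengths_nm[0] or grid[-1] > s.wavelengths_nm[-1]:
        raise SpectrumError(
            "target grid extends beyond the spectrum's wavelength span"
        )
    vals = np.interp(grid, s.wavelengths_nm, s.values)
    return Spectrum(grid, vals, s.role, s.sds_mm)


# ---------------------------------------------------------------------------
# I/O: two-column CSV with a JSON sidecar carrying role and channel metadata.

def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"wavelength_nm": s.wavelengths_nm, "value": s.values}
    ).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"role": s.role, "sds_mm": s.sds_mm}))


def read_spectrum_csv(
    path: str | Path, role: str | None = None, sds_mm: float | None = None
) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"wavelength_nm", "value"} <= set(df.columns):
        raise SpectrumError(f"{path}: expected columns wavelength_nm,value")
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        role = role or meta.get("role")
        sds_mm = sds_mm if sds_mm is not None else meta.get("sds_mm")
    if role is None or sds_mm is None:
        raise SpectrumError(f"{path}: role and sds_mm required (sidecar or arguments)")
    return Spectrum(
        df["wavelength_nm"].to_numpy(float), df["value"].to_numpy(float), role, float(sds_mm)
    )
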