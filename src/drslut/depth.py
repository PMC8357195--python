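"""Sampling depth from black-layer liftoff experiments.

Raising the probe above a perfectly absorbing plane in 50-µm steps yields
reflectance-versus-distance curves R(z).  The sampling depth at a
wavelength is the depth at which half of the collected signal is removed
by the absorbing plane: the smallest grid distance where R(z) reaches 50 %
of its plateau (default criterion; an alternative "maximum sensitivity"
criterion — the increment with the steepest rise — is available for
comparison).  Pooling (mu_s'(lambda), mu_a(lambda), D(lambda)) across the
calibration phantoms gives a per-SDS depth surface D(mu_s', mu_a) on the
same domain as the reflectance LUT, from which the depth profile of any
fitted tissue spectrum can be read off.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.interpolate import (
    LinearNDInterpolator,
    NearestNDInterpolator,
    RegularGridInterpolator,
)
from scipy.spatial import Delaunay, QhullError

from .lut import LUT_MUA_RANGE, LUT_MUSP_RANGE, LutIOError
from .phantoms import LiftoffCurve

__all__ = [
    "DepthTable",
    "DepthError",
    "depth_from_liftoff",
    "build_depth_table",
    "query_depth",
    "depth_at_qband",
    "save_depth_table",
    "load_depth_table",
]

_FORMAT_VERSION = 1
QBAND_NM = 542.0
INCREMENT_MM = 0.05


class DepthError(ValueError):
    """Invalid liftoff data or depth-table query."""


class UnreliableDepthWarning(UserWarning):
    """Liftoff curve has not plateaued within the travel range."""


@dataclass(frozen=True, eq=False)
class DepthTable:
    """Sampling-depth surface D(mu_s', mu_a) in mm for one SDS channel."""

    sds_mm: float
    musp_grid: np.ndarray
    mua_grid: np.ndarray
    values: np.ndarray
    extrapolated: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.values <= 0):
            raise DepthError("sampling depths must be positive")

    def _grid_interp(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.musp_grid, self.mua_grid),
            self.values,
            method="linear",
            bounds_error=False,
            fill_value=None,
        )


def _column(curve: LiftoffCurve, wavelength_nm: float) -> np.ndarray:
    idx = np.argmin(np.abs(curve.wavelengths_nm - wavelength_nm))
    if abs(curve.wavelengths_nm[idx] - wavelength_nm) > 1e-6:
        raise DepthError(f"wavelength {wavelength_nm} nm not on the curve grid")
    return curve.reflectance[:, idx]


def depth_from_liftoff(
    curve: LiftoffCurve,
    wavelength_nm: float,
    criterion: str = "half_plateau",
    monotone_tol: float = 0.01,
) -> float:
    """Sampling depth (mm, a multiple of 0.05) at one wavelength.

    ``half_plateau``: the plateau is the mean reflectance over the five
    deepest increments (2.80-3.00 mm); the depth is the smallest grid
    distance with R >= 0.5 * plateau.  ``max_sensitivity``: the distance at
    the increment with the largest rise in R.
    """
    r = _column(curve, wavelength_nm)
    plateau = float(np.mean(r[-5:]))
    if plateau <= 0:
        raise DepthError("liftoff curve carries no signal at this wavelength")
    drops = np.diff(r)
    if np.any(drops < -monotone_tol * plateau):
        raise DepthError("liftoff curve decreases with distance beyond tolerance")
    if r[-1] < 0.9 * r.max():
        warnings.warn(
            "liftoff curve has not plateaued by 3 mm; depth may be unreliable",
            UnreliableDepthWarning,
            stacklevel=2,
        )
    z = curve.distances_mm
    if criterion == "half_plateau":
        idx = int(np.argmax(r >= 0.5 * plateau))
        return float(z[idx])
    if criterion == "max_sensitivity":
        return float(z[int(np.argmax(drops)) + 1])
    raise DepthError(f"unknown depth criterion {criterion!r}")


def build_depth_table(
    recipes_and_curves,
    sds_mm: float,
    grid_spacing: float = 0.1,
    criterion: str = "half_plateau",
    plateau_tolerance: float | None = None,
    metadata: dict | None = None,
) -> DepthTable:
    """Pool liftoff depths across phantoms into a per-SDS depth surface.

    ``recipes_and_curves``: sequence of (PhantomRecipe, LiftoffCurve).
    Wavelengths whose liftoff curve is still rising at the end of the
    travel (relative rise over the last five increments above
    ``plateau_tolerance``) have no meaningful half-plateau depth and are
    excluded from the pool.  Scattered (mu_s', mu_a, D) triples are
    interpolated linearly (triangulation) onto the regular grid; nodes
    outside the convex hull of the reliable pool take the nearest pooled
    value and are flagged.
    """
    mus, mas, depths = [], [], []
    for recipe, curve in recipes_and_curves:
        d = np.array(
            [depth_from_liftoff(curve, w, criterion) for w in curve.wavelengths_nm]
        )
        if plateau_tolerance is not None:
            refl = curve.reflectance
            with np.errstate(divide="ignore", invalid="ignore"):
                tail_rise = refl[-1] / refl[-6] - 1.0
            keep = np.isfinite(tail_rise) & (tail_rise <= plateau_tolerance)
        else:
            keep = np.ones(d.size, dtype=bool)
        mus.append(recipe.musp[keep])
        mas.append(recipe.mua[keep])
        depths.append(d[keep])
    mu = np.concatenate(mus)
    ma = np.concatenate(mas)
    dd = np.concatenate(depths)
    pts = np.column_stack([mu, ma])
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DepthError(f"degenerate liftoff scatter geometry: {exc}") from exc

    musp_grid = np.arange(LUT_MUSP_RANGE[0], LUT_MUSP_RANGE[1] + grid_spacing / 2,
                          grid_spacing)
    mua_grid = np.arange(LUT_MUA_RANGE[0], LUT_MUA_RANGE[1] + grid_spacing / 2,
                         grid_spacing)
    mg, ag = np.meshgrid(musp_grid, mua_grid, indexing="ij")
    interp = LinearNDInterpolator(tri, dd)
    grid = interp(mg, ag)
    nan = np.isnan(grid)
    if nan.any():
        nearest = NearestNDInterpolator(pts, dd)
        grid[nan] = nearest(mg[nan], ag[nan])
    outside = tri.find_simplex(
        np.column_stack([mg.ravel(), ag.ravel()])
    ).reshape(mg.shape) < 0
    meta = dict(metadata or {})
    meta.setdefault("build_date", _dt.date.today().isoformat())
    meta.update(criterion=criterion, n_points=int(dd.size))
    return DepthTable(sds_mm, musp_grid, mua_grid, grid, outside, meta)


def query_depth(table: DepthTable, musp, mua):
    """Depth (mm) at property values; clamped and flagged outside the domain."""
    musp = np.asarray(musp, float)
    mua = np.asarray(mua, float)
    flags = (
        (musp < LUT_MUSP_RANGE[0]) | (musp > LUT_MUSP_RANGE[1])
        | (mua < LUT_MUA_RANGE[0]) | (mua > LUT_MUA_RANGE[1])
    )
    mu_c = np.clip(musp, *LUT_MUSP_RANGE)
    ma_c = np.clip(mua, *LUT_MUA_RANGE)
    pts = np.column_stack([np.atleast_1d(mu_c).ravel(), np.atleast_1d(ma_c).ravel()])
    vals = table._grid_interp()(pts).reshape(np.broadcast(musp, mua).shape)
    return vals, flags


def depth_at_qband(wavelengths_nm, depth_mm) -> float:
    """Depth at the 542-nm oxyhemoglobin Q-band, interpolating within 2 nm."""
    wl = np.asarray(wavelengths_nm, float)
    d = np.asarray(depth_mm, float)
    exact = np.isclose(wl, QBAND_NM)
    if exact.any():
        return float(d[exact][0])
    below = wl[wl < QBAND_NM]
    above = wl[wl > QBAND_NM]
    if below.size and above.size and (QBAND_NM - below.max() <= 2.0) and (
        above.min() - QBAND_NM <= 2.0
    ):
        return float(np.interp(QBAND_NM, wl, d))
    raise DepthError("no samples within 2 nm of 542 nm")


def save_depth_table(tables, path) -> None:
    if isinstance(tables, DepthTable):
        tables = [tables]
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        for t in tables:
            g = f.create_group(f"sds_{t.sds_mm:.2f}")
            g.create_dataset("musp_grid", data=t.musp_grid)
            g.create_dataset("mua_grid", data=t.mua_grid)
            g.create_dataset("values", data=t.values)
            g.create_dataset("extrapolated", data=t.extrapolated.astype(np.uint8))
            g.attrs["sds_mm"] = t.sds_mm
            g.attrs["metadata"] = json.dumps(t.metadata)


def load_depth_table(path) -> dict[float, DepthTable]:
    out: dict[float, DepthTable] = {}
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format_version") != _FORMAT_VERSION:
                raise LutIOError(f"unsupported depth-table file version in {path}")
            for name in f:
                g = f[name]
                t = DepthTable(
                    sds_mm=float(g.attrs["sds_mm"]),
                    musp_grid=g["musp_grid"][...],
                    mua_grid=g["mua_grid"][...],
                    values=g["values"][...],
                    extrapolated=g["extrapolated"][...].astype(bool),
                    metadata=json.loads(g.attrs["metadata"]),
                )
                out[t.sds_mm] = t
    except (OSError, KeyError) as exc:
        raise LutIOError(f"cannot read depth-table file {path}: {exc}") from exc
    return out
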