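"""Derivation of the eight climatic covariates from monthly weather.

The covariates summarise precipitation (annual total, wettest/driest-quarter
totals, seasonality as a coefficient of variation) and temperature (annual
mean, warmest-month maximum, coldest-month minimum, seasonality CV) over a
*trailing window* — the 12 or 36 calendar months immediately preceding a given
month — or over a multi-decade mean-monthly climatology.

Conventions (fixed here because the field uses several):

* quarters are any 3 *consecutive* months within the window, no wrap-around;
* 36-month annual precipitation is annualised (x 12/36) so that 12- and
  36-month variables share units;
* CVs use the sample standard deviation (n-1); precipitation CV is computed
  on millimetres (0 when the mean is 0, without the +1 offset some bioclim
  implementations add), temperature CV on Kelvin so the statistic is
  well-behaved around 0 deg C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .climate import ClimateCube

__all__ = [
    "COVARIATE_NAMES",
    "CovariateVector",
    "WindowSpec",
    "extract_window",
    "bioclim_vars",
    "climatology_vars",
    "covariate_surface",
    "covariate_cube",
    "surface_to_netcdf",
]

#: Canonical order of the eight covariates.
COVARIATE_NAMES = (
    "ann_prec",
    "prec_wet_q",
    "prec_dry_q",
    "prec_cv",
    "ann_tmean",
    "tmax_warm_m",
    "tmin_cold_m",
    "temp_cv",
)

_KELVIN = 273.15
VALID_LENGTHS = (12, 36)


class CovariateVector(NamedTuple):
    """The eight climatic covariates for one cell and window."""

    ann_prec: float      # annualised precipitation total, mm/yr
    prec_wet_q: float    # wettest-quarter precipitation, mm
    prec_dry_q: float    # driest-quarter precipitation, mm
    prec_cv: float       # precipitation seasonality, % (sample CV)
    ann_tmean: float     # mean temperature, deg C
    tmax_warm_m: float   # warmest-month maximum, deg C
    tmin_cold_m: float   # coldest-month minimum, deg C
    temp_cv: float       # temperature seasonality, % (sample CV on Kelvin)


@dataclass(frozen=True)
class WindowSpec:
    """Trailing window: the ``length`` months strictly before ``end_exclusive``."""

    end_exclusive: tuple[int, int]  # (year, month); the window ends just before it
    length: int = 12

    def __post_init__(self) -> None:
        if self.length not in VALID_LENGTHS:
            raise ValueError(f"window length must be one of {VALID_LENGTHS}")
        y, m = self.end_exclusive
        if not 1 <= m <= 12:
            raise ValueError("month must be in 1..12")


def extract_window(cube: ClimateCube, cell: tuple[int, int], spec: WindowSpec) -> dict:
    """Monthly sub-series for one cell over a trailing window.

    Returns a dict with keys ``precip, tmin, tmax, tmean`` (each length
    ``spec.length``) and ``months`` (the PeriodIndex covered).  Raises if the
    window extends before the cube start — callers must not silently truncate.
    """
    y, m = spec.end_exclusive
    end = pd.Period(year=y, month=m, freq="M")
    e = int(end.ordinal - cube.time[0].ordinal)  # index of end_exclusive
    s = e - spec.length
    if s < 0:
        raise ValueError(
            f"window of {spec.length} months before {y}-{m:02d} starts before cube"
        )
    if e > len(cube.time):
        raise ValueError(f"window end {y}-{m:02d} beyond cube time span")
    iy, ix = cell
    return {
        "months": cube.time[s:e],
        "precip": cube.precip[s:e, iy, ix].copy(),
        "tmin": cube.tmin[s:e, iy, ix].copy(),
        "tmax": cube.tmax[s:e, iy, ix].copy(),
        "tmean": cube.tmean[s:e, iy, ix].copy(),
    }


def _sample_cv(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        return 0.0
    return float(100.0 * values.std(ddof=1) / mean)


def bioclim_vars(precip, tmin, tmax, tmean) -> CovariateVector:
    """The eight covariates for one monthly series (length 12 or 36)."""
    precip = np.asarray(precip, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    tmean = np.asarray(tmean, dtype=float)
    n = precip.size
    if not (tmin.size == tmax.size == tmean.size == n):
        raise ValueError("series lengths differ")
    if n not in VALID_LENGTHS:
        raise ValueError(f"series length must be one of {VALID_LENGTHS}, got {n}")
    quarters = sliding_window_view(precip, 3).sum(axis=-1)  # all consecutive triples
    return CovariateVector(
        ann_prec=float(precip.sum() * 12.0 / n),
        prec_wet_q=float(quarters.max()),
        prec_dry_q=float(quarters.min()),
        prec_cv=_sample_cv(precip),
        ann_tmean=float(tmean.mean()),
        tmax_warm_m=float(tmax.max()),
        tmin_cold_m=float(tmin.min()),
        temp_cv=_sample_cv(tmean + _KELVIN),
    )


def climatology_vars(
    cube: ClimateCube, cell: tuple[int, int], baseline: tuple[int, int]
) -> CovariateVector:
    """Covariates of the mean monthly climatology over ``baseline`` years.

    The 12-value mean seasonal cycle (per variable) is computed over the
    baseline years (both ends inclusive) and then summarised by
    :func:`bioclim_vars` as a 12-month series.
    """
    y0, y1 = baseline
    if y1 < y0:
        raise ValueError("baseline end precedes start")
    s = int(pd.Period(year=y0, month=1, freq="M").ordinal - cube.time[0].ordinal)
    e = int(pd.Period(year=y1, month=12, freq="M").ordinal - cube.time[0].ordinal) + 1
    if s < 0 or e > len(cube.time):
        raise ValueError("baseline not fully inside cube time span")
    iy, ix = cell
    clim = {}
    for name in ("precip", "tmin", "tmax", "tmean"):
        series = getattr(cube, name)[s:e, iy, ix]
        clim[name] = series.reshape(-1, 12).mean(axis=0)
    return bioclim_vars(clim["precip"], clim["tmin"], clim["tmax"], clim["tmean"])


def covariate_surface(cube: ClimateCube, spec: WindowSpec) -> dict[str, np.ndarray]:
    """Per-cell covariates for one trailing window: name -> (ny, nx) array.

    Masked cells propagate as NaN.
    """
    y, m = spec.end_exclusive
    end = pd.Period(year=y, month=m, freq="M")
    e = int(end.ordinal - cube.time[0].ordinal)
    s = e - spec.length
    if s < 0 or e > len(cube.time):
        raise ValueError("window outside cube time span")
    out = _window_block_vars(
        cube.precip[s:e], cube.tmin[s:e], cube.tmax[s:e], cube.tmean[s:e]
    )
    for arr in out.values():
        arr[~cube.mask] = np.nan
    return out


def _window_block_vars(precip, tmin, tmax, tmean) -> dict[str, np.ndarray]:
    """Vectorised bioclim over one window block with leading time axis."""
    n = precip.shape[0]
    quarters = sliding_window_view(precip, 3, axis=0).sum(axis=-1)
    mean_p = precip.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_cv = np.where(
            mean_p == 0, 0.0, 100.0 * precip.std(axis=0, ddof=1) / mean_p
        )
    tk = tmean + _KELVIN
    return {
        "ann_prec": precip.sum(axis=0) * 12.0 / n,
        "prec_wet_q": quarters.max(axis=0),
        "prec_dry_q": quarters.min(axis=0),
        "prec_cv": prec_cv,
        "ann_tmean": tmean.mean(axis=0),
        "tmax_warm_m": tmax.max(axis=0),
        "tmin_cold_m": tmin.min(axis=0),
        "temp_cv": 100.0 * tk.std(axis=0, ddof=1) / tk.mean(axis=0),
    }


def covariate_cube(cube: ClimateCube, length: int = 12) -> dict:
    """All trailing-window covariate surfaces at once.

    For every month ``t`` of the cube with a complete trailing window of
    ``length`` months (i.e. from position ``length`` onwards), computes the
    eight covariates of the window ending immediately before ``t``.

    Returns a dict with ``end_months`` (PeriodIndex, length T - length) and one
    ``(T - length, ny, nx)`` array per covariate name.  Entry ``i`` belongs to
    the window ending just before ``end_months[i]``.
    """
    if length not in VALID_LENGTHS:
        raise ValueError(f"window length must be one of {VALID_LENGTHS}")
    T = len(cube.time)
    if T <= length:
        raise ValueError("cube shorter than one window")
    nw = T - length  # windows [s, s+length) for s = 0 .. nw-1

    def win(arr):  # (nw, ny, nx, length)
        return sliding_window_view(arr, length, axis=0)[:nw]

    precip_w = win(cube.precip)
    quarters = sliding_window_view(cube.precip, 3, axis=0).sum(axis=-1)
    quarters_w = sliding_window_view(quarters, length - 2, axis=0)[:nw]
    mean_p = precip_w.mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_cv = np.where(
            mean_p == 0, 0.0, 100.0 * precip_w.std(axis=-1, ddof=1) / mean_p
        )
    tk_w = win(cube.tmean) + _KELVIN
    out = {
        "end_months": cube.time[length:],
        "ann_prec": precip_w.sum(axis=-1) * 12.0 / length,
        "prec_wet_q": quarters_w.max(axis=-1),
        "prec_dry_q": quarters_w.min(axis=-1),
        "prec_cv": prec_cv,
        "ann_tmean": win(cube.tmean).mean(axis=-1),
        "tmax_warm_m": win(cube.tmax).max(axis=-1),
        "tmin_cold_m": win(cube.tmin).min(axis=-1),
        "temp_cv": 100.0 * tk_w.std(axis=-1, ddof=1) / tk_w.mean(axis=-1),
    }
    bad = ~cube.mask
    if bad.any():
        for name in COVARIATE_NAMES:
            out[name][:, bad] = np.nan
    return out


def surface_to_netcdf(surfaces: dict[str, np.ndarray], path, y=None, x=None) -> None:
    """Write covariate surfaces as a NetCDF file, one band per covariate."""
    import xarray as xr

    first = surfaces[COVARIATE_NAMES[0]]
    ny, nx = first.shape
    coords = {
        "y": np.asarray(y) if y is not None else np.arange(ny, dtype=float),
        "x": np.asarray(x) if x is not None else np.arange(nx, dtype=float),
    }
    ds = xr.Dataset(
        {name: (("y", "x"), surfaces[name]) for name in COVARIATE_NAMES},
        coords=coords,
    )
    ds.to_netcdf(path, engine="scipy")
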