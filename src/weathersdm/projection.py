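"""Projection of a fitted model onto gridded covariates and area accounting.

Each month's covariate surfaces are pushed through the fitted model's
logistic output to give a suitability surface; the monthly surfaces are
averaged into a static composite, binarised at the equal training
sensitivity = specificity threshold into core habitat, and summed (cells x
cell area) into the suitable-area time series whose annual statistics feed
the abundance analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import COVARIATE_NAMES
from .maxent import MaxentResults

__all__ = [
    "project_surface",
    "project_series",
    "composite_mean",
    "equal_ss_threshold",
    "binary_surface",
    "suitability_fraction",
    "AreaSeries",
    "area_series",
]


def _surface_table(surfaces: dict[str, np.ndarray], names) -> tuple[pd.DataFrame, np.ndarray, tuple]:
    missing = [n for n in names if n not in surfaces]
    if missing:
        raise ValueError(f"covariate surfaces missing: {missing}")
    shape = np.asarray(surfaces[names[0]]).shape
    cols = {}
    for n in names:
        arr = np.asarray(surfaces[n], dtype=float)
        if arr.shape != shape:
            raise ValueError("covariate surfaces have inconsistent shapes")
        cols[n] = arr.ravel()
    table = pd.DataFrame(cols)
    valid = ~table.isna().any(axis=1).to_numpy()
    return table, valid, shape


def project_surface(results: MaxentResults, surfaces: dict[str, np.ndarray],
                    output: str = "logistic") -> np.ndarray:
    """Cellwise suitability for one month's covariate surfaces.

    ``surfaces`` maps covariate name -> 2-D array.  Cells with any missing
    covariate propagate as NaN.
    """
    names = results.model.covariates
    table, valid, shape = _surface_table(surfaces, names)
    out = np.full(table.shape[0], np.nan)
    if valid.any():
        out[valid] = results.predict(table[valid], output=output)
    return out.reshape(shape)


def project_series(results: MaxentResults, covariate_stacks: dict[str, np.ndarray],
                   output: str = "logistic") -> np.ndarray:
    """Suitability for a stack of months: name -> (T, ny, nx) arrays in,
    (T, ny, nx) suitability out."""
    names = results.model.covariates
    table, valid, shape = _surface_table(covariate_stacks, names)
    out = np.full(table.shape[0], np.nan)
    if valid.any():
        out[valid] = results.predict(table[valid], output=output)
    return out.reshape(shape)


def composite_mean(surfaces) -> np.ndarray:
    """Cellwise arithmetic mean of suitability surfaces, ignoring NaN months."""
    if isinstance(surfaces, np.ndarray):
        stack = surfaces
    else:
        surfaces = list(surfaces)
        if not surfaces:
            raise ValueError("no surfaces to composite")
        stack = np.stack(surfaces)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("expected a non-empty (T, ny, nx) stack")
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack, axis=0)


def equal_ss_threshold(presence_scores, background_scores) -> float:
    """Threshold equalising training sensitivity and specificity.

    Candidates are the unique observed scores; sensitivity is the fraction of
    presences scoring >= t and specificity the fraction of background scoring
    < t.  Returns the candidate minimising |sens - spec|, lowest first on
    ties.
    """
    p = np.sort(np.asarray(presence_scores, dtype=float))
    b = np.sort(np.asarray(background_scores, dtype=float))
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    cand = np.unique(np.concatenate([p, b]))
    sens = 1.0 - np.searchsorted(p, cand, side="left") / p.size
    spec = np.searchsorted(b, cand, side="left") / b.size
    gap = np.abs(sens - spec)
    # ties resolve to the lowest candidate; tolerate float rounding in gaps
    tied = np.flatnonzero(gap <= gap.min() + 1e-12)
    return float(cand[tied[0]])


def binary_surface(surface: np.ndarray, t: float) -> np.ndarray:
    """Core-habitat indicator: 1 where suitability >= t, NaN preserved."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    surface = np.asarray(surface, dtype=float)
    out = np.where(surface >= t, 1.0, 0.0)
    out[np.isnan(surface)] = np.nan
    return out


def suitability_fraction(binary_stack: np.ndarray) -> np.ndarray:
    """Per-cell fraction of months classed suitable (habitat-stability map)."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(binary_stack, axis=0)


@dataclass
class AreaSeries:
    """Monthly suitable-area totals and their annual summaries.

    ``monthly`` has columns (year, month, area_km2); ``annual`` has
    (year, mean, min, max, n_months, partial).  The annual statistic carried
    into the abundance analysis is the mean of the 12 monthly areas.
    """

    monthly: pd.DataFrame
    annual: pd.DataFrame

    def annual_values(self, stat: str = "mean") -> pd.Series:
        if stat not in ("mean", "min", "max", "sum"):
            raise ValueError(f"unknown annual statistic {stat!r}")
        if stat == "sum":
            s = self.monthly.groupby("year")["area_km2"].sum()
        else:
            s = self.annual.set_index("year")[stat]
        return s.rename("area_km2")

    def plot(self, ax=None):
        """Annual band (min-max) with the annual mean line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        a = self.annual
        ax.fill_between(a["year"], a["min"], a["max"], alpha=0.3, color="grey",
                        label="monthly range")
        ax.plot(a["year"], a["mean"], color="k", label="annual mean")
        ax.set_xlabel("year")
        ax.set_ylabel("core habitat area (km$^2$)")
        ax.legend()
        return ax


def area_series(binary_stack: np.ndarray, months: pd.PeriodIndex,
                cell_area: float | np.ndarray) -> AreaSeries:
    """Suitable-area series from monthly binary surfaces.

    ``cell_area`` is km^2 per cell, scalar or (ny, nx).  Monthly area is the
    sum of suitable-cell areas; annual rows report mean/min/max over the
    months available that year, flagging partial years.
    """
    binary_stack = np.asarray(binary_stack, dtype=float)
    if binary_stack.shape[0] != len(months):
        raise ValueError("stack length and months differ")
    area_map = np.broadcast_to(
        np.asarray(cell_area, dtype=float), binary_stack.shape[1:]
    )
    vals = np.nansum(binary_stack * area_map, axis=(1, 2))
    monthly = pd.DataFrame({
        "year": months.year,
        "month": months.month,
        "area_km2": vals,
    })
    g = monthly.groupby("year")["area_km2"]
    annual = g.agg(mean="mean", min="min", max="max", n_months="size").reset_index()
    annual["partial"] = annual["n_months"] < 12
    return AreaSeries(monthly=monthly, annual=annual)
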