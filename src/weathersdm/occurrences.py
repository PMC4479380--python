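"""Quality filtering, deduplication and covariate stamping of occurrence records.

Records arrive as a DataFrame with columns ``species, lon, lat, year, month,
date_acc_months, loc_acc_km, source``.  Preparation (i) drops records whose
date or location accuracy exceeds the stated bounds (bounds inclusive — the
exclusion rule is strictly "greater than"), (ii) collapses multiple records
within a fixed radius in the same month and year to a single record, and
(iii) stamps each surviving record with the eight climatic covariates of the
trailing window(s) ending immediately before its month.

Deduplication uses greedy first-seed clustering in input order: within each
(year, month) group a record joins the first already-retained record lying
within the radius, otherwise it seeds a new cluster; each cluster contributes
its first-seen record.  The distance metric is Euclidean on kilometre grids
(synthetic data) or haversine great-circle on lon/lat degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import ClimateCube
from .covariates import COVARIATE_NAMES, covariate_cube

__all__ = [
    "REQUIRED_COLUMNS",
    "OccurrenceSet",
    "filter_records",
    "dedupe_records",
    "prepare_records",
    "stamp_covariates",
]

REQUIRED_COLUMNS = (
    "species",
    "lon",
    "lat",
    "year",
    "month",
    "date_acc_months",
    "loc_acc_km",
    "source",
)

_EARTH_RADIUS_KM = 6371.0088


@dataclass
class OccurrenceSet:
    """Occurrence records plus a provenance log of the filters applied."""

    records: pd.DataFrame
    log: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in ("lon", "lat", "year", "month") if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")


def filter_records(
    records: pd.DataFrame,
    max_date_acc: float = 1.0,
    max_loc_acc_km: float = 10.0,
    year_range: tuple[int, int] | None = None,
) -> OccurrenceSet:
    """Drop records failing the accuracy bounds or outside ``year_range``.

    Bounds are inclusive: a record with date accuracy exactly 1 month and
    location accuracy exactly 10 km is retained.  Removal counts are logged
    per reason.
    """
    _check_columns(records)
    df = records.reset_index(drop=True)
    keep = pd.Series(True, index=df.index)
    log = []

    if "date_acc_months" in df.columns:
        bad = df["date_acc_months"] > max_date_acc
        log.append({"filter": "date_accuracy", "removed": int(bad.sum()),
                    "bound_months": max_date_acc})
        keep &= ~bad
    if "loc_acc_km" in df.columns:
        bad = df["loc_acc_km"] > max_loc_acc_km
        log.append({"filter": "location_accuracy", "removed": int(bad.sum()),
                    "bound_km": max_loc_acc_km})
        keep &= ~bad
    if year_range is not None:
        y0, y1 = year_range
        bad = (df["year"] < y0) | (df["year"] > y1)
        log.append({"filter": "year_range", "removed": int((bad & keep).sum()),
                    "range": [int(y0), int(y1)]})
        keep &= ~bad

    out = df[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("all records removed by filters", stacklevel=2)
    return OccurrenceSet(out, log)


def _pairwise_km(lon, lat, lon0, lat0, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return np.hypot(lon - lon0, lat - lat0)
    if metric == "haversine":
        p1, p2 = np.radians(lat), np.radians(lat0)
        dp = p2 - p1
        dl = np.radians(lon0) - np.radians(lon)
        a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
        return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    raise ValueError(f"unknown metric {metric!r}")


def dedupe_records(
    records: pd.DataFrame | OccurrenceSet,
    radius_km: float = 5.0,
    metric: str = "euclidean",
) -> OccurrenceSet:
    """Collapse same-month-and-year records within ``radius_km`` to one record.

    Greedy first-seed clustering in input order (stable across calls, hence
    idempotent).  ``metric='euclidean'`` treats lon/lat as kilometre
    coordinates; ``'haversine'`` as degrees.
    """
    prev_log: list = []
    if isinstance(records, OccurrenceSet):
        prev_log = list(records.log)
        records = records.records
    _check_columns(records)
    df = records.reset_index(drop=True)
    keep_idx: list[int] = []
    for _, group in df.groupby(["year", "month"], sort=True):
        seeds_lon: list[float] = []
        seeds_lat: list[float] = []
        for i in group.index:
            lon, lat = df.at[i, "lon"], df.at[i, "lat"]
            if seeds_lon:
                d = _pairwise_km(
                    np.asarray(seeds_lon), np.asarray(seeds_lat), lon, lat, metric
                )
                if (d <= radius_km).any():
                    continue
            seeds_lon.append(lon)
            seeds_lat.append(lat)
            keep_idx.append(i)
    out = df.loc[sorted(keep_idx)].reset_index(drop=True)
    log = prev_log + [{
        "filter": "dedupe",
        "radius_km": radius_km,
        "metric": metric,
        "removed": int(len(df) - len(out)),
    }]
    return OccurrenceSet(out, log)


def prepare_records(
    records: pd.DataFrame,
    max_date_acc: float = 1.0,
    max_loc_acc_km: float = 10.0,
    year_range: tuple[int, int] | None = None,
    radius_km: float = 5.0,
    metric: str = "euclidean",
) -> OccurrenceSet:
    """Filter then deduplicate, preserving the combined provenance log."""
    filtered = filter_records(records, max_date_acc, max_loc_acc_km, year_range)
    return dedupe_records(filtered, radius_km=radius_km, metric=metric)


def stamp_covariates(
    records: pd.DataFrame | OccurrenceSet,
    cube: ClimateCube,
    window_lengths: tuple[int, ...] = (12, 36),
    precomputed: dict[int, dict] | None = None,
) -> tuple[pd.DataFrame, list]:
    """Attach trailing-window covariates to each record.

    Each record gains the eight covariates per window length, named
    ``{covariate}_{length}m``, taken from the grid cell containing its
    coordinates with the window ending immediately before its (year, month).
    Records whose windows start before the cube, or that fall outside the
    grid, are excluded with a logged reason.

    ``precomputed`` may carry ``{length: covariate_cube(cube, length)}`` to
    avoid recomputation across calls.

    Returns (design table, log).
    """
    if isinstance(records, OccurrenceSet):
        records = records.records
    _check_columns(records)
    df = records.reset_index(drop=True)
    cubes = dict(precomputed or {})
    for L in window_lengths:
        if L not in cubes:
            cubes[L] = covariate_cube(cube, L)

    # locate cells and time positions
    n = len(df)
    iy = np.empty(n, dtype=int)
    ix = np.empty(n, dtype=int)
    inside = np.ones(n, dtype=bool)
    for i in range(n):
        try:
            iy[i], ix[i] = cube.cell_index(df.at[i, "lon"], df.at[i, "lat"])
        except IndexError:
            inside[i] = False
    periods = pd.PeriodIndex(
        year=df["year"].to_numpy(), month=df["month"].to_numpy(), freq="M"
    )
    tpos = periods.asi8 - cube.time[0].ordinal  # index of record month in cube

    max_len = max(window_lengths)
    in_time = (tpos >= max_len) & (tpos < len(cube.time))
    ok = inside & in_time
    log = [
        {"filter": "stamp_outside_grid", "removed": int((~inside).sum())},
        {"filter": "stamp_window_out_of_range",
         "removed": int((inside & ~in_time).sum()),
         "window_lengths": list(window_lengths)},
    ]

    out = df[ok].reset_index(drop=True)
    sel_t = tpos[ok]
    sel_iy, sel_ix = iy[ok], ix[ok]
    for L in window_lengths:
        cc = cubes[L]
        # entry i of cc corresponds to window ending before cube month i + L
        rows = sel_t - L
        for name in COVARIATE_NAMES:
            out[f"{name}_{L}m"] = cc[name][rows, sel_iy, sel_ix]
    return out, log
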