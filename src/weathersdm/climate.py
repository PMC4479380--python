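"""Monthly gridded weather container.

A :class:`ClimateCube` holds a contiguous monthly series of gridded
precipitation and temperature fields on a regular 2-D grid.  It is the raw
predictor source for every climatic covariate computed downstream.  Internally
the fields are plain ``(time, y, x)`` numpy arrays; :meth:`ClimateCube.to_xarray`
and :meth:`ClimateCube.to_netcdf` provide the standard container/serialisation
forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["ClimateCube"]


@dataclass
class ClimateCube:
    """Monthly weather series on a regular grid.

    Parameters
    ----------
    time : pandas.PeriodIndex
        Contiguous monthly time axis.
    y, x : ndarray
        1-D cell-centre coordinates.  For synthetic grids these are plain
        kilometre offsets; for geographic grids, degrees latitude/longitude.
    precip : ndarray, shape (T, ny, nx)
        Monthly precipitation total (mm).
    tmin, tmax, tmean : ndarray, shape (T, ny, nx)
        Monthly minimum / maximum / mean temperature (deg C).
    mask : ndarray of bool, shape (ny, nx), optional
        True marks valid cells.  Defaults to all-valid.
    """

    time: pd.PeriodIndex
    y: np.ndarray
    x: np.ndarray
    precip: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    tmean: np.ndarray
    mask: np.ndarray | None = None
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.time = pd.PeriodIndex(self.time, freq="M")
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        for name in ("precip", "tmin", "tmax", "tmean"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.mask is None:
            self.mask = np.ones((self.y.size, self.x.size), dtype=bool)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        T, ny, nx = len(self.time), self.y.size, self.x.size
        for name in ("precip", "tmin", "tmax", "tmean"):
            arr = getattr(self, name)
            if arr.shape != (T, ny, nx):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(T, ny, nx)}")
        if T > 1:
            steps = np.diff(self.time.asi8)
            if not np.all(steps == 1):
                raise ValueError("time axis must be contiguous monthly")
        m = self.mask
        if not (self.tmin[:, m] <= self.tmean[:, m] + 1e-9).all():
            raise ValueError("tmin must be <= tmean everywhere")
        if not (self.tmean[:, m] <= self.tmax[:, m] + 1e-9).all():
            raise ValueError("tmean must be <= tmax everywhere")
        if (self.precip[:, m] < 0).any():
            raise ValueError("precip must be non-negative")
        self._validated = True

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return len(self.time), self.y.size, self.x.size

    def index_of(self, year: int, month: int) -> int:
        """Position of (year, month) on the time axis; raises if outside."""
        p = pd.Period(year=year, month=month, freq="M")
        i = int(p.ordinal - self.time[0].ordinal)
        if not 0 <= i < len(self.time):
            raise IndexError(f"{year}-{month:02d} outside cube time span")
        return i

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """(iy, ix) of the grid cell containing the point, nearest-centre rule."""
        ix = int(np.argmin(np.abs(self.x - x)))
        iy = int(np.argmin(np.abs(self.y - y)))
        for coord, val, i in ((self.x, x, ix), (self.y, y, iy)):
            half = (np.abs(np.diff(coord)).min() / 2.0) if coord.size > 1 else np.inf
            if abs(coord[i] - val) > half + 1e-9:
                raise IndexError(f"point ({x}, {y}) outside grid")
        return iy, ix

    # ------------------------------------------------------------------
    def to_xarray(self) -> xr.Dataset:
        coords = {
            "time": self.time.to_timestamp(),
            "y": self.y,
            "x": self.x,
        }
        data = {
            name: (("time", "y", "x"), getattr(self, name))
            for name in ("precip", "tmin", "tmax", "tmean")
        }
        data["mask"] = (("y", "x"), self.mask.astype(np.int8))
        return xr.Dataset(data, coords=coords)

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy")

    @classmethod
    def from_xarray(cls, ds: xr.Dataset) -> "ClimateCube":
        time = pd.DatetimeIndex(ds["time"].values).to_period("M")
        mask = ds["mask"].values.astype(bool) if "mask" in ds else None
        return cls(
            time=time,
            y=ds["y"].values,
            x=ds["x"].values,
            precip=ds["precip"].values,
            tmin=ds["tmin"].values,
            tmax=ds["tmax"].values,
            tmean=ds["tmean"].values,
            mask=mask,
        )

    @classmethod
    def from_netcdf(cls, path) -> "ClimateCube":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_xarray(ds.load())
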