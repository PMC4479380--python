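"""Synthetic island, weather history, occurrences and transect counts.

Every downstream stage of the pipeline is exercised against data from this
module, whose statistical structure mirrors the assumptions of the analysis:

* **Weather** — a sinusoidal seasonal cycle (coldest and wettest months in
  austral winter, June-August) plus a smooth west-east spatial gradient
  (wet-mild west, dry-continental east), i.i.d. Gaussian interannual
  anomalies shared by all months of a year, and small month-level noise.
  An optional multi-year *unfavourable excursion* raises winter minima by a
  fixed number of degrees and scales wettest-quarter precipitation.
* **Truth** — a known logistic suitability surface driven by the same
  covariates the pipeline derives (coldest-month minimum, wettest-quarter
  precipitation, annual precipitation, all standardised within the cube),
  penalising warm winters and heavy rain, so the excursion depresses it.
* **Occurrences** — an inhomogeneous sampling process: focal records fall on
  cell-months with probability proportional to truth x observer-effort bias;
  two companion (target-group) species follow the bias alone.
* **Transect counts** — negative-binomial spotlight counts whose expectation
  tracks mean truth over the transect's cell in a fixed 4-month survey
  season, optionally *held low* (decoupled from suitability) after a
  suppression year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import ClimateCube
from .covariates import covariate_cube

__all__ = [
    "SyntheticConfig",
    "TruthSurface",
    "gen_weather",
    "truth_surface",
    "gen_occurrences",
    "gen_transects",
]

WINTER_MONTHS = (6, 7, 8)  # climatologically coldest and wettest quarter


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic island and its weather history.

    Temperature fields are deg C, precipitation mm/month, cell areas km^2.
    The anomaly window imposes the unfavourable excursion: winter minima
    raised by ``anomaly_winter_warming`` and wettest-quarter precipitation
    scaled by ``anomaly_wet_quarter_scale`` in those years.
    """

    grid_rows: int = 20
    grid_cols: int = 20
    cell_area_km2: float = 25.0
    start_year: int = 1950
    end_year: int = 2009
    seed: int = 0
    anomaly_window: tuple[int, int] | None = (2001, 2003)
    anomaly_winter_warming: float = 2.0
    anomaly_wet_quarter_scale: float = 1.5
    suppression_start_year: int | None = None
    suppression_factor: float = 0.4

    # weather-process parameters
    tmean_base: float = 11.0
    temp_seasonal_amp: float = 7.0
    temp_gradient: float = 3.0          # west-east warming, deg C across grid
    diurnal_down: float = 5.0           # tmean - tmin
    diurnal_up: float = 5.5             # tmax - tmean
    precip_base: float = 70.0
    precip_seasonal_amp: float = 45.0
    precip_gradient: float = 0.8        # multiplier range: 1+g/2 (west) .. 1-g/2 (east)
    year_temp_sd: float = 0.5
    month_temp_sd: float = 0.4
    year_precip_sd: float = 10.0
    month_precip_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.grid_rows < 10 or self.grid_cols < 10:
            raise ValueError("grid must be at least 10 x 10")
        if self.end_year - self.start_year + 1 < 20:
            raise ValueError("simulation span must cover at least 20 years")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


@dataclass
class TruthSurface:
    """Known per-cell-month suitability in [0, 1] (pipeline ground truth)."""

    values: np.ndarray           # (T, ny, nx)
    months: pd.PeriodIndex
    y: np.ndarray
    x: np.ndarray
    window_length: int
    params: dict = field(default_factory=dict)

    def month_index(self, year: int, month: int) -> int:
        p = pd.Period(year=year, month=month, freq="M")
        i = int(p.ordinal - self.months[0].ordinal)
        if not 0 <= i < len(self.months):
            raise IndexError(f"{year}-{month:02d} outside truth months")
        return i


def gen_weather(config: SyntheticConfig) -> ClimateCube:
    """Generate the monthly weather cube.  Identical seeds give identical cubes."""
    rng = np.random.default_rng(config.seed)
    ny, nx = config.grid_rows, config.grid_cols
    years = np.arange(config.start_year, config.end_year + 1)
    T = 12 * years.size
    time = pd.period_range(
        start=f"{config.start_year}-01", periods=T, freq="M"
    )
    months = time.month.to_numpy()
    year_idx = np.repeat(np.arange(years.size), 12)

    # coldest (and wettest) month is July: phase the cycle on month 7
    phase = np.cos(2 * np.pi * (months - 7) / 12.0)  # 1 in July, -1 in January
    # temperature warms south->north, precipitation dries west->east: the
    # two climatic axes are independent so the niche has 2-D spatial
    # structure rather than a single confounded gradient
    gx = np.linspace(0.0, 1.0, nx)[None, :] * np.ones((ny, 1))  # west->east
    gy = np.linspace(0.0, 1.0, ny)[:, None] * np.ones((1, nx))  # south->north

    t_anom = rng.normal(0.0, config.year_temp_sd, size=years.size)
    p_anom = rng.normal(0.0, config.year_precip_sd, size=years.size)
    t_noise = rng.normal(0.0, config.month_temp_sd, size=(T, ny, nx))
    p_noise = rng.normal(0.0, config.month_precip_sd, size=(T, ny, nx))

    tmean = (
        config.tmean_base
        - config.temp_seasonal_amp * phase[:, None, None]
        + config.temp_gradient * gy[None, :, :]
        + t_anom[year_idx][:, None, None]
        + t_noise
    )
    precip_mult = 1.0 + config.precip_gradient * (0.5 - gx)  # wet west, dry east
    precip = (
        (config.precip_base + config.precip_seasonal_amp * phase[:, None, None])
        * precip_mult[None, :, :]
        + p_anom[year_idx][:, None, None]
        + p_noise
    )

    if config.anomaly_window is not None:
        a0, a1 = config.anomaly_window
        in_window = (time.year >= a0) & (time.year <= a1)
        in_winter = np.isin(months, WINTER_MONTHS)
        hit = (in_window & in_winter)[:, None, None]
        tmean = tmean + np.where(hit, config.anomaly_winter_warming, 0.0)
        precip = np.where(hit, precip * config.anomaly_wet_quarter_scale, precip)

    precip = np.clip(precip, 0.0, None)
    return ClimateCube(
        time=time,
        y=np.arange(ny, dtype=float) * np.sqrt(config.cell_area_km2),
        x=np.arange(nx, dtype=float) * np.sqrt(config.cell_area_km2),
        precip=precip,
        tmin=tmean - config.diurnal_down,
        tmax=tmean + config.diurnal_up,
        tmean=tmean,
    )


DEFAULT_TRUTH_PARAMS = {
    "b0": 0.75,       # logit of suitability at average conditions
    "b_tmin": 1.2,    # penalty per SD of warmer coldest-month minimum
    "b_pwq": 1.2,     # penalty per SD of wetter wettest quarter
    "b_annp": 0.4,    # penalty per SD of higher annual precipitation
}


def truth_surface(
    cube: ClimateCube,
    window_length: int = 36,
    params: dict | None = None,
) -> TruthSurface:
    """True suitability: a logistic in three trailing-window covariates.

    Covariates are standardised by their global mean/sd over the cube's
    valid cell-months, so the surface is deterministic given the weather.
    Warmer winter minima, a wetter wettest quarter and higher annual
    precipitation all reduce suitability.
    """
    p = dict(DEFAULT_TRUTH_PARAMS, **(params or {}))
    cc = covariate_cube(cube, window_length)

    def z(name):
        arr = cc[name]
        return (arr - np.nanmean(arr)) / np.nanstd(arr)

    logit = (
        p["b0"]
        - p["b_tmin"] * z("tmin_cold_m")
        - p["b_pwq"] * z("prec_wet_q")
        - p["b_annp"] * z("ann_prec")
    )
    values = 1.0 / (1.0 + np.exp(-logit))
    return TruthSurface(
        values=values,
        months=cc["end_months"],
        y=cube.y,
        x=cube.x,
        window_length=window_length,
        params=p,
    )


def gen_occurrences(
    truth: TruthSurface,
    bias: np.ndarray | None = None,
    n_focal: int = 800,
    n_target_group: int = 1600,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    spotlight_fraction: float = 0.5,
) -> pd.DataFrame:
    """Occurrence records for the focal species and two companions.

    Focal records fall on cell-months with probability proportional to
    ``truth x bias``; companion records follow the spatial bias alone with a
    uniform month.  ``bias`` is a per-cell sampling-effort surface (>= 0,
    uniform by default).  Accuracy fields are generated within the pipeline's
    quality filters; ``source`` marks roughly ``spotlight_fraction`` of the
    records as spotlight sightings.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    T, ny, nx = truth.values.shape
    if bias is None:
        bias = np.ones((ny, nx))
    bias = np.asarray(bias, dtype=float)
    if bias.shape != (ny, nx):
        raise ValueError("bias surface shape mismatch")
    if (bias < 0).any() or not (bias > 0).any():
        raise ValueError("bias must be >= 0 with at least one positive cell")

    def sample(weights: np.ndarray, n: int, species: str) -> pd.DataFrame:
        w = weights.ravel()
        total = w.sum()
        if total <= 0:
            raise ValueError("all-zero sampling weights; cannot generate records")
        idx = rng.choice(w.size, size=n, p=w / total)
        t, iy, ix = np.unravel_index(idx, weights.shape)
        return pd.DataFrame({
            "species": species,
            "lon": truth.x[ix],
            "lat": truth.y[iy],
            "year": truth.months[t].year,
            "month": truth.months[t].month,
            "date_acc_months": rng.integers(0, 2, size=n),
            "loc_acc_km": np.round(rng.uniform(0.0, 5.0, size=n), 2),
            "source": np.where(
                rng.random(n) < spotlight_fraction, "spotlight", "other"
            ),
        })

    focal = sample(truth.values * bias[None, :, :], n_focal, "focal")
    bias_t = np.broadcast_to(bias[None, :, :], (T, ny, nx))
    n1 = n_target_group // 2
    comp1 = sample(bias_t, n1, "companion_1")
    comp2 = sample(bias_t, n_target_group - n1, "companion_2")
    return pd.concat([focal, comp1, comp2], ignore_index=True)


def gen_transects(
    truth: TruthSurface,
    n_regions: int = 8,
    transects_per_region: int = 4,
    years=None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    suppression_start_year: int | None = None,
    suppression_factor: float = 0.4,
    k: float = 40.0,
    dispersion: float = 2.0,
    survey_months: tuple[int, ...] = (1, 2, 3, 4),
    drop_fraction: float = 0.0,
    return_expected: bool = False,
) -> pd.DataFrame:
    """Spotlight transect counts tracking local suitability.

    The grid's columns are tiled into ``n_regions`` contiguous blocks; each
    region holds ``transects_per_region`` transects on distinct random cells.
    The count of transect t in year y is negative binomial with mean
    ``k x (mean truth over its cell in the survey-season months of y)`` and
    dispersion ``dispersion`` (variance mu + mu^2/dispersion — spotlight
    counts are overdispersed).  From ``suppression_start_year`` on, the
    expectation is *held low*: pinned to ``suppression_factor`` times the
    transect's pre-suppression long-run mean, decoupled from suitability.
    ``drop_fraction`` removes random transect-years to exercise the
    complete-panel filters.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    T, ny, nx = truth.values.shape
    if years is None:
        # years whose whole survey season has truth values
        valid = [
            y
            for y in np.unique(truth.months.year)
            if all(
                pd.Period(year=y, month=m, freq="M") in truth.months
                for m in survey_months
            )
        ]
        years = valid
    years = np.asarray(sorted(years), dtype=int)

    # assign transect cells: contiguous column blocks per region
    blocks = np.array_split(np.arange(nx), n_regions)
    records = []
    transect_cells = {}
    for r, cols in enumerate(blocks):
        cells = [(iy, ix) for iy in range(ny) for ix in cols]
        chosen = rng.choice(len(cells), size=transects_per_region, replace=False)
        for j, ci in enumerate(chosen):
            transect_cells[f"R{r}T{j}"] = (r, cells[ci])

    season_idx = {}
    for y in years:
        season_idx[y] = [truth.month_index(y, m) for m in survey_months]

    for tid, (region, (iy, ix)) in transect_cells.items():
        mu_by_year = np.array([
            k * truth.values[season_idx[y], iy, ix].mean() for y in years
        ])
        if suppression_start_year is not None:
            pre = years < suppression_start_year
            if pre.any():
                pinned = suppression_factor * mu_by_year[pre].mean()
            else:
                pinned = suppression_factor * mu_by_year.mean()
            mu_by_year = np.where(pre, mu_by_year, pinned)
        for y, mu in zip(years, mu_by_year):
            if mu <= 0:
                count = 0
            else:
                count = int(rng.negative_binomial(
                    dispersion, dispersion / (dispersion + mu)
                ))
            rec = {"transect": tid, "region": f"region_{region}",
                   "year": int(y), "count": count}
            if return_expected:
                rec["expected"] = float(mu)
            records.append(rec)

    df = pd.DataFrame(records)
    if drop_fraction > 0:
        keep = rng.random(len(df)) >= drop_fraction
        df = df[keep].reset_index(drop=True)
    return df
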