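"""Abundance index, regional change, changepoints and segmented regression.

The abundance index (AI) is the yearly total of spotlight-count sightings
over the fixed panel of transects surveyed in every year of the analysis
span.  Its relationship to the modelled suitable-area series is probed by

* at-most-one-changepoint (AMOC) detection of a shift in mean AI and in the
  area:AI ratio — by default a distribution-free rank-based CUSUM statistic
  (Pettitt-type) with permutation significance, optionally the Gaussian
  mean-change likelihood criterion;
* ordinary least-squares regressions of annual suitable area on ln(AI),
  fitted separately before and after the ratio changepoint (the changepoint
  year belongs to the pre segment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

__all__ = [
    "AbundanceSeries",
    "abundance_index",
    "regional_change",
    "ChangepointResult",
    "changepoint_mean",
    "ratio_changepoint",
    "segmented_regression",
]


@dataclass
class AbundanceSeries:
    """Annual abundance index over a fixed transect panel."""

    years: np.ndarray
    ai: np.ndarray
    panel: list = field(default_factory=list)
    excluded: list = field(default_factory=list)

    def to_series(self) -> pd.Series:
        return pd.Series(self.ai, index=pd.Index(self.years, name="year"), name="ai")


def abundance_index(
    counts: pd.DataFrame, years=None, completeness: str = "every_year"
) -> AbundanceSeries:
    """Total annual sightings over the panel of consistently surveyed transects.

    ``counts`` needs columns (transect, year, count).  The panel keeps only
    transects with a count in every year of ``years`` (default: all years
    present); transects with gaps are excluded and logged.
    """
    if completeness != "every_year":
        raise ValueError("only completeness='every_year' is supported")
    df = counts[["transect", "year", "count"]].copy()
    if years is None:
        years = np.sort(df["year"].unique())
    years = np.asarray(list(years), dtype=int)
    df = df[df["year"].isin(years)]
    tab = df.pivot_table(index="transect", columns="year", values="count",
                         aggfunc="sum")
    tab = tab.reindex(columns=years)
    complete = tab.dropna()
    excluded = sorted(set(tab.index) - set(complete.index))
    if complete.empty:
        raise ValueError("no transect surveyed in every year; empty panel")
    ai = complete.sum(axis=0).to_numpy()
    return AbundanceSeries(
        years=years,
        ai=np.asarray(ai, dtype=float),
        panel=sorted(complete.index),
        excluded=excluded,
    )


def _bin_magnitude(delta: float) -> str:
    a = abs(delta)
    if a < 3:
        return "small"
    if a <= 6:
        return "medium"
    return "large"


def regional_change(
    counts: pd.DataFrame,
    early: tuple[int, int] = (1997, 1999),
    late: tuple[int, int] = (2007, 2009),
) -> pd.DataFrame:
    """Per-region change in mean annual sightings between two 3-year periods.

    For each transect the mean annual count over ``early`` and ``late`` is
    differenced; transect differences are summed per region.  Only transects
    surveyed in all six years enter.  Regions with no detections across both
    periods, or with a change of exactly zero, are excluded with a reason.
    Magnitude bins: small < 3, medium 3-6, large > 6 sightings.
    """
    need = {"transect", "region", "year", "count"}
    if not need.issubset(counts.columns):
        raise ValueError(f"counts must have columns {sorted(need)}")
    span = list(range(early[0], early[1] + 1)) + list(range(late[0], late[1] + 1))
    df = counts[counts["year"].isin(span)]
    tab = df.pivot_table(index="transect", columns="year", values="count",
                         aggfunc="sum").reindex(columns=span)
    complete = tab.dropna()
    early_cols = list(range(early[0], early[1] + 1))
    late_cols = list(range(late[0], late[1] + 1))
    per_transect = pd.DataFrame({
        "early_mean": complete[early_cols].mean(axis=1),
        "late_mean": complete[late_cols].mean(axis=1),
    })
    per_transect["delta"] = per_transect["late_mean"] - per_transect["early_mean"]
    region_of = counts.drop_duplicates("transect").set_index("transect")["region"]
    per_transect["region"] = region_of.reindex(per_transect.index)

    rows = []
    for region, grp in per_transect.groupby("region", sort=True):
        delta = float(grp["delta"].sum())
        total = float(grp["early_mean"].sum() + grp["late_mean"].sum())
        excluded, reason = False, ""
        if total == 0:
            excluded, reason = True, "no detections in the region"
        elif delta == 0:
            excluded, reason = True, "no change in the AI"
        rows.append({
            "region": region,
            "delta": delta,
            "direction": "increase" if delta > 0 else "decrease",
            "magnitude": _bin_magnitude(delta),
            "n_transects": len(grp),
            "excluded": excluded,
            "reason": reason,
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
@dataclass
class ChangepointResult:
    """Single (at-most-one) changepoint in a series' mean.

    ``k`` is the size of the pre segment; ``label`` is the label (year) of the
    last pre-segment observation when labels are supplied.
    """

    k: int
    label: object
    pre_mean: float
    pre_se: float
    post_mean: float
    post_se: float
    statistic: float
    p_value: float
    significant: bool
    method: str

    def summary(self) -> str:
        lab = f" (after {self.label})" if self.label is not None else ""
        return (
            f"changepoint at position {self.k}{lab} [{self.method}]\n"
            f"  pre  mean {self.pre_mean:.3f} +/- {self.pre_se:.3f} (se, n={self.k})\n"
            f"  post mean {self.post_mean:.3f} +/- {self.post_se:.3f} (se)\n"
            f"  statistic {self.statistic:.3f}, permutation P = {self.p_value:.4f}"
            f" ({'significant' if self.significant else 'not significant'})"
        )


def _split_statistics(x: np.ndarray, method: str) -> np.ndarray:
    """Statistic for every split k = 1..n-1 (larger = stronger shift)."""
    n = x.size
    k = np.arange(1, n)
    if method == "rank_cusum":
        # rank CUSUM standardised by its null variance profile ~ k(n-k):
        # without the standardisation the raw statistic is biased towards
        # balanced splits and mislocalises asymmetric shifts
        r = rankdata(x)
        u = 2.0 * np.cumsum(r)[:-1] - k * (n + 1)
        return np.abs(u) / np.sqrt(k * (n - k))
    if method == "gaussian":
        cs = np.cumsum(x)
        s1 = cs[:-1]
        s2 = cs[-1] - s1
        # between-segment sum of squares: the likelihood-gain criterion
        return s1**2 / k + s2**2 / (n - k) - cs[-1] ** 2 / n
    raise ValueError(f"unknown changepoint method {method!r}")


def changepoint_mean(
    series,
    method: str = "rank_cusum",
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    labels=None,
) -> ChangepointResult:
    """At-most-one changepoint in the mean of a series.

    The split maximising the criterion over all n-1 candidate positions is
    returned (earliest split on exact ties); significance comes from
    ``n_permutations`` random reorderings of the series (P = fraction of
    permuted maxima at least as large, with the +1 correction).
    """
    if isinstance(series, pd.Series):
        labels = series.index.to_numpy() if labels is None else labels
        x = series.to_numpy(dtype=float)
    else:
        x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("changepoint detection needs a series of length >= 4")
    stats = _split_statistics(x, method)
    k = int(np.argmax(stats)) + 1
    obs = float(stats[k - 1])

    if rng is None:
        rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(x)
        if _split_statistics(perm, method).max() >= obs - 1e-12:
            exceed += 1
    p_value = (1.0 + exceed) / (n_permutations + 1.0)

    pre, post = x[:k], x[k:]

    def se(v):
        return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")

    return ChangepointResult(
        k=k,
        label=None if labels is None else labels[k - 1],
        pre_mean=float(pre.mean()),
        pre_se=se(pre),
        post_mean=float(post.mean()),
        post_se=se(post),
        statistic=obs,
        p_value=float(p_value),
        significant=bool(p_value <= alpha),
        method=method,
    )


def ratio_changepoint(
    area_annual: pd.Series,
    ai: pd.Series | AbundanceSeries,
    **kwargs,
) -> ChangepointResult:
    """Changepoint in the yearly ratio (suitable area) / (abundance index).

    Restricted to common years; zero-AI years are excluded with a warning
    (the ratio is undefined there).
    """
    if isinstance(ai, AbundanceSeries):
        ai = ai.to_series()
    common = area_annual.index.intersection(ai.index)
    area = area_annual.loc[common]
    ai = ai.loc[common]
    nz = ai > 0
    if (~nz).any():
        warnings.warn(
            f"excluding {int((~nz).sum())} zero-AI year(s) from the ratio",
            stacklevel=2,
        )
    ratio = (area[nz] / ai[nz]).rename("area_ai_ratio")
    if len(ratio) < 4:
        raise ValueError("fewer than 4 usable common years for the ratio")
    return changepoint_mean(ratio, **kwargs)


def segmented_regression(
    area_annual: pd.Series,
    ai: pd.Series | AbundanceSeries,
    changepoint_year: int,
    cp_in: str = "pre",
) -> dict[str, dict]:
    """Pre/post OLS of annual suitable area on ln(AI).

    The AI is natural-log transformed to stabilise its variance.  With
    ``cp_in='pre'`` (default) the changepoint year closes the pre segment.
    Each segment needs >= 3 years.  Returns per-segment slope, intercept,
    r-squared, F with (1, n-2) df and its two-sided P.
    """
    if isinstance(ai, AbundanceSeries):
        ai = ai.to_series()
    common = area_annual.index.intersection(ai.index)
    area = area_annual.loc[common].astype(float)
    ai = ai.loc[common].astype(float)
    nz = ai > 0
    if (~nz).any():
        warnings.warn(
            f"excluding {int((~nz).sum())} zero-AI year(s) from the regression",
            stacklevel=2,
        )
        area, ai = area[nz], ai[nz]
    years = np.asarray(common[nz] if (~nz).any() else common)
    if cp_in == "pre":
        pre_mask = years <= changepoint_year
    elif cp_in == "post":
        pre_mask = years < changepoint_year
    else:
        raise ValueError("cp_in must be 'pre' or 'post'")

    out = {}
    for name, mask in (("pre", pre_mask), ("post", ~pre_mask)):
        if mask.sum() < 3:
            raise ValueError(
                f"{name} segment has {int(mask.sum())} years; need >= 3"
            )
        y = area[mask].to_numpy()
        X = sm.add_constant(np.log(ai[mask].to_numpy()))
        fit = sm.OLS(y, X).fit()
        out[name] = {
            "slope": float(fit.params[1]),
            "intercept": float(fit.params[0]),
            "r2": float(fit.rsquared),
            "F": float(fit.fvalue),
            "df": (int(fit.df_model), int(fit.df_resid)),
            "p": float(fit.f_pvalue),
            "n": int(mask.sum()),
            "years": [int(v) for v in years[mask]],
        }
    return out
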