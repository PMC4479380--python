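"""Target-group background sampling.

Presence-only models need a sample of the *available* environment.  Drawing
that sample uniformly in space confounds the model with survey effort; a
target-group background instead draws from the occurrence records of species
surveyed by the same methods (the focal species included), so the background
inherits exactly the presence data's spatio-temporal sampling bias.

Each background point is an i.i.d. draw, with replacement, from the empirical
distribution over the unique (location, year, month) triples of the prepared
target-group records, weighted by record multiplicity — "in direct proportion
to both the temporal and spatial distribution" of the group's records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .climate import ClimateCube
from .occurrences import OccurrenceSet, stamp_covariates

__all__ = ["build_target_group_background", "stamp_background"]


def build_target_group_background(
    target_records: pd.DataFrame | OccurrenceSet,
    n: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample ``n`` background points from the target-group record distribution.

    Rows are drawn uniformly with replacement from the prepared target-group
    records, which weights every unique (lon, lat, year, month) triple by its
    multiplicity.  Returns a DataFrame with columns lon, lat, year, month.
    """
    if isinstance(target_records, OccurrenceSet):
        target_records = target_records.records
    if len(target_records) == 0:
        raise ValueError("target group is empty; cannot build background")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(target_records), size=n)
    cols = ["lon", "lat", "year", "month"]
    out = target_records.iloc[idx][cols].reset_index(drop=True)
    return out


def stamp_background(
    background: pd.DataFrame,
    cube: ClimateCube,
    window_lengths: tuple[int, ...] = (12, 36),
    precomputed: dict[int, dict] | None = None,
) -> tuple[pd.DataFrame, list]:
    """Covariate-stamp background points, deduplicating repeated triples.

    Background samples repeat the same (location, year, month) triple many
    times; covariates are computed once per unique triple and broadcast back,
    which is exact and much cheaper than stamping row by row.
    """
    cols = ["lon", "lat", "year", "month"]
    uniq, inverse = np.unique(
        background[cols].to_numpy(float), axis=0, return_inverse=True
    )
    uniq_df = pd.DataFrame(uniq, columns=cols)
    uniq_df["year"] = uniq_df["year"].astype(int)
    uniq_df["month"] = uniq_df["month"].astype(int)
    stamped, log = stamp_covariates(
        uniq_df, cube, window_lengths=window_lengths, precomputed=precomputed
    )
    if len(stamped) < len(uniq_df):
        # map retained unique triples back; dropped triples drop their copies
        key = ["lon", "lat", "year", "month"]
        merged = background.merge(stamped, on=key, how="inner")
        return merged.reset_index(drop=True), log
    out = stamped.iloc[inverse].reset_index(drop=True)
    return out, log
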