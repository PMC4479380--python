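"""Synthetic island generators: weather structure, occurrence sampling,
transect counts, and their documented statistical properties."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest, chisquare, pearsonr

from weathersdm import (
    SyntheticConfig,
    changepoint_mean,
    gen_occurrences,
    gen_transects,
    gen_weather,
    truth_surface,
)
from weathersdm.synthetic import WINTER_MONTHS


def small_config(**kw):
    base = dict(grid_rows=10, grid_cols=10, start_year=1980, end_year=1999, seed=0)
    base.update(kw)
    return SyntheticConfig(**base)


def coldest_month_tmin_by_year(cube):
    """Per cell and year, the minimum monthly tmin (T years, ny, nx)."""
    ny_years = len(cube.time) // 12
    return cube.tmin.reshape(ny_years, 12, *cube.tmin.shape[1:]).min(axis=1)


class TestGenWeather:
    def test_same_seed_identical(self):
        a, b = gen_weather(small_config()), gen_weather(small_config())
        for name in ("precip", "tmin", "tmax", "tmean"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_physical_ordering_and_nonnegative_precip(self):
        cube = gen_weather(small_config(seed=5))
        assert (cube.tmin <= cube.tmean).all()
        assert (cube.tmean <= cube.tmax).all()
        assert (cube.precip >= 0).all()

    def test_seasonal_cycle_winter_cold_and_wet(self):
        cube = gen_weather(small_config(seed=2, anomaly_window=None))
        month = cube.time.month.to_numpy()
        winter = np.isin(month, WINTER_MONTHS)
        summer = np.isin(month, (12, 1, 2))
        assert cube.tmean[winter].mean() < cube.tmean[summer].mean() - 5
        assert cube.precip[winter].mean() > cube.precip[summer].mean() + 20

    def test_null_anomaly_leaves_climatology_unchanged(self):
        cfg = small_config(
            anomaly_window=(1990, 1992), anomaly_winter_warming=0.0,
            anomaly_wet_quarter_scale=1.0,
        )
        cube = gen_weather(cfg)
        years = cube.time.year.to_numpy().reshape(-1, 12)[:, 0]
        per_year = coldest_month_tmin_by_year(cube).mean(axis=(1, 2))
        inside = np.isin(years, (1990, 1991, 1992))
        # only interannual noise separates the window from the rest
        assert abs(per_year[inside].mean() - per_year[~inside].mean()) < 1.0

    def test_winter_warming_shifts_coldest_month_minimum(self):
        # mean coldest-month tmin inside the window exceeds the outside mean
        # by the imposed warming, up to Monte-Carlo error over 20 seeds
        diffs = []
        for seed in range(20):
            cfg = small_config(
                seed=seed, anomaly_window=(1990, 1992),
                anomaly_winter_warming=2.0, anomaly_wet_quarter_scale=1.0,
            )
            cube = gen_weather(cfg)
            years = cube.time.year.to_numpy().reshape(-1, 12)[:, 0]
            per_year = coldest_month_tmin_by_year(cube).mean(axis=(1, 2))
            inside = np.isin(years, (1990, 1991, 1992))
            diffs.append(per_year[inside].mean() - per_year[~inside].mean())
        assert np.mean(diffs) == pytest.approx(2.0, abs=0.3)

    def test_wet_quarter_scaling(self):
        cfg = small_config(
            anomaly_window=(1990, 1992), anomaly_winter_warming=0.0,
            anomaly_wet_quarter_scale=2.0,
        )
        cube = gen_weather(cfg)
        month = cube.time.month.to_numpy()
        year = cube.time.year.to_numpy()
        winter = np.isin(month, WINTER_MONTHS)
        inside = (year >= 1990) & (year <= 1992)
        ratio = (cube.precip[winter & inside].mean()
                 / cube.precip[winter & ~inside].mean())
        assert ratio == pytest.approx(2.0, abs=0.2)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError, match="10 x 10"):
            small_config(grid_rows=5)
        with pytest.raises(ValueError, match="20 years"):
            small_config(end_year=1990)


class TestTruthSurface:
    def test_values_in_unit_interval_and_deterministic(self):
        cube = gen_weather(small_config())
        t1 = truth_surface(cube, 12)
        t2 = truth_surface(cube, 12)
        assert (t1.values >= 0).all() and (t1.values <= 1).all()
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_warm_wet_excursion_lowers_truth(self):
        cfg = small_config(anomaly_window=(1992, 1994),
                           anomaly_winter_warming=2.0,
                           anomaly_wet_quarter_scale=1.5)
        truth = truth_surface(gen_weather(cfg), 12)
        s = pd.Series(truth.values.mean(axis=(1, 2)), index=truth.months)
        ann = s.groupby(s.index.year).mean()
        window = ann.loc[1993:1995].mean()  # lagged by the trailing window
        outside = ann.drop(range(1992, 1996)).mean()
        assert window < outside - 0.1


class TestGenOccurrences:
    def make_truth(self, values, months=None):
        from weathersdm.synthetic import TruthSurface

        T, ny, nx = values.shape
        months = months or pd.period_range("1990-01", periods=T, freq="M")
        return TruthSurface(values=values, months=months,
                            y=np.arange(ny) * 5.0, x=np.arange(nx) * 5.0,
                            window_length=12)

    def test_uniform_truth_uniform_bias_gives_uniform_cells(self):
        truth = self.make_truth(np.ones((12, 4, 4)))
        occ = gen_occurrences(truth, n_focal=8000, n_target_group=0, seed=0)
        counts = occ.groupby(["lat", "lon"]).size()
        stat, p = chisquare(counts.reindex(
            pd.MultiIndex.from_product([np.arange(4) * 5.0] * 2), fill_value=0))
        assert p > 0.001

    def test_degenerate_bias_concentrates_records(self):
        truth = self.make_truth(np.ones((12, 4, 4)))
        bias = np.zeros((4, 4))
        bias[2, 3] = 1.0
        occ = gen_occurrences(truth, bias=bias, n_focal=200,
                              n_target_group=100, seed=0)
        assert (occ["lat"] == 10.0).all() and (occ["lon"] == 15.0).all()

    def test_two_region_ratio_binomial(self):
        # truth 0.8 in the left half, 0.2 in the right -> 4:1 record ratio
        values = np.full((12, 4, 4), 0.2)
        values[:, :, :2] = 0.8
        truth = self.make_truth(values)
        occ = gen_occurrences(truth, n_focal=2000, n_target_group=0, seed=1)
        n_left = int((occ["lon"] < 10.0).sum())
        assert binomtest(n_left, 2000, 0.8).pvalue > 0.001

    def test_companions_follow_bias_not_truth(self, rng):
        # effort-corrected companion density should be uncorrelated with
        # truth; a single draw's null correlation has sd ~ 1/sqrt(cells-2),
        # so the check averages over replicate seeds
        values = np.broadcast_to(
            rng.uniform(0.05, 1.0, (1, 6, 6)), (24, 6, 6)
        ).copy()
        truth = self.make_truth(values)
        bias = rng.uniform(0.2, 1.0, (6, 6))
        order = np.lexsort((np.tile(truth.x, 6), np.repeat(truth.y, 6)))
        rhos = []
        for seed in range(8):
            occ = gen_occurrences(truth, bias=bias, n_focal=10,
                                  n_target_group=10_000, seed=seed)
            comp = occ[occ["species"] != "focal"]
            density = comp.groupby(["lat", "lon"]).size().to_numpy(float)
            rate = density / bias.ravel()[order]
            rho, _ = pearsonr(rate, values[0].ravel()[order])
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_all_zero_weights_error(self):
        truth = self.make_truth(np.zeros((12, 4, 4)))
        with pytest.raises(ValueError, match="zero"):
            gen_occurrences(truth, n_focal=10, n_target_group=0, seed=0)

    def test_same_seed_identical(self):
        truth = self.make_truth(np.ones((12, 4, 4)))
        a = gen_occurrences(truth, n_focal=100, n_target_group=50, seed=9)
        b = gen_occurrences(truth, n_focal=100, n_target_group=50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_focal_density_tracks_truth_times_bias(self, rng):
        values = np.broadcast_to(
            rng.uniform(0.1, 1.0, (1, 5, 5)), (12, 5, 5)
        ).copy()
        truth = self.make_truth(values)
        bias = rng.uniform(0.5, 2.0, (5, 5))
        occ = gen_occurrences(truth, bias=bias, n_focal=10_000,
                              n_target_group=0, seed=4)
        counts = (
            occ.groupby(["lat", "lon"]).size()
            .reindex(pd.MultiIndex.from_product(
                [np.arange(5) * 5.0, np.arange(5) * 5.0]), fill_value=0)
            .to_numpy(float)
        )
        w = (values[0] * bias).ravel()
        expected = 10_000 * w / w.sum()
        stat, p = chisquare(counts, expected)
        assert p > 0.001


class TestGenTransects:
    def make_truth(self, values):
        from weathersdm.synthetic import TruthSurface

        T, ny, nx = values.shape
        return TruthSurface(values=values,
                            months=pd.period_range("1990-01", periods=T, freq="M"),
                            y=np.arange(ny) * 5.0, x=np.arange(nx) * 5.0,
                            window_length=12)

    def test_zero_rate_gives_zero_counts(self):
        truth = self.make_truth(np.ones((60, 10, 10)))
        counts = gen_transects(truth, n_regions=2, transects_per_region=3,
                               seed=0, k=0.0)
        assert (counts["count"] == 0).all()

    def test_counts_overdispersed(self):
        truth = self.make_truth(np.ones((240, 10, 10)))
        counts = gen_transects(truth, n_regions=2, transects_per_region=5,
                               seed=1, k=20.0, dispersion=2.0)
        g = counts.groupby("transect")["count"]
        # NB(mu=20, size=2): variance = mu + mu^2/2 = 220 >> mu
        assert g.var().mean() > 3 * g.mean().mean()

    def test_stationary_truth_no_changepoint_under_null(self):
        # the changepoint stage should find no significant shift at alpha=.05
        # in >= 90% of replicate null series
        truth = self.make_truth(np.full((240, 10, 10), 0.5))
        hits = 0
        n = 60
        for seed in range(n):
            counts = gen_transects(truth, n_regions=3, transects_per_region=3,
                                   seed=seed, k=20.0)
            ai = counts.groupby("year")["count"].sum()
            res = changepoint_mean(ai, n_permutations=199, seed=seed)
            hits += res.significant
        assert hits / n <= 0.10

    def test_suppression_scales_posterior_means(self):
        # factor 0.4 from year 15 of 20 -> post/pre mean ratio ~= 0.4
        truth = self.make_truth(np.full((240, 10, 10), 0.5))
        ratios = []
        for seed in range(50):
            counts = gen_transects(
                truth, n_regions=2, transects_per_region=4, seed=seed,
                k=30.0, suppression_start_year=2004, suppression_factor=0.4,
            )
            pre = counts[counts["year"] < 2004]["count"].mean()
            post = counts[counts["year"] >= 2004]["count"].mean()
            ratios.append(post / pre)
        assert np.mean(ratios) == pytest.approx(0.4, abs=0.05)

    def test_dropped_years_thin_the_table(self):
        truth = self.make_truth(np.ones((240, 10, 10)))
        full = gen_transects(truth, seed=3)
        thinned = gen_transects(truth, seed=3, drop_fraction=0.2)
        assert len(thinned) < len(full)

    def test_same_seed_identical(self):
        truth = self.make_truth(np.ones((120, 10, 10)))
        a = gen_transects(truth, seed=11)
        b = gen_transects(truth, seed=11)
        pd.testing.assert_frame_equal(a, b)
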