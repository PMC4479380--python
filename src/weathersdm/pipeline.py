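"""End-to-end orchestration: weather -> SDM -> projection -> abundance.

:func:`run_full_model` executes the whole analysis from a single declarative
:class:`RunConfig`: generate (or load) the monthly weather cube, prepare and
covariate-stamp occurrences, build the bias-matched target-group background,
fit the maximum-entropy model (16-covariate window selection, correlation
screen, final fit, cross-validation), project it onto every month, binarise
to core habitat, and relate the suitable-area series to the abundance index
via changepoints and segmented regression.

:func:`run_independent_model` repeats the analysis with spotlight-sourced
records removed from both the focal occurrence set and the target group, so
the suitable-area series is independent of the spotlight counts in the AI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import background as bg
from . import maxent as mx
from . import occurrences as occ
from . import projection as pj
from .climate import ClimateCube
from .covariates import COVARIATE_NAMES, covariate_cube
from .synthetic import (
    SyntheticConfig,
    TruthSurface,
    gen_occurrences,
    gen_transects,
    truth_surface,
)

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_full_model",
    "run_independent_model",
    "headline_scenario_config",
]


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0

    # synthetic inputs
    n_focal: int = 800
    n_target_group: int = 1600
    truth_window: int = 36
    truth_params: dict | None = None
    n_transect_regions: int = 8
    transects_per_region: int = 4
    transect_k: float = 40.0
    transect_dispersion: float = 2.0

    # optional file inputs (override synthetic generation)
    weather_path: str | None = None
    occurrences_path: str | None = None
    transects_path: str | None = None

    # occurrence preparation
    max_date_acc: float = 1.0
    max_loc_acc_km: float = 10.0
    year_range: tuple[int, int] | None = None
    dedupe_radius_km: float = 5.0
    distance_metric: str = "euclidean"

    # model
    window_lengths: tuple[int, ...] = (12, 36)
    background_n: int = 10_000
    beta_multiplier: float = 1.0
    k_folds: int = 10
    do_cv: bool = True
    do_window_selection: bool = True
    correlation_threshold: float = 0.85

    # projection / abundance
    annual_stat: str = "mean"
    ai_years: tuple[int, int] | None = None
    changepoint_method: str = "rank_cusum"
    n_permutations: int = 999
    alpha: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Artifact bundle of one pipeline run."""

    config: RunConfig
    cube: ClimateCube
    truth: TruthSurface | None
    occurrences: pd.DataFrame
    transects: pd.DataFrame
    presence_table: pd.DataFrame
    background_table: pd.DataFrame
    window_choice: dict | None
    window_table: pd.DataFrame | None
    correlations: pd.DataFrame
    model_results: mx.MaxentResults
    eval_report: mx.EvalReport | None
    importance: pd.Series
    threshold: float
    suitability: np.ndarray
    suitability_months: pd.PeriodIndex
    composite: np.ndarray
    area: pj.AreaSeries
    ai: ab.AbundanceSeries
    cp_ai: ab.ChangepointResult
    cp_ratio: ab.ChangepointResult
    regression: dict
    regional: pd.DataFrame
    prep_log: list

    def manifest(self) -> dict:
        return {
            "config_digest": self.config.digest(),
            "n_presences": int(len(self.presence_table)),
            "n_background": int(len(self.background_table)),
            "covariates": list(self.model_results.model.covariates),
            "threshold": self.threshold,
            "cv_auc": None if self.eval_report is None else
                [self.eval_report.mean_auc, self.eval_report.sd_auc],
            "ai_changepoint_year": _as_int(self.cp_ai.label),
            "ratio_changepoint_year": _as_int(self.cp_ratio.label),
        }

    def report(self) -> dict:
        """Flat numeric summary of the run's headline quantities."""
        ann = self.area.annual_values(self.config.annual_stat)
        out = {
            "threshold": self.threshold,
            "mean_area_km2": float(ann.mean()),
            "min_area_km2": float(self.area.monthly["area_km2"].min()),
            "max_area_km2": float(self.area.monthly["area_km2"].max()),
            "ai_changepoint_year": _as_int(self.cp_ai.label),
            "ai_pre_mean": self.cp_ai.pre_mean,
            "ai_post_mean": self.cp_ai.post_mean,
            "ai_changepoint_p": self.cp_ai.p_value,
            "ratio_changepoint_year": _as_int(self.cp_ratio.label),
            "ratio_changepoint_p": self.cp_ratio.p_value,
            "pre_r2": self.regression["pre"]["r2"],
            "pre_p": self.regression["pre"]["p"],
            "pre_slope": self.regression["pre"]["slope"],
            "post_r2": self.regression["post"]["r2"],
            "post_p": self.regression["post"]["p"],
        }
        if self.eval_report is not None:
            out["cv_auc_mean"] = self.eval_report.mean_auc
            out["cv_auc_sd"] = self.eval_report.sd_auc
        return out

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cube.to_netcdf(outdir / "weather.nc")
        self.occurrences.to_csv(outdir / "occurrences.csv", index=False)
        self.transects.to_csv(outdir / "transects.csv", index=False)
        self.presence_table.to_csv(outdir / "presence_table.csv", index=False)
        self.background_table.to_csv(outdir / "background_table.csv", index=False)
        self.area.monthly.to_csv(outdir / "area_monthly.csv", index=False)
        self.area.annual.to_csv(outdir / "area_annual.csv", index=False)
        self.regional.to_csv(outdir / "regional_change.csv", index=False)
        self.correlations.to_csv(outdir / "correlation_screen.csv", index=False)
        if self.window_table is not None:
            self.window_table.to_csv(outdir / "window_selection.csv", index=False)
        np.savetxt(outdir / "composite_suitability.txt", self.composite)
        self.model_results.to_json(outdir / "model.json")
        with open(outdir / "report.json", "w") as fh:
            json.dump({"manifest": self.manifest(), "report": self.report(),
                       "prep_log": self.prep_log}, fh, indent=1, default=str)


def _as_int(v):
    return None if v is None else int(v)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _prepare_species(records: pd.DataFrame, config: RunConfig):
    """Filter + dedupe each species separately, concatenating results."""
    parts, logs = [], []
    for sp, grp in records.groupby("species", sort=True):
        prepared = occ.prepare_records(
            grp,
            max_date_acc=config.max_date_acc,
            max_loc_acc_km=config.max_loc_acc_km,
            year_range=config.year_range,
            radius_km=config.dedupe_radius_km,
            metric=config.distance_metric,
        )
        parts.append(prepared.records)
        logs.append({"species": sp, "log": prepared.log})
    return pd.concat(parts, ignore_index=True), logs


def run_full_model(
    config: RunConfig,
    outdir=None,
    occurrences: pd.DataFrame | None = None,
    transects: pd.DataFrame | None = None,
    cube: ClimateCube | None = None,
) -> PipelineResult:
    """Execute the whole pipeline; see module docstring for the stages."""
    seeds = _spawn_seeds(config.seed, 6)

    # --- inputs -------------------------------------------------------
    truth = None
    if cube is None:
        if config.weather_path:
            cube = ClimateCube.from_netcdf(config.weather_path)
        else:
            cube = gen_weather_for(config)
    if occurrences is None:
        if config.occurrences_path:
            occurrences = pd.read_csv(config.occurrences_path)
        else:
            truth = truth_surface(cube, config.truth_window, config.truth_params)
            occurrences = gen_occurrences(
                truth,
                n_focal=config.n_focal,
                n_target_group=config.n_target_group,
                rng=np.random.default_rng(seeds[0]),
            )
    if transects is None:
        if config.transects_path:
            transects = pd.read_csv(config.transects_path)
        else:
            if truth is None:
                truth = truth_surface(cube, config.truth_window, config.truth_params)
            transects = gen_transects(
                truth,
                n_regions=config.n_transect_regions,
                transects_per_region=config.transects_per_region,
                rng=np.random.default_rng(seeds[1]),
                suppression_start_year=config.synthetic.suppression_start_year,
                suppression_factor=config.synthetic.suppression_factor,
                k=config.transect_k,
                dispersion=config.transect_dispersion,
            )

    # --- occurrence preparation --------------------------------------
    prepared, prep_log = _prepare_species(occurrences, config)
    focal = prepared[prepared["species"] == "focal"]
    if focal.empty:
        raise ValueError("no focal-species records after preparation")

    cov_cubes = {L: covariate_cube(cube, L) for L in config.window_lengths}
    presence_table, stamp_log = occ.stamp_covariates(
        focal, cube, config.window_lengths, precomputed=cov_cubes
    )
    prep_log.append({"species": "focal", "log": stamp_log})

    # --- target-group background -------------------------------------
    points = bg.build_target_group_background(
        prepared, n=config.background_n,
        rng=np.random.default_rng(seeds[2]),
    )
    background_table, bg_log = bg.stamp_background(
        points, cube, config.window_lengths, precomputed=cov_cubes
    )
    prep_log.append({"species": "background", "log": bg_log})

    # --- covariate choice --------------------------------------------
    window_choice = window_table = None
    if config.do_window_selection and len(config.window_lengths) == 2:
        window_choice, window_table = mx.select_window_per_variable(
            presence_table, background_table,
            window_lengths=tuple(config.window_lengths),
            seed=seeds[3],
            beta_multiplier=config.beta_multiplier,
        )
        chosen = [window_choice[b] for b in sorted(window_choice)]
    else:
        L = config.window_lengths[0]
        chosen = [f"{name}_{L}m" for name in COVARIATE_NAMES]

    correlations = mx.correlation_screen(
        presence_table, background_table,
        threshold=config.correlation_threshold, columns=chosen,
    )

    # --- final fit and evaluation ------------------------------------
    model = mx.MaxentModel(
        presence_table[chosen], background_table[chosen], covariates=chosen,
        beta_multiplier=config.beta_multiplier,
    )
    results = model.fit()
    importance = mx.permutation_importance(results, seed=seeds[4])
    eval_report = None
    if config.do_cv:
        eval_report = mx.cross_validate(
            presence_table[chosen], background_table[chosen],
            k=config.k_folds, seed=seeds[4],
            beta_multiplier=config.beta_multiplier,
        )
        eval_report.importance = importance
        eval_report.correlations = correlations

    score_p, score_b = results.training_scores()
    threshold = pj.equal_ss_threshold(score_p, score_b)

    # --- monthly projection ------------------------------------------
    max_len = max(config.window_lengths)
    months = cube.time[max_len:]
    stacks = {}
    for col in chosen:
        base, suffix = col.rsplit("_", 1)
        L = int(suffix[:-1])
        offset = max_len - L
        stacks[col] = cov_cubes[L][base][offset:]
    suitability = pj.project_series(results, stacks)
    composite = pj.composite_mean(suitability)
    binary = pj.binary_surface(suitability, threshold)
    area = pj.area_series(binary, months, config.synthetic.cell_area_km2)

    # --- abundance analysis ------------------------------------------
    years = None
    if config.ai_years is not None:
        years = range(config.ai_years[0], config.ai_years[1] + 1)
    ai = ab.abundance_index(transects, years=years)
    annual = area.annual_values(config.annual_stat)
    annual = annual[annual.index.isin(ai.years)]
    cp_kwargs = dict(
        method=config.changepoint_method,
        n_permutations=config.n_permutations,
        alpha=config.alpha,
    )
    cp_ai = ab.changepoint_mean(ai.to_series(), seed=seeds[5], **cp_kwargs)
    cp_ratio = ab.ratio_changepoint(annual, ai, seed=seeds[5], **cp_kwargs)
    regression = ab.segmented_regression(annual, ai, int(cp_ratio.label))

    ai_years = ai.years
    early = (int(ai_years[0] + 7), int(ai_years[0] + 9))
    late = (int(ai_years[-1] - 2), int(ai_years[-1]))
    regional = ab.regional_change(transects, early=early, late=late)

    result = PipelineResult(
        config=config, cube=cube, truth=truth, occurrences=occurrences,
        transects=transects, presence_table=presence_table,
        background_table=background_table, window_choice=window_choice,
        window_table=window_table, correlations=correlations,
        model_results=results, eval_report=eval_report, importance=importance,
        threshold=threshold, suitability=suitability,
        suitability_months=months, composite=composite, area=area, ai=ai,
        cp_ai=cp_ai, cp_ratio=cp_ratio, regression=regression,
        regional=regional, prep_log=prep_log,
    )
    if outdir is not None:
        result.save(outdir)
    return result


def gen_weather_for(config: RunConfig) -> ClimateCube:
    from .synthetic import gen_weather

    return gen_weather(config.synthetic)


def run_independent_model(
    config: RunConfig,
    full_result: PipelineResult | None = None,
    outdir=None,
) -> tuple[PipelineResult, dict]:
    """Re-run the pipeline with spotlight records removed from presences and
    target group; returns (independent result, comparison with full model)."""
    if full_result is None:
        full_result = run_full_model(config)
    records = full_result.occurrences
    if "source" not in records.columns:
        raise ValueError("occurrence records carry no source flags")
    kept = records[records["source"] != "spotlight"].reset_index(drop=True)
    if kept[kept["species"] == "focal"].empty:
        raise ValueError("no non-spotlight focal records; cannot build "
                         "independent model")
    independent = run_full_model(
        config, outdir=outdir, occurrences=kept,
        transects=full_result.transects, cube=full_result.cube,
    )
    both = np.isfinite(full_result.composite) & np.isfinite(independent.composite)
    comp_corr = float(np.corrcoef(
        full_result.composite[both], independent.composite[both]
    )[0, 1])
    comparison = {
        "full_auc": None if full_result.eval_report is None
            else full_result.eval_report.mean_auc,
        "independent_auc": None if independent.eval_report is None
            else independent.eval_report.mean_auc,
        "full_importance": full_result.importance.to_dict(),
        "independent_importance": independent.importance.to_dict(),
        "composite_correlation": comp_corr,
        "n_presence_full": int(len(full_result.presence_table)),
        "n_presence_independent": int(len(independent.presence_table)),
    }
    if outdir is not None:
        with open(Path(outdir) / "independent_comparison.json", "w") as fh:
            json.dump(comparison, fh, indent=1)
    return independent, comparison


def headline_scenario_config(
    seed: int = 0,
    excursion: tuple[int, int] = (1998, 2000),
    suppression_start_year: int = 2001,
) -> RunConfig:
    """Compact decline scenario: a 3-year unfavourable weather excursion
    followed by persistent count suppression.

    A 12 x 12 island over 1988-2009 keeps a full fit-project-analyse cycle
    fast enough to replicate across many seeds while retaining the structure
    of interest: suitability (and hence expected counts) dips through the
    excursion, and from ``suppression_start_year`` the counts are held low
    regardless of the recovered suitability.  Truth responds to 12-month
    windows so the timing of the dip is sharp, and the island's climatic
    gradients are steep relative to the interannual anomalies so the
    suitable-area series responds gradually rather than all-or-nothing to
    island-wide weather swings.

    Because counts respond to truth in the summer survey season, the first
    abundance-index year affected by the excursion is ``excursion[0] + 1``;
    the expected changepoint labels (last pre-shift year) are therefore
    ``excursion[0]`` for the AI and ``suppression_start_year - 1`` for the
    area:AI ratio.
    """
    syn = SyntheticConfig(
        grid_rows=12, grid_cols=12,
        start_year=1988, end_year=2009,
        seed=seed,
        anomaly_window=excursion,
        anomaly_winter_warming=2.0,
        anomaly_wet_quarter_scale=1.5,
        suppression_start_year=suppression_start_year,
        suppression_factor=0.4,
        temp_gradient=6.0,
        precip_gradient=1.2,
        year_temp_sd=0.35,
        year_precip_sd=7.0,
    )
    return RunConfig(
        synthetic=syn,
        seed=seed,
        n_focal=500,
        n_target_group=1000,
        truth_window=12,
        window_lengths=(12,),
        background_n=2000,
        do_cv=False,
        do_window_selection=False,
        ai_years=(1990, 2009),
        n_permutations=499,
    )
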