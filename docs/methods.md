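# Methods

This note records the modelling choices behind `weathersdm`: the statistical
model and its assumptions, the conventions fixed where the field admits
several, what the synthetic data do and do not emulate, and the numerical
details that matter for reproducing results.

## Climatic covariates

Eight covariates summarise a monthly weather series: annual precipitation,
wettest- and driest-quarter precipitation, precipitation seasonality
(coefficient of variation), annual mean temperature, warmest-month maximum,
coldest-month minimum, and temperature seasonality (CV). They are computed
over **trailing windows** — the 12 or 36 calendar months strictly preceding a
reference month — so each occurrence record sees the weather an individual
actually experienced (12 months ≈ one breeding cycle of an annual breeder;
36 months ≈ a 3–4-year lifetime with cumulative or lagged effects), or over a
30-year mean-monthly climatology for the static climate model.

Conventions, fixed once and used everywhere:

* **Quarters** are any 3 *consecutive* months inside the window; no
  wrap-around. A consequence worth knowing: on purely cyclical weather, a
  12-month window whose boundary falls inside a wet or dry season clips that
  season's full quarter, so 12- and 36-month quarter variables coincide only
  for windows that contain both seasonal extremes in their interior.
* **Annualisation**: 36-month precipitation totals are scaled by 12/36 so
  the two window lengths share units.
* **CVs** use the sample standard deviation (n−1). Precipitation CV is
  computed on mm and defined as 0 for an all-dry window (no +1 offset — some
  bioclim implementations add one to the mean; the choice is documented here
  because the convention is not universal). Temperature CV is computed on
  Kelvin, which keeps the statistic positive and smooth around 0 °C.
* `tmean` is taken from the data when supplied, else (tmin+tmax)/2.

Windows that would extend before the weather archive raise an error;
callers must not silently truncate. The vectorised stack
(`covariate_cube`) is tested cell-by-cell against the scalar path.

## Occurrence preparation

Records with date accuracy worse than 1 month or location accuracy worse
than 10 km are excluded (bounds inclusive: the exclusion rule is strictly
"greater than"). Within each (year, month), records within a 5 km radius
collapse to one by **greedy first-seed clustering** in input order: a record
joins the first already-retained record within the radius, otherwise it
seeds a new cluster. The rule is deterministic and idempotent; chained
configurations (A–B close, B–C close, A–C far) yield two records, because
cluster members are not themselves attachment points. Distances are
Euclidean on the synthetic kilometre grid and haversine on geographic
coordinates; grid snapping is not used, but the metric is configurable.

## Target-group background

Presence-only models confound suitability with survey effort unless the
background carries the same bias as the presences. The background is built
by resampling, with replacement, whole records from the prepared
occurrence set of the *target group* — the focal species plus companion
species recorded by the same survey methods. Sampling rows directly weights
every unique (location, year, month) triple by its record multiplicity,
which is exactly "in direct proportion to the spatial and temporal
distribution" of the group's effort. Duplicated triples are deliberately
not collapsed. Background size (default 10,000 in the pipeline; 100,000
supported and tested for distributional agreement) trades Monte-Carlo error
against fit cost. Presence rows are *not* added to the background.

## Maximum-entropy model

Features are linear, quadratic and pairwise-product transforms of the
covariates (8 covariates → 44 features), min-max scaled to [0, 1] with
constants fixed on the background; presence and projection features are
clamped to the background range. Hinge and threshold classes are not
offered — smooth features give more general response curves. Constant
features are dropped with a warning.

The fit maximises the presence log-likelihood of the background-normalised
Gibbs distribution minus an L1 penalty `β_j = β_mult · s_j/√m`. The penalty
is a standard surrogate for the per-feature defaults of the widely used
Maxent software, whose tuned constants are version-specific; `β_mult`
(default 1.0) is exposed in the configuration. Optimisation is L-BFGS-B on
the split `λ = λ⁺ − λ⁻` (both halves bound at zero), which makes the
penalised objective smooth on the feasible orthant; convergence is declared
on relative objective change below `tol` (default 1e-9), and hitting the
iteration cap raises an error carrying the objective trace. Invariants
checked in tests: the fitted distribution sums to one over the background;
the objective trace is monotone; with β = 0 the feature expectations under
`q` equal the presence means (the maximum-entropy moment conditions); a
4-cell fixture with one binary feature recovers the closed-form solution
λ = ln 3 to 1e-6.

The logistic output is `e^H q/(1+e^H q)` with `H` the entropy of the fitted
background distribution: a monotone calibration that pins an average
background cell at 0.5. AUC is the Mann-Whitney probability that a random
presence outscores a random background point (ties count one half) — note
this is *presence vs background*, not presence vs absence, so its ceiling
is well below 1 for a widespread species. On the default synthetic island
the true suitability itself only attains AUC ≈ 0.6 against the
target-group background (mean truth ≈ 0.6 — the species is common), and the
fitted model sits within 0.005 of that ceiling; discrimination is bounded
by the species' prevalence, not by the estimator.

Permutation importance shuffles one covariate across the pooled
presence + background rows, rebuilds that covariate's features with the
original scaling constants, and records the training-AUC drop, normalised
to percentages (one permutation by default, matching common practice;
`n_perm` raises stability). Window selection fits the full 16-covariate
(12 m + 36 m) model and keeps the higher-importance version of each
variable, preferring the 12-month version on ties (shorter memory,
parsimony). Correlation screening reports pooled Pearson correlations with
|r| ≥ 0.85 flagged but never auto-drops: the model tolerates correlated
covariates. Cross-validation partitions presences into k random folds
(default 10) and scores each held-out fold against the full background.

## Projection, threshold and area

The fitted model is projected on every month with a complete trailing
window, giving one suitability surface per month; the cellwise mean over
months is the composite map, and the per-cell fraction of suitable months
is the stability map. The binary threshold equalises training sensitivity
(fraction of presences at or above t) and specificity (fraction of
background below t) over the exhaustive candidate set of observed scores,
taking the lowest candidate on ties — ties are resolved after rounding the
sensitivity–specificity gap at 1e-12 so float noise cannot flip the choice.
Monthly core-habitat area is the suitable-cell count times cell area
(constant on synthetic grids; cellwise cosine-corrected on geographic
grids). The **annual area statistic carried into the abundance analysis is
the mean of the 12 monthly areas** — the within-year band (min–max) is
reported alongside — configurable to min/max/sum since "total annual area"
is ambiguous in common usage.

## Abundance analysis

The abundance index (AI) for year y is the summed count over the panel of
transects surveyed in *every* year of the analysis span; incomplete
transects are excluded and logged. Regional 10-year change sums
per-transect differences of two 3-year means, excluding regions with no
detections or zero net change; magnitudes bin as <3, 3–6, >6 sightings.

Changepoint detection is at-most-one-change on the mean. The default
statistic is a **rank-based CUSUM** (Pettitt-type sign statistic),
standardised by its null variance profile √(k(n−k)): without the
standardisation the raw statistic is biased toward balanced splits and
mislocalises asymmetric shifts (a property visible in tests; the
standardised version localises a 3-sd shift to within ±1 position in ≥95%
of simulated series). Significance comes from permutation of the series
(999 permutations by default, add-one correction), honouring the
distribution-free assumption; a Gaussian likelihood (between-segment
sum-of-squares) criterion is available as an alternative. Reported
pre/post uncertainties are standard errors of the segment means and are
labelled as such.

The changepoint year is the *last pre-segment year*, and the segmented
regression assigns that year to the pre segment (configurable). The AI is
natural-log transformed before ordinary least squares of annual area on
ln(AI); each segment needs ≥3 years, zero-AI years are excluded with a
warning (the log and the ratio are undefined there). Slope, r², F with
(1, n−2) degrees of freedom and the two-sided P are reported per segment.

## Synthetic data: what it emulates, what it does not

The generator produces the statistical structure the analysis assumes, not
any real geography:

* **Weather** — sinusoidal seasonal cycle (coldest and wettest months
  June–August), linear spatial gradients with temperature varying
  south→north and precipitation west→east (independent axes, so the niche
  has genuine 2-D spatial structure; a single shared axis would let the
  species' cold-winter preference and dry-climate preference cancel),
  i.i.d. Gaussian year anomalies shared by all months of a year, plus small
  monthly noise. Defaults: 20×20 cells of 25 km², 1950–2009, base
  temperature 11 °C with 7 °C seasonal amplitude and a 3 °C gradient,
  70 mm/month base precipitation with 45 mm amplitude and a ±40% gradient,
  year-anomaly SDs 0.5 °C and 10 mm. The *unfavourable excursion* adds a
  fixed winter warming (default 2 °C) and scales wettest-quarter
  precipitation (default 1.5×) inside the anomaly window.
* **Truth** — a logistic in the standardised trailing-window coldest-month
  minimum, wettest-quarter precipitation and annual precipitation
  (coefficients 1.2, 1.2, 0.4 per SD; intercept 0.75), so warm winters and
  heavy rain depress suitability and the excursion produces a suitability
  dip with the trailing-window lag.
* **Occurrences** — focal records fall on cell-months with probability
  proportional to truth × effort bias; two companion species follow the
  bias alone; coordinates are cell centres; accuracy fields are generated
  within the pipeline's filters; about half the records carry a spotlight
  source flag.
* **Transect counts** — negative binomial (dispersion 2.0 — spotlight
  counts are overdispersed) with mean k × (mean truth over the transect
  cell in a fixed 4-month summer survey season). From the suppression year
  on, the expectation is pinned to 0.4× the transect's pre-suppression
  long-run mean, *decoupled from suitability* — that decoupling is the
  phenomenon the post-changepoint analysis must detect.

Passing tests on these data show the pipeline recovers structure it is
built to see: proportional sampling, a known suitability ordering, sharp
mean shifts. They do not show robustness to what the generator omits —
spatially correlated weather noise, observer-varying detectability,
topography, dispersal limitation, or density dependence in counts.

## The compact decline scenario

The replicated end-to-end check runs a 12×12 island over 1988–2009 with the
excursion in 1998–2000, suppression from 2001, truth on 12-month windows
(short memory keeps the dip's timing sharp), steeper gradients (6 °C,
±60% precipitation) and smaller year anomalies (0.35 °C, 7 mm) so the
binarised area responds gradually to island-wide swings rather than
saturating at zero or the full island. Counts respond to truth in the
summer season *after* each winter, so the last unaffected AI year is the
excursion's first year; the expected changepoint labels are therefore
1998 (AI) and 2000 (ratio, last year before suppression). The scenario
reproduces all five structural findings — area dip, significant positive
pre-regression, non-significant post-regression, both changepoints within
±1 year — in ≈96% of seeds; problem sizes (500 presences, 2,000 background
points, 264 projected months, 499 permutations) were chosen so a full
replicate costs well under a second.

## Known limitations

* The L1 penalty is a surrogate for, not a reimplementation of, the Maxent
  software's tuned per-class regularisation; coefficient-level equality
  with that tool is not a goal — distributional agreement on synthetic data
  is.
* The rank-CUSUM changepoint detects a single mean shift; gradual trends
  and multiple shifts are out of scope.
* Area is binarised before summation, so area responds nonlinearly to
  suitability near the threshold; on small grids a strong island-wide
  anomaly can still zero the area series.
* Cell areas on geographic grids use the spherical cosine rule; no
  projection support.
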