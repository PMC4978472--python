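# Methods

`antshift` implements a community-level climate-vulnerability analysis
for ground-foraging ant assemblages sampled along an altitudinal
gradient: thermal-niche estimation by weighted averaging, an
extinction-risk statistic per future decade, spatially corrected
occurrence models, and projection of altitudinal richness patterns
under decadal warming offsets. This note records the models, the
defaults and why they were chosen, what the synthetic data do and do
not emulate, and the numerical choices that matter.

## Climate representation

Temperature is carried on planar regular rasters (30 m cells by
default, matching fine-scale downscaled climate products). A decade's
mean grid is the cell-wise average of its minimum and maximum grids.
Site temperature uses the nine-cell rule: the mean of the 3×3 block of
cells centred on the site's cell. Because the mean is linear, averaging
the min/max grids first and then taking the nine-cell mean equals
taking per-grid nine-cell means and averaging afterwards, so only the
former is implemented. Sites in edge cells use the available ≤9 cells
with a logged warning; the synthetic site sampler avoids edge cells
altogether so the rule is always exact in generated studies.

Warming scenarios are additive offsets per decade relative to the
baseline; the default is the A1B-style sequence +0.5, +1.2, +2.4,
+3.5 °C for the 2020s–2080s. Offsets must be non-decreasing, which is
what makes the at-risk species sets provably nested across decades.

The "lowest air temperature" around a site is the 1st percentile
(linear interpolation between order statistics, numpy's default) of
cell temperatures whose centres lie within a lateral buffer of 100 m.
Buffer membership is by Euclidean distance to cell centres; the site's
own cell is always included. The study-area threshold for a decade is
the minimum of these per-site values.

## Thermal niches (weighted averaging)

For species *j* with abundance *y_ij* at sites with temperature *x_i*:

- optimum `WA_j = Σ_i x_i y_ij / Σ_i y_ij`
- tolerance `TOL_j = sqrt( Σ_i (x_i − WA_j)² y_ij / Σ_i y_ij )`

The square root is applied to the weighted variance so the tolerance is
in °C and can be added to the optimum; `WA + TOL` is the species'
maximum air temperature tolerance used by the risk rule. Optimal and
tolerance *altitudes* use the same two operations with altitude in
place of temperature.

Standard errors bootstrap whole sites (rows) with replacement — 1000
cycles by default — so within-site covariance between species is
preserved; resamples in which a species vanishes entirely are redrawn.

Whole-model accuracy uses weighted-averaging calibration: a site's
temperature is inferred from its community as the abundance-weighted
mean of species optima, then linearly deshrunk by inverse deshrinking
(the initial estimates are regressed on the observed temperatures and
the regression inverted — the convention of classical transfer-function
software). The reported r² is the apparent squared Pearson correlation;
mean bias and RMSE come from bootstrap out-of-bag predictions, and an
out-of-bag r² is reported alongside.

**Uneven sampling bias.** Weighted averaging is consistent only when
the gradient is sampled (locally) evenly. Under a site design heavily
concentrated at one end — as altitude-stratified forest surveys are —
WA estimates are pulled toward the densely sampled end by roughly
`TOL² · d log f/dT` where `f` is site density in temperature. With the
default survey-like design this structural bias is ≈0.4–0.5 °C.
Parameter-recovery validation therefore runs on the `calibration`
preset (below), which uses the same study sizes but spreads sites
uniformly in altitude across a gradient wide enough to contain every
niche; there the mean absolute optimum error is ≈0.16 °C at default
sizes. Users estimating niches from unevenly sampled surveys should
expect the same pull in their own estimates.

## Extinction risk

A species is at risk in a decade if `WA + TOL` is strictly smaller
than the decade's lowest available air temperature — i.e. even the
coldest place a community member could retreat to is already warmer
than the species' upper thermal limit. The risk rate is the percentage
of assessed species at risk. Strict inequality makes the boundary case
"exactly equal" safe.

Band rates aggregate the same species-level classification (against the
study-area-wide threshold) over the species recorded — positive
abundance at ≥1 site — in each altitude band (≤200, 200–400, …,
>1000 m). An alternative `threshold_scope="band"` assesses each band's
species against the band's own lowest temperature; it is not the
default because the warm lowland bands then receive the *highest*
thresholds and their (widely shared) species are classified at risk en
masse, inverting the expected altitudinal gradient of vulnerability.

The altitude–risk relationship is a maximum-likelihood logistic
regression of the species-level risk indicator on optimal altitude, fit
separately for occurrence-frequency classes (all, >1 %, >5 %, >10 %).
The species, not the site, is the regression unit. Complete separation
is detected (all fitted probabilities at 0/1, or IRLS failure), flagged
on the returned curve, and the coefficients of an L2-regularised refit
are reported with a warning rather than raised.

## Occurrence models

The response is presence/absence (abundance > 0). Although the
underlying counts are abundances, discrimination metrics (AUC,
sensitivity, specificity) require a binary outcome, and occurrence
modelling reconciles the two; this also makes the Youden threshold and
the presence surfaces well defined.

The model is an additive logistic regression: one penalised B-spline
smooth (4 basis functions, cubic, penalty weight 1) per predictor plus
linear spatial terms, fitted by penalised IRLS (statsmodels `GLMGam`).
The nine predictors are annual/January/July × max/mean/min air
temperature. All nine are retained despite strong mutual correlation —
single variables have materially lower predictive power, and the modest
per-term basis size keeps concurvity in check. Quasi-separable
responses (possible with noise-free synthetic step data) abort IRLS;
the fit then escalates the penalty by factors of 100 until it
stabilises and flags the model as not fully converged.

Spatial structure is screened with Moran's I (inverse-distance weights
within a neighbourhood, row-standardised, analytical two-sided z-test
under the normality assumption; ≥8 sites required). The default
correction is the autocovariate: the distance-weighted mean of
neighbours' responses within a radius of 3× the median
nearest-neighbour distance; isolated sites receive the global mean
response. Moran eigenvector maps (leading eigenvectors of the doubly
centred weight matrix) are available as an alternative set of linear
spatial predictors for users who prefer that correction; the
autocovariate remains the default.

Validation is a stratified 70/30 split: AUC is the rank statistic on
the test split; sensitivity and specificity are evaluated at the
threshold maximising Youden's J on the *training* predictions. A test
split that loses one class is resampled with an incremented seed and
the seed recorded. AUC ≥ 0.7 is carried as the acceptability flag. The
model-uncertainty range is reported as (1 − mean AUC, 1 − mean
sensitivity) across species.

## Projection

Each decade's nine predictor surfaces are derived from the baseline
annual-mean grid by a parametric seasonal decomposition: January and
July means offset by a winter drop (default 15 °C) and summer rise
(default 12 °C) modulated by smooth spatial anomaly fields, and
per-month extremes ±4 °C around the month mean. Warming offsets shift
all nine surfaces equally. Cells whose predictors fall outside a
model's training range are clipped to the range edge (climate-envelope
convention) and counted in an extrapolation warning. The autocovariate
of unsurveyed cells is unknown and is held at its training mean.

Presence is probability ≥ the model's stored Youden threshold. The
suitable-area proportion per decade is the fraction of presence cells;
its OLS regression on decade index (0–4) classifies species as
decreased / increased / stable at α = 0.05. Decade labels are parsed as
mid-decade years, so the 2000s→2080s span is 80 years — this is the
arithmetic that turns peak altitudes of 263 m and 656 m into
4.9 m yr⁻¹.

Richness is the per-cell count of predicted presences. The peak
altitude is the centre of the 50-m altitude bin with maximal mean
richness (ties to the lower bin). The richness–altitude curve is
classified from a quadratic least-squares fit on the binned means,
weighted by the number of cells per bin: *bell-shaped* if the quadratic
coefficient is significantly negative and the vertex lies strictly
inside the observed range; *monotonic-decrease*/*increase* if the
fitted parabola is monotone with non-zero total change over the range;
*flat* otherwise. The cell-count weights matter: hypsometry
concentrates area at low altitude, and without weights a handful of
near-empty summit bins with zero richness dominates the curvature and
misclassifies genuinely declining profiles.

## Synthetic studies

The generator produces what the analysis assumes and nothing more: a
smooth mountain landscape (sum of Gaussian bumps, one dominant summit
of fixed width so the top altitude band is always populated; altitudes
raised to an exponent of 1.6 so high ground is rare, as in real
hypsometry); temperature from a 6.5 °C km⁻¹ lapse rate plus smooth
noise (s.d. 0.1 °C); 335 sites in six altitude bands; 29 species with
Gaussian thermal niches (optima uniform on 7.0–12.9 °C, tolerances on
0.8–2.0 °C, peak abundance 20); negative binomial counts (size 1.5)
with a shared lognormal site effect (log-s.d. 0.4, exponential
covariogram, range 300 m) that gives occurrence data the spatial
autocorrelation the autocovariate is meant to absorb.

Three configurations of the one generator serve different purposes:

- **default** — the survey-emulating design: band counts
  157/77/27/25/21/28, sea-level mean 13.0 °C, relief to 1200 m. Used
  for risk rates, SDM validation and null calibration.
- **`calibration()`** — same sizes, sites uniform in altitude
  (45×5 + 110 per band) over a warmer, taller landscape (14.0 °C,
  1600 m) whose realised gradient covers every niche. Used for
  parameter recovery (see the uneven-sampling note above).
- **`rangeshift()`** — sea-level mean 9.5 °C, relief to 1400 m. The
  warmest sites sit *below* the warm half of the community's optima, so
  warm-adapted species stack at the lowest altitudes — the temperate
  "warm edge" regime. Baseline richness then declines monotonically
  with altitude, and each warming offset moves the richness peak
  upslope by ≈ offset/lapse. This geometry was chosen from the
  analytic expected-richness profile: a bounded relief of ~9 °C cannot
  simultaneously cover a ~12 °C community (needed for unbiased niche
  recovery) and put the community's warm edge at sea level (needed for
  the temperate baseline), so the two regimes are separate presets.

What the generator does **not** emulate: real geography and dispersal
barriers, habitat covariates (forest type is a label only), species
interactions, detection error beyond count noise, and any calibration
of the occurrence-frequency spectrum to a real survey. Passing tests on
these data show that the estimators recover the structures they assume;
they do not show that those assumptions hold in any real landscape.

## Validation protocol and problem sizes

The replicate suites (`antshift.experiments`) use seeds 1–20 on 96×96
grids with the full 335-site, 29-species design; the tests and
`scripts/acceptance.py` call the same functions. On one CPU the whole
test suite runs in ~1.5 min and the acceptance script in ~1 min. The
headline projection suite measures, per seed, whether richness-peak
altitudes are non-decreasing across the five decades and whether the
curve shape transitions from monotonic-decrease (baseline) to
bell-shaped (2080s); with the locked presets this holds in 19/20 and
15/20 seeds respectively, with a mean synthetic upward rate of
≈6 m yr⁻¹.

## Known limitations

- The curve-shape classifier is a three-parameter summary; profiles
  with plateaus or heavy tails can land in *flat* even when visually
  declining. The per-decade binned profiles are exposed so users can
  inspect them directly.
- Projection holds the autocovariate at its training mean, which
  removes spatial contagion from the projected surfaces; relative
  (between-decade) comparisons are unaffected, absolute suitability in
  strongly clustered regions may be understated.
- The seasonal decomposition ties all nine predictors to one baseline
  surface; their mutual correlations (~0.95+) are realistic for
  temperature variables but mean the smooths share signal, and
  per-term effect estimates should not be interpreted individually.
- Bootstrap SEs treat sites as exchangeable; under strong spatial
  autocorrelation they are mildly optimistic.
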