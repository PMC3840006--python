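# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic validation does and does not establish.

## Habitat model

A site is represented as a mosaic of cells, each carrying an area, ordinal
substrate and cover codes, and per-cell power-law rating curves for depth
and velocity. The rating-curve form (`x = a·Q^b`, a ≥ 0, b finite) is a
deliberate simplification of a calibrated hydraulic simulation: the
downstream analysis consumes only the WUA–discharge relation, which is
insensitive to how the within-site hydraulic detail is produced so long as
depth and velocity respond monotonically and smoothly to discharge.

Suitability curves are piecewise linear in depth and velocity (clamped
outside their breakpoints) and categorical for substrate and cover. The
composite suitability index is the product of the four components — the
classical convention for physical habitat simulation — with the geometric
mean available as a configuration option, since the aggregation rule is a
genuinely open choice. WUA is the area-weighted CSI sum normalised per
hectare of wetted site area, so 0 ≤ WUA ≤ 10 000 m²/ha by construction.

Intercohort segregation removes a cell from a younger stage's WUA whenever
an older stage (dominance order adult > juvenile > young-of-the-year)
attains *strictly* greater CSI there. Ties leave the cell shared: dominance
means having more favourable conditions, and a stage with CSI 0 cannot
dominate (strictness makes this automatic). Adult WUA is never modified.
WUA–discharge curves are evaluated on a discharge grid; queries interpolate
linearly and clamp at the grid ends.

## Carrying capacity

K (trout/ha) is mean summer WUA divided by the territory area of an
individual of stage-average length, with the territory allometry
log₁₀T = (2.64 − 0.96·age)·log₁₀L − (2.72 − 0.90·age). The coefficients are
taken as fixed inputs; note the implied scaling — super-quadratic in length
for young-of-the-year (exponent 2.64), sub-quadratic for older fish (1.68).
The summer window is July 1 – September 30 inclusive; K is kept continuous
(densities are per-hectare rates, not head counts). Mean length per
site × year × stage is an input; the generator supplies it with small
interannual jitter (YOY 6.0 ± 0.3 cm, juvenile 13.0 ± 0.6, adult 22.0 ± 1.0).

## Temperature models

The thermal metric, Tmax7d, is the maximum over July–September of the 7-day
rolling mean; windows must lie wholly inside the season, and a window with
any missing day is skipped (if all are skipped, that is an error, not a
silent NaN). The regional air model is a linear mixed model of station
Tmax7d-air on latitude and altitude with a random intercept by year
(stations in the same year share an anomaly); a single year degenerates to
OLS. Air-to-water conversion is fitted with a random intercept and slope by
river basin; the reported per-basin lines are fixed effects plus basin
BLUPs, with a per-basin OLS fallback if the mixed fit fails and a
plain-regression fallback (with a warning) for a single basin. Defaults for
both models are the fitted coefficients quoted in the README.

## Removal estimation

Three-pass removal estimation uses the classical constant-effort solution:
conditional on the total catch T, the pass pattern is multinomial with
probabilities ∝ p·qⁱ⁻¹, and the conditional MLE solves
R/T = q/(1−q) − 3q³/(1−q³) (R = c₂ + 2c₃), after which N̂ = T/(1−q̂³).
A worthwhile subtlety: this is *not* the exact maximizer of the
unconditional multinomial likelihood over integer N — for catches
(100, 50, 25) the conditional solution returns exactly (N = 200, p = 0.5)
while the exact integer-N maximizer is (198, 0.509). The conditional
solution is the field-standard estimator and is what this package uses; the
test suite checks it against a brute-force grid over q of the same
conditional likelihood. Validity requires a declining pattern (c₁ > c₃);
non-declining patterns raise an explicit error and the pipeline drops and
counts them rather than silently imputing. Variance uses the standard
large-sample formula, scaled by area⁻² for densities.

## Density-driver models

Stage-specific predictor tables contain: K of the stage and year; the D/K
saturation ratio the cohort experienced the previous year at the previous
stage (for YOY: the adult stock's D/K); the D/K ratios of both accompanying
stages in the current year; the capacity ratio across the ontogenetic
transition (K_x,i / K_{x−1,i−1}); and the standardized emergence-flow
metrics Q_em (March–April mean over historical median) and Q_max7d (maximum
7-day mean over historical median). The first year per site is dropped
(undefined lags) and rows with undefined ratios (K = 0) are excluded with a
stored count.

The forest is explicit bagging over CART regression trees: each tree is
fitted to an n-out-of-n bootstrap sample with `mtry` candidate predictors
per split, and each tree's out-of-bag rows provide honest predictions.
Building the bagging loop directly (over scikit-learn decision trees) keeps
per-tree bootstrap membership available, which the three OOB-based outputs
need: tuning (OOB MSE over a (mtry, ntree) grid, computed from leading
subsets of one maximal forest per mtry), explained variance
(OOB R² = 1 − MSE_OOB/var(y), the "% variance explained" convention), and
permutation importance (per-tree OOB MSE increase after permuting one
predictor, averaged over trees and expressed as % of the mean per-tree OOB
MSE — the unnormalised %IncMSE variant). A test cross-checks the OOB R²
against scikit-learn's own `RandomForestRegressor.oob_score_`. On pure-noise
responses OOB R² is mildly negative (≈ −0.15), as with R's randomForest;
this is expected behaviour, not an error. Partial dependence is the mean
prediction over the data with one predictor pinned to grid values; grid
points outside the data range are flagged (forests extrapolate flat).
Replication-mode defaults are mtry = 3, ntree = 600. All stochastic steps
take explicit seeds.

## Thermal limitation

The response is the relative residual r = log₁₀(1 + x) with
x = (observed − predicted)/predicted, predictions taken out-of-bag so the
residuals are honest. Log base 10 is used for both the residual and the
temperature transform; the base is forced by the CTT arithmetic
(10^1.318 = 20.8 °C) and is configuration-exposed. Observed zero densities
are floored to x = −1 + 10⁻⁶ and flagged; rows with non-positive
predictions are dropped row-wise.

Quantile regressions of r on log₁₀T use case-resampling bootstrap
(site × year rows, the same resamples across quantiles) for percentile CIs;
cross-quantile slope differences reuse the paired draws. The CTT is the
smallest observed log₁₀T above which every residual is non-positive, with a
minimum tail support of 5 observations to prevent single-point thresholds;
if positive residuals persist at the maximum temperature the CTT is
undefined and reported as such (a sentinel, not an error).

The breakpoint model is a continuous broken stick
r ~ 1 + t + (t − bp)₊ (t = log₁₀T) with random intercept and independent
random slopes per site on both segments (variance components). Continuity
at the breakpoint is imposed: it is the standard identifiable form of a
segmented model. The breakpoint is chosen on a grid in °C (coarse 0.5 °C
scan over the central observed range, refined to 0.1 °C), but the search
objective is the profile likelihood of the *fixed-effects* analogue (site
fixed intercepts): free random slopes can absorb between-site heterogeneity
and bias the breakpoint estimate, and statsmodels' MixedLM reports a
non-finite likelihood when a variance component collapses to the boundary,
which would poison the comparison. Both sides of every candidate knot must
hold at least 10 % of the rows (min 5), the usual guard against degenerate
edge breakpoints. The full random structure is then fitted at the selected
breakpoint by maximum likelihood, falling back to simpler random structures
on non-convergence; a likelihood-ratio statistic against the no-breakpoint
model is reported with a χ²(2) reference that ignores grid selection and is
therefore approximate (the kink term's Wald test is the cleaner null check).

## Projection

Thermal suitability of a grid cell is Tmax7d-water ≤ 19.4 °C (inclusive),
with Tmax7d-water derived from the air surface plus a scenario offset
ΔT_air, converted through the cell's basin line. The capacity shortfall
above the breakpoint inverts the residual transform using only the
post-breakpoint decline component: reduction = (1 − 10^(δ·(t − t_bp)₊))×100,
capped to [0, 100]. Using the decline component alone (rather than the full
fitted line) makes the reduction exactly zero at the breakpoint and
monotone above it; scenario offsets are configuration inputs. Suitable-area
fraction is non-increasing in ΔT_air by construction.

## Synthetic study system

The generator emulates a 12-year, 51-site, 3-basin monitoring network on
the warm margin of a cold-water species' range. Defaults: 30 cells per
site; site areas 0.05–0.15 ha; site-level structural quality (probability
of good substrate 0.05–0.95, cover propensity 0.1–0.95) and hydraulic scale
(depth scale 0.18–0.38, wide within-site lognormal jitter so every site
retains shallow slow margin cells); daily discharge lognormal AR(1) around
a site median (CV 0.6, lag-1 autocorrelation 0.85); air temperatures on the
regional surface with year anomalies (SD 1 °C) and site noise (SD 0.5 °C),
converted through the basin lines with SD 0.5 °C.

Population dynamics are a stage-structured recursion saturating toward each
stage's K with a sharp contest-competition form (Maynard Smith–Slatkin,
D = B/(1 + (B/K)^γ)^(1/γ), γ = 4), which encodes territorial exclusion:
flux-limited well below K, capped near K above it. Transition rates
(fecundity 80 effective YOY per adult, survivals 0.85/0.90/0.70) are chosen
so that all stages sit near their ceilings in benign years — the regime in
which habitat capacity is the dominant driver. High emergence flows depress
recruitment (exp(−0.08·(Q_max7d − 1)₊)). Above the 19.4 °C breakpoint a
multiplicative penalty 10^(slope·(log₁₀T − log₁₀bp)) acts on realized
density — never on K — with stage slopes −12.80 / −1.28 / −2.94 per log₁₀ °C
and lognormal site heterogeneity (CV 0.7, putting the YOY site-slope SD
near 9, the scale of the fitted random slopes); heterogeneity is
multiplicative so every site declines above the breakpoint, at different
rates. Process noise is lognormal with CV 0.20. Observation is three
binomial removal passes with capture probability 0.5. Every output is a
deterministic function of the master seed.

What passing the end-to-end checks shows: the analysis chain recovers the
structures the generator embeds — K as the dominant driver, a breakpoint
near 19.4 °C with a steep negative YOY slope, critical thresholds above the
breakpoint, monotone loss of suitable area under warming. What it does not
show: performance under the ways real data differ from the generator —
non-constant capture probability, habitat selection curves estimated with
error, serially correlated measurement error, anthropogenic stressors
confounded with temperature, and dispersal between sites, none of which are
simulated.

## Problem sizes

Simulation-based checks use the study-scale defaults (51 sites × 12 years;
48 stations × 12 years for the air model; 20 replicates for breakpoint
recovery; 400–1000 bootstrap repetitions for quantile CIs), with smaller
configurations in unit tests where only correctness of the mechanics is at
stake.

## Known limitations

Hydraulics are rating-curve stand-ins, not calibrated hydraulic models; the
habitat selection curves are inputs, not estimated from use–availability
data; the removal estimator assumes constant capture probability across
passes and stages; the χ²(2) reference for the breakpoint LRT ignores grid
selection; the projection treats sites as independent cells (no stream
network topology); and scenario warming is a uniform air offset rather than
a downscaled climate field.
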