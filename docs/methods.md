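# Methods

`firestream` estimates the effect of a watershed wildfire on downstream winter
(December–February) and summer (July–September) stream water temperatures from
a single site's daily record: water temperature, air temperature,
precipitation, potential evapotranspiration (PET), and optionally streamflow,
plus the fire date. Three complementary approaches are run on the same
seasonal indices; agreement across them is the evidence, since no paired
control watershed is assumed.

## Indices and calendar conventions

For each season the package computes the mean water temperature (MWT, °C) and
the accumulated degree-days above 0 °C (ADD, degree-day Celsius), along with
mean air temperature, precipitation totals and flow means. ADD is the raw
cumulative sum of daily mean water temperature; sub-zero daily means are not
truncated, so a complete season satisfies ADD = MWT × n_days to machine
precision (a `floor_add_at_zero` flag is available for the truncated variant).
Winters are labeled by their January year (Dec 2001–Feb 2002 → winter 2002)
and include Feb 29 when present; season lengths therefore vary (90–92 days)
and every per-day aggregate uses actual day counts.

The pre-fire phase is the most recent 3–7 complete seasons strictly before
the season containing the fire; the post-fire phase is the first three
complete seasons strictly after it; the fire season itself is excluded. A
winter that merely follows a summer fire in the same calendar year is treated
as the first post-fire season (it postdates the burn); this rule is recorded
in output metadata.

A season/index value is reported only when at least 95% of its days are
observed (per-week requirement: 100%); these completeness thresholds are
package defaults, configurable per call.

## Approach 1 — year-resampling bootstrap

Pre-fire years are resampled with replacement into 1000 subsamples of three
years; each subsample's median seasonal index forms a null distribution. The
change estimate is the median of the three post-fire values minus the
500th-ranked (lower-middle order statistic) subsample median, and the change
is significant at the 0.05 level when the post-fire median falls strictly
below the 25th or strictly above the 975th ranked value. Ranks are 1-based
order statistics of the sorted medians — no interpolation — matching the rank
language of the procedure.

The test's true level is not the nominal 0.05: a median of three post-fire
years is compared against order statistics of medians of three resampled
pre-fire years, and year-to-year weather variability enters both sides. The
test-suite characterizes the level by simulation under the synthetic null
(measured rejection rate is reported, not corrected) and verifies that the
subsample-median distribution matches exhaustive enumeration over the
n_pre³ equally likely draws.

## Approach 2 — weekly air–water regression with SARIMA errors

Each season is split into 13 consecutive weekly blocks from its first day:
twelve 7-day blocks and a remainder block (6–7 days in winter, 8 in summer),
kept so that weekly ADDs sum exactly to the seasonal ADD. Two nested
regressions of the weekly water index on weekly mean air temperature are
fitted by Gaussian maximum likelihood:

    Twater = b0 + b1(1 − X) + b2(1 − X)·Tair + b3·X·Tair + e

with X ≡ 1 in the *unrestricted* model (one common line) and X = 0/1 on
pre/post-fire weeks in the *restricted* model. The naming follows the study
convention and is inverted relative to usual statistical usage: the
"restricted" model is the richer one (two extra parameters, b1 and b2). The
error e follows a seasonal ARIMA (p,d,q)(P,D,Q) process with period 13;
consecutive seasons are treated as adjacent cycles (the inter-year gap is not
modeled), and incomplete weeks keep their lattice slot with a missing
response so the error process stays aligned.

Orders are selected by AICc grid search (p,q ∈ {0,1,2}, d ∈ {0,1},
P,Q ∈ {0,1}, D = 0) on the unrestricted model only, and the winning set is
imposed on both fits — otherwise the likelihood-ratio test would compare
non-nested models. The LRT has 2 degrees of freedom (b1, b2); rejection at
p < 0.05 indicates a post-fire shift in the air–water relation. Residual
diagnostics on the richer fit: Shapiro–Wilk normality, a Bonferroni-adjusted
maximum externally-studentized-residual outlier test, and a score test for
variance depending on the fitted mean (half the explained sum of squares of
scaled squared innovations, chi-square with 1 df).

Numerical choices: with all orders zero the Gaussian MLE is ordinary least
squares and is computed in closed form (statsmodels OLS), which makes the
iid-error limit exact rather than optimizer-approximate; nonzero orders use
statsmodels SARIMAX (L-BFGS, Powell fallback), and LRT statistics negative
within optimizer tolerance are clamped to zero. R² is reported on the
regression mean (the `r2_dynamic` field additionally includes one-step ARIMA
error predictions).

### The ADD/MWT slope-scaling ratio

With weekly ADD = weekly MWT × n_days, fitting the same regression to both
responses multiplies every coefficient by exactly 7 when all weeks have 7
days — the package verifies this to 1e-9. With the remainder week retained,
the ratio is displaced:

    slope_ADD = 7·slope_MWT + (n13 − 7)/13 · E[MWT₁₃]·(E[MAT₁₃] − E[MAT]) / var(MAT)

The displacement scales with the *uncentered* water-temperature level of the
final week times that week's air-temperature anomaly, and only the
low-frequency within-season air-temperature variance reduces it (weekly noise
attenuates the MWT slope by the same factor and cancels). On the synthetic
study conditions the ratio consequently lands noticeably below 7 — far below
for summer, where the water-temperature level is highest. Ratios within a
few percent of 7, as field studies
report, are what equal-length weekly blocks would produce; under this
package's remainder-week convention they should not be expected, and the
corresponding acceptance check on synthetic winter data fails for exactly
this reason. The convention is kept because it conserves ADD additivity.

## Approach 3 — random-forest counterfactual attribution

A random-forest regression of **daily** water temperature on weather
covariates is trained on pre-fire season days only; driven with observed
post-fire weather it yields a no-fire counterfactual. Candidate covariates:
daily air temperature; day of the water year (Oct 1 = 1); trailing rolling
means of air temperature (windows 30–200 d, groundwater/hyporheic proxies);
trailing rolling sums of precipitation and PET (1–200 d, runoff proxies);
and October–March / January–June precipitation totals. Candidate models use
1–3 covariates, screened so no pair exceeds |Pearson r| = 0.7 on pre-fire
season days, and are ranked by

    AICc = n·ln(OOB-MSE) + 2k + 2k(k+1)/(n − k − 1),   k = n_covariates + 1

using the forest's out-of-bag MSE as its internal generalization estimate
(the information criterion for a forest is not otherwise defined; penalizing
covariate count preserves the parsimony intent). Hyperparameters are chosen
jointly: mtry ∈ {1..n_covariates}, ntree configurable (default
{100, 250, 500}; scripted runs use 200). The default rolling-window grid
{1, 7, 15, 30, 60, 90, 120, 150, 180, 200} keeps enumeration tractable; a
full 1–200 sweep is available via configuration.

Leave-one-year-out cross-validation withholds each pre-fire season-year,
refits, predicts the held-out season daily, and aggregates to seasonal MWT
(mean) and ADD (sum). Metrics across held-out seasonal values: Nash–Sutcliffe
efficiency, bias (positive = underprediction), RMSE; a daily-resolution
variant is exposed. A caution the LOOCV step exists to catch: because
season-total and day-of-year covariates can act as year identifiers, the
OOB-based AICc sometimes selects models that interpolate year identity and
cross-validate poorly (strongly negative NSE); the selected model should not
be trusted for attribution without inspecting its LOOCV skill.

The fire contribution is the median over the three post-fire years of
(observed − predicted) seasonal MWT or ADD; the weather contribution is the
median predicted post-fire index minus the median observed pre-fire index
(the decomposition of the total change into parts attributable to the burn
and to weather alone; the weather part is an interpretation recorded in
output metadata). Predicted ADD equals predicted MWT × days by construction,
since both aggregate the same daily predictions.

### Uncertainty of the fire contribution

The naive standard error of a 3-value median, sd/√3, is well calibrated only
if the three per-year errors are independent. They are not: all three post
years are predicted by the *same* fitted forest, so they share its estimation
error, and in null simulations the across-replicate spread of the fire
contribution exceeds the naive SE, leaving ±2 SE intervals covering zero well
short of their nominal rate. Under no fire effect, a post-year
(observed − predicted) value is distributionally the same quantity as a LOOCV
fold error, and for errors e_i = b + ε_i with shared component b,
Var(median) = σ_b² + c·σ_ε² ≤ σ_b² + σ_ε² = E[e²] — the marginal per-year
error variance, which LOOCV RMSE estimates. The reported SE is therefore
floored by the LOOCV seasonal RMSE whenever LOOCV results are supplied (the
`attribute` command always supplies them); this is deliberately the
conservative upper bound. The test-suite verifies the resulting ±2 SE null
coverage by simulation.

## Synthetic-data generator

The generator exists so every stage can be verified by parameter recovery;
it emulates the statistical structure the analyses assume, not stream
physics. Defaults describe a rain-dominated Pacific-Northwest montane site:

| parameter | default | meaning |
|---|---|---|
| tair_mean_annual / tair_amplitude | 8.6 / 10.6 °C | annual air-temperature sinusoid (peak mid-July) |
| tair_ar1 / tair_noise_sd | 0.6 / 1.5 °C | AR(1) day-to-day anomaly (innovation sd) |
| precip_winter_mean / summer_mean | 8 / 1 mm d⁻¹ | DJF / JAS daily means; Bernoulli occurrence × exponential intensity |
| precip_wet_prob winter / summer | 0.55 / 0.15 | wet-day probabilities |
| pet_mean / pet_amplitude | 2.5 / 2.5 mm d⁻¹ | non-negative sinusoid peaking mid-summer |
| water_intercept / water_slope | 3.0 °C / 0.35 | response to the smoothed air temperature |
| water_smoothing_window | 30 d | air-temperature smoothing (makes rolling covariates informative) |
| precip_cooling | 0.01 °C mm⁻¹ | cooling per mm of 7-day precipitation (runoff advection) |
| water_noise_ar1 / water_noise_sd | 0.5 / 0.3 °C | AR(1) residual water-temperature noise |
| n_pre_years / n_post_years | 7 / 3 | study layout around the fire date (2008-07-15) |

Precipitation parameters are piecewise by month (DJF winter, JAS summer,
shoulder months the average of the two) so configured seasonal means are
exact expectations. Water temperature is floored at 0 °C, mimicking winter
streams; tests relying on exact linearity configure parameters so the floor
is never hit. The fire effect is a season-specific additive step on
post-fire season days, optionally decaying per year — the simplest mechanism
consistent with a detectable season-specific shift. Not emulated: energy
balance, snowpack, shade, flow responses to fire, serially correlated
multi-year droughts, observation gaps (tests insert these explicitly).
Passing recovery tests therefore show the inference machinery is correct
under its assumptions, not that those assumptions hold for any particular
stream.

## Problem sizes used in verification

Simulation checks run at sizes chosen for a single-CPU workstation:
bootstrap-vs-enumeration at n_boot = 10⁵; bootstrap level/power at 500
replicates × 4 effect sizes (0, 0.5, 1, 2 × noise sd) with the step applied
at the seasonal level (exactly equivalent to daily injection without decay);
LRT level/power at 200 null + 100 alternative simulations through the
closed-form OLS path; attribution recovery and null coverage at 20 seeds
each with the known-informative covariate pair (30-day air mean, 7-day
precipitation sum) and ntree = 200. The scripted end-to-end run enumerates
candidates over the {7, 30} window grid.

## Known limitations

* The bootstrap compares a 3-year median against resampled 3-of-n medians;
  its level is characterized, not corrected, and no multiplicity adjustment
  is applied across the season × index grid.
* The regression stage assumes a linear weekly air–water relation and omits
  precipitation covariates.
* The forest cannot extrapolate beyond the pre-fire covariate range; in
  seasons dominated by advective (runoff/baseflow) heat input its
  counterfactual skill degrades, which LOOCV metrics make visible.
* Attribution requires complete post-fire weather; post years with missing
  weather are dropped (at least two must remain).
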