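# Methods

## Model

The unit of observation is the US state-year (50 states plus DC, annual). The
response is the natural log of real per-capita healthcare expenditure; all
regressors enter as one-year-lagged logs, so coefficients are elasticities.
Five blocks of explanatory variables are used: (1) state-specific
time-varying controls — smoking prevalence, real per-capita income, percent
elderly, percent African-American, percent Hispanic; (2) mean annual cigarette
consumption per adult current smoker, treated as mismeasured; (3) real
cigarette excise tax, interacted with the eight BEA Economic Region
indicators (the tax coefficients proxy cross-border measurement error in
consumption, not a causal tax effect); (4) lagged cross-sectional national
averages (equally weighted over states, averaged on the raw scale and then
logged) of candidate variables, which absorb common national trends; and
(5) state-specific constants.

The model is a reduced-form autoregression with exogenous lags only: there is
no lagged dependent variable, and the stationary relation between the
(individually unit-root) log series plus stationary residuals is read as a
cointegrating regression. Residual stationarity is checked with a per-state
Phillips–Perron test combined Fisher-style across states.

## Estimation

`fit_2sls` absorbs state constants by within-demeaning and instruments the
consumption elasticity with smoking prevalence lagged two and three years and
consumption lagged three years. Conventions, chosen once and used everywhere:

* **Residuals and sigma** use the original (not first-stage fitted)
  consumption column — the standard 2SLS residual definition; `sigma² =
  SSR / (N − K − G_fe)` where `G_fe` counts absorbed intercept cells.
* **Cluster-robust covariance**: sandwich over the within-transformed,
  instrumented design with clusters = states and small-sample factor
  `G/(G−1) · (N−1)/(N−K)`, where K counts slope coefficients **plus**
  absorbed fixed-effect intercepts — the same degrees of freedom used for
  sigma, matching the `dofminus`-style accounting of panel FE-IV software.
  With 51 clusters, 95% intervals built this way still run a few points below
  nominal coverage (a well-known property of cluster-robust inference at
  moderate G); the synthetic studies below quantify this.
* **Confidence intervals and p-values** use normal (z) critical values, not
  t: the published intervals this package mirrors reproduce exactly with
  1.96 (e.g. 0.104 − 1.96·0.0323 = 0.0407).
* **Absorbed columns** (zero within-group variation) are never silently
  dropped; they are removed from the slope vector and reported.
* **R² statistics**: within R² is the squared correlation of demeaned score
  and response; between and total R² include the estimated state effects in
  the score, so an exact fit scores 1 on all three. `rho` is the share of
  error variance due to state constants, `σ_α²/(σ_α²+σ_ε²)`.
* **Regional heterogeneity** (`fit_regional`) interacts chosen elasticities
  with region indicators and tests homogeneity by the textbook F on
  restricted/unrestricted SSR from the within-OLS projection (all regressors
  treated exogenous there, so the SSR nesting that the F requires holds
  exactly). Sequential grouping repeatedly merges the pair of region groups
  with the largest equality-test p-value while it exceeds 5%.

When the survey break is bridged with an intercept shift, the fixed-effect
cells become state × pre/post-break; the first post-break year then has
single-row cells, which contribute nothing to the slopes but identify the
shifted intercept — this is exactly how expanding estimation windows cross
the break.

## Out-of-sample validation

Recursive estimation starts from a base window (default 1992–2006) and adds
one year of all states' data at a time. One-step forecasts for year t+1 use
the fit through t, regressors dated t, and the state's (post-break, when
bridged and available) intercept; no data later than t enters, which a test
enforces. Multi-step forecasts condition on the *observed* explanatory paths
at each target−1 with the single origin fit — forecasting the unit-root
regressors themselves would produce uselessly wide intervals, and with no
lagged dependent variable the reduced form needs nothing else. Accuracy:
log-scale RMSFE, mean relative bias `mean((ŷ−y)/y)·100` on levels, and the
pooled forecast–observed correlation on levels (inflated by fixed-effect
cross-state variation; reported as such, not corrected). Level forecasts use
the lognormal-mean back-transform `exp(m + σ²/2)`; parameter-estimation
variance is excluded from point back-transforms (it is handled in the
scenario simulation, and is negligible for the point forecasts).

## Specification search and break bridging

All `2^k` subsets of the candidate national-average controls are enumerated
(binary-counter order) and scored by one-step squared log errors on an
identical set of (state, target-year) cells over a pre-break selection window
(default 2007–2010), keeping selection disjoint from the post-break bridging
window (2011–2014) to avoid confounding the two choices. The Model Confidence
Set uses the Tmax statistic (largest studentized deviation of a candidate's
mean loss from the current-set average) with a moving-block bootstrap (default
block 2) that resamples whole target years, preserving cross-state error
dependence; the full pairwise range statistic is available for small candidate
sets. The elimination sequence is run to completion and each candidate's MCS
p-value is the running maximum of stage p-values, which makes survivor sets
exactly nested across levels; exact ties are indistinguishable by
construction. Failed specifications are excluded with a warning rather than
assigned infinite loss, which would distort bootstrap variances. The final
model is the surviving spec with the lowest mean loss, ties broken toward
fewer averages.

Bridging modes for the 2011 survey redesign: `intercept_shift` (a second
state-specific constant from 2011 on), `slope_shift` (a common post-2011
slope change for the survey-measured variables and their averages), `both`,
or `none`; the mode with the lowest post-break one-step RMSFE wins, and the
condition number of each mode's within design is reported so
bridge/trend-control collinearity is visible.

A structural caveat found in the synthetic studies: under a pure per-state
level shift, `both` nests `intercept_shift` and produces near-identical
forecasts, so a strict argmin between them is close to a coin flip; and
`slope_shift` partially absorbs the shift because the realized shift is
embedded in the post-break regressor columns themselves. The intercept bridge
also pays a re-estimation noise of order σ²/n_post in its first post-break
years, only partly offset by the AR(1) persistence gain. Consequently the
intercept bridge is reliably better than no bridge under a material break,
but does not dominate the other bridging modes in repeated sampling — a
selection among near-equivalent models, not a failure of any of them.

## Scenario simulation

A permanent annual relative reduction r compounds multiplicatively, so the
year-t log effect is `t·(β_prev ln(1−r_prev) + β_cons ln(1−r_cons))` and
savings per capita are `baseline·(1−exp(Δ_t))` — approximately linear
accumulation for small r. Trials draw the elasticity vector from
N(β̂, V̂_cluster) via Cholesky (50,000 trials by default); intervals are the
2.5/97.5 trial percentiles. The regression-error back-transform applies
identically to the factual and counterfactual arms and cancels in the
difference, so it is omitted. The cross-sectional prevalence-trend elasticity
can optionally be added to the propagation (`include_cs_trend`), but defaults
off: the correlated national trends it captures need not move with a new
policy. The baseline for dollar conversion is the population-weighted
national per-capita expenditure of the baseline year, configurable; five
percent of the 2014 national smoking levels corresponds to about 0.87
percentage points of prevalence and 16 packs/year of consumption.

## Synthetic data generator

`generate_panel` inverts the model: it draws national log-trends as random
walks with drift (declining smoking, growing income/expenditure), per-state
AR(1) deviations around them (reversion 0.85; prevalence and consumption
shocks correlated 0.5 — states that quit also smoke less), state fixed
effects (sd 0.15), and an AR(1) regression error with ρ = 0.56 and stationary
sd 0.0301, then builds ln expenditure exactly from the generating equation
with the study's elasticities (prevalence 0.104, consumption 0.113, income
0.259, elderly 0.493, region tax terms, and national-trend coefficients for
elderly −0.521, Hispanic 0.048, expenditure 0.784). Measured consumption
multiplies true consumption by `exp(noise − κ·(tax − mean tax))` with
classical sd 0.05 and κ = 0.05/$ — high-tax states under-measure consumption
through untaxed cross-border inflow. The 2011 survey break adds per-state
level shifts to the survey-derived variables (defaults: prevalence +1.0 pp,
consumption −15 packs/yr, Black +0.3 pp, Hispanic +0.4 pp, with cross-state
sds; magnitudes are order-of-magnitude choices surfaced as configuration, as
no published quantification exists). With all noise switched off
(`noiseless()`), estimation recovers the generating coefficients to machine
precision — the pipeline identity check.

What the generator does **not** emulate: actual state-by-state historical
values, spatial correlation of errors beyond the common trends, policy
feedback from expenditure to smoking, and the particular cross-sectional
collinearity pattern of the real averages. Passing tests therefore establish
that the machinery is correct and calibrated under the assumed structure,
not that the real-data point estimates are reproduced.

## Numerical choices and degenerate inputs

Rank deficiency raises an error naming the collinear columns (pivoted QR).
Phillips–Perron truncation defaults to `floor(4·(T/100)^{2/9})`; p-values are
MacKinnon's asymptotic approximation, which over-rejects at T ≈ 20 per state
and is amplified by Fisher combining — the unit-root size test therefore uses
longer series and a generous band. Degenerate (constant or too-short)
residual series are excluded from the panel unit-root test and listed, not
errored. Zero-variance loss differentials in the MCS are treated as exact
ties. Scenario savings are exactly zero (degenerate interval) when both
reductions are zero. Mean relative bias is forecast-minus-observed over
observed.

## Problem sizes

The test suite and the acceptance script run the studies at the study's panel
dimensions (51 states × 23 years) with 100–200 replications for recovery and
coverage rates, 25–40 seeded runs for selection-frequency checks, and 2,000 to
50,000 Monte-Carlo trials per scenario; these sizes give sampling error well
inside the asserted bands while keeping a full run to a few minutes on one
CPU.

## Known limitations

Observational, ecological, aggregate: the model supports forecasting of
aggregate state expenditure under continuation or intensification of existing
tobacco-control policy, not individual-level prediction or radically novel
policy regimes. The one-year lag is an approximation blending short-run
adjustment with cointegration error correction. Cluster-robust intervals at
G = 51 under-cover slightly (~92–93% measured at nominal 95% in the synthetic
studies). GMM and DOLS alternatives to 2SLS are out of scope; alternative
instrument *sets* are supported through `ModelSpec`.
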