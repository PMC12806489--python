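# Methods

This note records the model, the estimation choices, and what the synthetic
test bed does and does not establish.  It is the package's own account of
its science; empirical numbers quoted here are ones the test suite or
`scripts/acceptance.py` computes.

## The response model and its estimator

The object of interest at a site is the *boundary response* of ecosystem
respiration (ER) to volumetric soil moisture (SM): the ER attainable when
moisture is the limiting factor.  It is estimated by binning growing-season
(SM, ER) pairs into 0.05 % SM bins and taking the 90 % empirical quantile of
ER per bin (linear interpolation between order statistics — the common
default definition, fixed and documented here because several conventions
exist).  Bins are half-open intervals `[k·w, (k+1)·w)` anchored at SM = 0
with centres `(k+0.5)·w`; a small additive guard (1e-9 on the bin index)
keeps values lying exactly on an edge in the upper bin despite float
division.

Two screening choices interact with the quantile and deserve care:

* **Outlier screening is within-bin for ER, global for SM.**  The screen is
  the classical mean ± 2 SD rule, but applied to ER *inside each bin*
  (before the quantile) rather than to the pooled ER sample.  The reason is
  scale-equivariance: ER magnitude varies several-fold along the response,
  so a single pooled threshold sits near the response apex and deletes
  precisely the valid high-flux records that define the boundary there —
  flattening the peak and biasing both side slopes low (we measured a ~20 %
  apex shave and 30 %+ slope attenuation with the pooled variant on
  synthetic data).  Within-bin screening removes the same multiplicative
  range everywhere, which leaves the boundary shape intact.  SM itself has
  no response-dependent scale, so it is screened globally.  Bins with fewer
  than 3 records, or zero spread, are left unscreened.
* **Sparse bins are dropped.**  The upper quantile of 1–2 records is noise
  that can exceed the true peak under multiplicative error; bins with fewer
  than `min_bin_n = 5` records are excluded before smoothing.  The binning
  primitive itself keeps every non-empty bin; the threshold is a pipeline
  option.

The boundary points are smoothed with a centred 3-bin running average and
fitted with one univariate penalized cubic B-spline smooth (basis dimension
`min(10, n−1)`, penalty weight selected by generalized cross-validation
over a logarithmic grid, `1e-4 … 1e7`).  GCV was chosen over
likelihood-based selection because it is what the available fitting
machinery supports natively; on the synthetic test bed the two would be
expected to differ negligibly, as the curve R² is governed by boundary
noise, not penalty fine-tuning.  A constant boundary short-circuits to a
flat fit with R² = 0.

## Optimum detection

The candidate optimum is the SM centre at the unique maximum of the fitted
spline.  Adjacent exact ties collapse to their midpoint; non-adjacent ties
abort (`multiple_maxima`).  Detection succeeds only when the candidate is
strictly interior, each side retains at least 3 smoothed points (the
optimum point belongs to both sides), and ordinary least squares *on the
smoothed boundary points* gives slope > 0 with p ≤ α below and slope < 0
with p ≤ α above (two-sided t tests, α = 0.05 by default).  The side
regressions use the smoothed points rather than the spline values or the
raw half-hourly records: the points are the data the spline itself sees,
and the side slopes are then interpretable as boundary sensitivities in
µmol m⁻² s⁻¹ per % SM.

Two estimator properties worth knowing:

* **Apex displacement on asymmetric peaks.**  A 10-basis penalized spline
  rounds a kinked (tent-shaped) apex and shifts its maximum slightly toward
  the flatter side — about +1 SM point for slopes (0.30, 0.15) at the
  default configuration.  This is a smoothing bias, common to any GAM-type
  fit, and is the dominant term in the ~0.8–1.1 SM-point mean recovery
  error the acceptance suite measures; it cancels in cross-site regressions
  (it is nearly constant across sites, moving the intercept, not the
  slope).
* **Selection effect on flat responses.**  Regressing away from a *chosen*
  argmax is conditionally biased: on an exactly flat (plateau) response the
  points right of the selected maximum trend down by construction, so the
  declining-trend test rejects a flat truth more often than α suggests.
  Range-truncated sites (the response still rising at the wettest observed
  SM) do not suffer from this and are the reliable negative control; the
  plateau variant is provided but its rejection rate should not be expected
  to reach 1 − α.

## Confounder controls

*Partial Spearman*: all variables are rank-transformed, ranked SM and ER
are residualized on the ranked covariates (radiation, air temperature,
VPD) by least squares with intercept, and the Pearson correlation of the
residuals is returned; with no covariates this is exactly Spearman's r.
Spearman captures monotone, not unimodal, association — the statistic is
reported as described without further transformation, and its site-level
spread (sites with low optima correlate negatively, high optima
positively) is what makes the cross-site partial-vs-marginal regression
informative.  Note that partialling out a covariate that genuinely drives
ER (e.g. temperature through Q10) *raises* the SM–ER rank correlation;
parity between partial and marginal correlations is therefore expected
only when the covariates are independent of ER, which is how the
confounder-free test bed is configured.

*SHAP re-detection*: a random-forest regression of ER on SM, radiation,
temperature and VPD (LightGBM in random-forest mode: 500 bagged trees,
bagging fraction 0.8, feature fraction 0.9, fixed seed), with exact
path-dependent TreeSHAP attributions; in random-forest mode the library
reports per-tree contribution sums, which are divided by the tree count so
that baseline + attributions equals the prediction to machine precision
(the additivity identity is asserted to 1e-6 relative, measured ~1e-14).
The per-record SM attribution is pushed through the identical
bin → smooth → fit → detect chain.  With duplicated features the usage-
dependent attribution may credit one twin, but the twins' *sum* preserves
the single-feature attribution (measured ratio 1.00); under a pure
radiation-driven confounding scenario the SM attribution collapses to
< 2 % of the radiation attribution and the SHAP-space response loses its
amplitude, which is the meaningful signature of the control.

## Cross-site driver analysis

Relative weights follow Johnson's orthogonal-transformation estimator:
with `R_xx = PΔP'` the predictor correlation matrix and `r_xy` the
predictor–response correlations, `Λ = PΔ^{1/2}P'`, `β = Λ⁻¹ r_xy`, and the
raw weight of driver j is `Σ_k Λ²_jk β²_k`.  Raw weights are nonnegative,
sum to the OLS R² (asserted to 1e-8 against an independent OLS), and equal
squared correlations under exact orthogonality.  Singular `R_xx` aborts
with the most collinear pair named.

Ridge regression is run on z-scored variables (sample SD), penalty chosen
by efficient leave-one-out cross-validation over `1e-4 … 1e4`, coefficients
reported on the standardized scale, and 95 % confidence intervals from a
percentile bootstrap over sites (1000 replicates by default, re-
standardizing within each replicate, penalty held at the full-sample
choice for stability).  A coefficient is significant when its CI excludes
zero.  Per-coefficient 95 % intervals imply a ~5 % false-positive rate per
null driver — with 11 null drivers, some replicate will usually flag one;
the meaningful claims are the true driver's power (its CI excludes zero in
≥ 90 % of repeats) and calibration (null drivers flagged at ≈ the nominal
rate), which is what the acceptance suite asserts.

The optimum–moisture law is fitted by OLS across sites and across
vegetation-class means (classes weighted equally by default; a site-count
weighted variant is available — point size in the usual presentation of
such figures is display, not weighting).  A class with one site keeps its
point with a missing standard error.

Wilcoxon signed-rank comparison of Sen_below vs Sen_above drops zero
differences, enumerates the exact null for ≤ 25 untied pairs, and
otherwise uses the normal approximation with tie-corrected variance
`n(n+1)(2n+1)/24 − Σ(t³−t)/48` and a 1/2 continuity correction; the two
paths agree within 0.002 in p at n = 25 on the test bed.

## The synthetic test bed

`synth` generates half-hourly site series built to make every pipeline
stage falsifiable:

* **Soil moisture** — seasonal (cosine, peak day 81) + AR(1) latent
  dynamics mapped rank-preservingly (probability integral transform) onto
  the site's bounded wet–dry range (default 25 ± 20 %).  The near-uniform
  marginal keeps 0.05 % bins evenly occupied; with uneven occupancy the
  small-sample bias of the within-bin quantile tilts the boundary along the
  density gradient, which a 600-point segment regression will declare
  "significant".  The early-spring moisture peak averages to ~zero over the
  radiation-defined growing season, so the realized growing-season mean
  (the `SM_growth` covariate) measures the site's range centre without
  seasonal aliasing.
* **Sampling** — records are strided so any `n_records` spans at least one
  full annual cycle (5000 records ≈ 2-hourly over 14 months).  This mimics
  the sparseness of quality-filtered flux data and prevents a short record
  from aliasing the seasonal cycle into seasonal means.
* **ER** — a piecewise-linear tent in SM (so the side slopes have exact
  generator values) times `Q10^((T−T_ref)/10)` times lognormal noise
  (multiplicative, flux-proportional error being the standard model for
  night-time eddy-covariance data).  The stochastic multiplier is
  normalized so that its 90th percentile *after* a 2-SD within-scale screen
  equals one, making the configured tent the exact infinite-data boundary
  of the post-screen data — without this the truth would be the tent times
  an unknowable constant.  ER is floored at zero.
* **Temperature** — diurnal cycle (5 °C amplitude) plus fast synoptic
  AR(1) noise (4 °C SD, hours-scale memory).  Deliberately no deterministic
  seasonal term: a slow temperature component phase-locks with the seasonal
  moisture cycle inside the growing season (or, if stochastic, produces
  realization-level spurious SM–T correlations of |r| ≈ 0.2 from the few
  effective degrees of freedom per season) and would tilt the boundary
  outside the explicit coupling.  SM–confounder correlation is injected
  only through `confound_r`, via a Gaussian mixing weight that accounts for
  each confounder's deterministic variance; an unreachable target raises.
  For radiation the coupling acts on the cloudiness driver, since the
  day–night cycle caps the achievable whole-series correlation.
* **Networks** — per-site growing-season moisture targets drawn uniformly,
  true optima following `a + b·SM_growth + N(0, scatter)` (defaults 3,
  0.86, 3 %), infeasible optima handled by widening the site's range
  (logged), covariates other than the realized moisture/meteorology means
  drawn as independent noise.

What passing tests show: the estimator chain recovers known optima to
~1 SM point, side slopes to ~5 %, rejects range-truncated sites, is robust
to bin-width and quantile choices, and transmits a known cross-site law
end-to-end with honest CI coverage.  What they do not show: behaviour under
real-data pathologies the generator deliberately omits — u*-filtering
artifacts, energy-balance closure errors, instrument drift, gap-filling
structure, multi-year nonstationarity, or soil-moisture sensors that
saturate.  Time scales are compressed (hours-scale weather memory, one
annual cycle); the generator is a statistical emulator, not a hydrological
model.

## Numerical and interface choices

Missing values: the FLUXNET sentinel −9999 and any non-finite value are
treated identically as missing.  Timestamps are site-local, never
converted.  The growing season is days whose 15-day-smoothed daily-mean
GPP reaches p5 + 0.1·(p95 − p5) of the smoothed series (threshold and
window configurable; an explicit day-of-year window can override when GPP
is absent); with zero GPP amplitude every day is in season.  Outlier
screening uses the sample SD (ddof = 1); at SD = 0 everything is kept.
All stage failures downstream of I/O are data outcomes carried as reason
codes (`boundary_max`, `nonsig_below`, `nonsig_above`, `too_few_points`,
`multiple_maxima`, `too_few_bins`, `empty_after_*`), not exceptions.
Every stochastic step (forest bagging, bootstrap, generators) takes its
seed from one configuration value.
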