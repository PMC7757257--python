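# Methods

This note documents the statistical models, conventions, and synthetic-data
design behind `gppclim`, and what the passing test suite does and does not
demonstrate about real data.

## Data model and geometry

All gridded fields are monthly `time x lat x lon` arrays
(`GriddedSeries`) on regular cell-center grids stored south-to-north,
−180→180; readers normalise other orientations on ingest. Cell areas are
exact spherical rectangles, `A = R² Δλ (sin φ_top − sin φ_bottom)` with
R = 6371 km, so the global sum equals 4πR² to rounding. All regional
statistics (integrals, means, fractions) are area-weighted by default; a
cell-count convention is available where a caller prefers it. Missing data
live in an explicit boolean mask and all reductions are mask-aware;
cross-product comparisons are complete-case (a cell missing in any product is
excluded), which is the only symmetric choice when products are compared
pairwise. Carbon-flux unit conversions (gC/m²/month ↔ gC/m²/yr ↔ PgC/yr,
factor 10⁻¹⁵ g→Pg with cell areas in m²) are centralized in one table.

Regridding is integer-factor, area-weighted block averaging only; a coarse
cell with all-missing children is missing. Arbitrary-grid remapping is out of
scope.

The stand-in "vegetated land" mask keeps cells whose multi-product mean
annual GPP exceeds a floor (default 10 gC/m²/yr); the floor is configuration,
not science, and any externally supplied land/biome mask can be used instead.

## The LUE GPP model

`GPP = FPAR × PAR × LUE_max × f(T_min) × f(VPD)` per cell and month, in
gC/m²/month. The environmental scalars are piecewise-linear clamped ramps in
the MOD17 convention: `f(T_min)` is 0 at or below `tmin_min`, 1 at or above
`tmin_max`; `f(VPD)` is 1 at or below `vpd_min` (moist air) and 0 at or
above `vpd_max`. PAR is taken as 45% of downward shortwave, converted to
MJ/m²/month with the true month length (`0.45 × SW × 86400 × days × 10⁻⁶`);
0.45 is the standard literature value for the PAR fraction. Parameters are
biome-indexed user data: the package ships two clearly labelled illustrative
tables (four biome classes) whose pairing forms the two-member structural
ensemble, and any table can be supplied through the YAML config. A Magnus-
formula helper (`e_s = 610.94 exp(17.625 T / (T + 243.04))` Pa) is provided
for computing VPD from temperature and relative humidity, without asserting
any particular upstream VPD convention. The model is memoryless by
construction — permuting years permutes outputs identically — and monotone:
non-decreasing in FPAR, PAR, LUE_max and T_min, non-increasing in VPD.

## Anomalies, trends, IAV

Anomalies subtract the full-period mean at monthly (per calendar month),
seasonal (standard meteorological DJF/MAM/JJA/SON, with DJF of year Y using
December of Y−1 so the first year's DJF is missing), or annual scale. Trends
are ordinary least squares against calendar year, with two-tailed p-values
from the t distribution on n−2 degrees of freedom; a perfectly constant
series is reported as slope 0 with zero standard error. Detrending subtracts
the fitted line and restores the original mean, so detrended series keep
their baseline; IAV is the sample standard deviation (ddof = 1) of the
detrended annual series. Ensemble statistics are the element-wise mean and
the 1σ sample spread across members (zero for a single member).

## Climate-only extraction from S1/S2 pairs

Paired simulations isolate the climate signal: S1 carries CO2 forcing only
(its interannual variability is recycled early-century climate, i.e. none in
the synthetic emulation), S2 carries CO2 plus climate. For every grid cell
and calendar month we fit a linear OLS trend in year to S1 and subtract the
*centered* fitted variation (`slope·(year − ȳ)`) from S2, preserving S2's
long-term mean — the anchoring is a convention choice; centering is the one
that leaves anomaly baselines untouched. The result's per-month trend is
trend(S2) − trend(S1) up to rounding, exactly nulling a shared trend and
leaving a trendless S1 without effect. A quadratic option exists for
curvature in the CO2 response, but the default is linear: a subtracted
"trend" is operationally a fitted polynomial in time, and linear is the
minimal faithful choice.

## The sensitivity regression and its decompositions

The central model regresses annual GPP anomalies on annual temperature,
precipitation, and radiation anomalies:

GPP_y = γ·TEMP_y + λ·PREC_y + δ·RAD_y + ε_y.

Conventions:

* **Intercept.** An intercept is always fitted by default even though
  anomalies have near-zero mean: omitting it would bias the slopes whenever a
  detrending or anomaly convention shifts the mean. It is switchable.
* **Detrending.** For IAV analysis all four series are detrended before the
  fit (`detrend_first=True`, the default). For trend attribution the fit runs
  on raw series, and each driver's contribution is the OLS trend of its
  reconstructed component γ·TEMP etc.; by linearity of OLS the three
  contributions plus the residual trend equal the total GPP trend to machine
  precision, a closure asserted per cell in the tests.
* **Inference.** Closed-form OLS with t-based standard errors on n−k
  degrees of freedom (k = 4 with intercept). When the inputs were detrended
  first, the quoted degrees of freedom do not discount the detrending step;
  with 35 years this overstates precision by under 2% and inflates type-I
  rates from 5% to roughly 5.5–6% — visible in the null-data tests and
  accepted as the conventional practice the pipeline mirrors. No
  multiple-testing correction is applied to significance maps by default
  (matching common practice for such maps); a Benjamini–Hochberg option is
  available.
* **LMG relative importance.** Each regressor's share of the full-model R² is
  its R² increment averaged over all 3! = 6 entry orders, enumerated
  explicitly. Subset R² values come from centered moment matrices
  (`R²(S) = s_yS' S_SS⁻¹ s_yS / s_yy`), which ties all seven subset
  evaluations to one covariance computation; the test oracle independently
  refits every submodel by least squares. Shares are non-negative, sum to R²,
  are invariant to positive rescaling of any regressor, and permute with the
  labels.
* **Aggregation to global driver contributions.** Per-cell LMG shares are
  first renormalized to sum to one — attributing all *explained* variability
  and leaving the unexplained share out of the budget — then weighted by the
  cell's IAV magnitude and area and aggregated, so the three percentages sum
  to 100. Whether to carry the unexplained variance through instead is a
  genuine convention fork; renormalization is the choice that yields a
  closed three-way budget.
* **Trend normalization.** Two conventions ship as named options: dividing a
  trend map by the area-weighted mean |trend| over vegetated cells
  (`mean-abs`, the default), or by a supplied globally integrated trend
  (`global-integral`). They differ in sign behaviour and magnitude; neither
  is asserted as canonical.

Rank-deficient designs fail loudly, naming the collinear pair. Fits need at
least 8 years; per-cell map fits skip masked or incomplete cells.

## Comparison diagnostics

The critical correlation threshold is `r* = t*/√(n−2+t*²)` with t* the
two-tailed t critical value on n−2 df; for n = 35 this gives 0.28, 0.33, 0.43
at P < 0.1, 0.05, 0.01. Cross-product correlation maps use the detrended
annual ensemble-mean anomalies per cell (member-pair spread is available
separately). Relative IAV maps divide each cell's σ by the area-weighted
vegetated-mean σ, so their weighted mean is 1. Trend-sign agreement counts
the vegetated area where all products share a strict sign; cells where any
product's |trend| < 10⁻¹² cannot assert a sign and count as disagreement
(configurable). Biome-grouped IAV normalizes per-cell σ by the global mean
cell σ and summarises each biome by quartiles — the procedure applies
unchanged to GPP or any proxy field such as solar-induced fluorescence.

## The synthetic-data generator

The generator is the pipeline's ground truth and emulates the statistical
structure the analysis assumes:

* **Climate.** Each variable is `climatology(month, lat) + trend·(t − t̄) +
  AR(1) anomalies`, monthly, with the seasonal cycle peaking in July north of
  the equator and January south of it. Anomalies are AR(1) month-to-month
  (default coefficient 0.3) rather than white noise, because the regressions
  run on annual means and autocorrelation is the realistic stress. The
  scenario states the anomaly sd on the *annual* scale — the scale the
  analysis uses — and the monthly innovation variance is set analytically so
  the stationary 12-month mean has exactly that sd. Defaults: anomaly sd
  0.5 °C / 8 mm/month / 4 W/m²; trends +0.3 °C, +0.5 mm/month, +0.5 W/m² per
  decade; 35 years; precipitation clipped at zero (the default mean keeps
  clipping inactive).
* **Sensitivities.** Three latitude belts emulate the broad observed pattern:
  temperature-dominant extratropics (|lat| ≥ 35°: γ = 50, λ = 0.8, δ = 1.5),
  precipitation-dominant semiarid subtropics (15–35°: γ = 10, λ = 3, δ = 1),
  and a radiation-important wet tropical belt (< 15°: γ = 15, λ = 1, δ = 6),
  in gC/m²/yr per °C, mm/month, and W/m². At the default anomaly scales the
  dominant driver's signal sd is roughly three times its competitors'.
* **GPP ensembles.** Member m adds to a seasonal baseline the response
  `Σ_d coef_d·(1 + jitter_{m,d})·driver_response_d` plus white residual noise
  (annual-scale sd 10 gC/m²/yr). The multiplicative jitter (10% relative,
  per member per coefficient, uniform across cells) emulates structural
  ensemble spread; 3 members by default. The truth record stores base and
  per-member coefficients — the effective truth of the ensemble-*mean* series
  is the member-mean coefficient, which is what recovery tests target — and
  suffices to reconstruct noiseless members exactly.
* **S1/S2 pairs.** S1 = baseline + CO2 ramp (+ optional noise); S2 adds the
  climate response. Noiseless pairs make the extraction algebra exact.
* **FPAR.** A monthly climatology plus a precipitation-anomaly coupling and
  noise, clipped to [0, 1].
* **Reproducibility.** Every generator is a pure function of (scenario,
  seed); substreams are derived by hashing the generator's name into the seed
  sequence, so adding generators never shifts existing streams.

What the generator does *not* emulate — and hence what passing tests cannot
show: ENSO-like teleconnection patterns (anomalies are spatially
independent), realistic land/ocean geography, vegetation memory and lagged
climate responses, non-linear or time-varying sensitivities, observational
error structure, and the spatial error correlation of real products. Tests on
this world validate the *machinery* (estimators, conventions, closures,
error rates), not the climate realism of any conclusion drawn from real data.

## Problem sizes and numerical choices

Routine tests run on an 18 × 36 (10°) or 6 × 12 (30°) grid over 35 synthetic
years — large enough for area-weighting and fraction statistics to be
meaningful, small enough for a seconds-scale suite; the null-hypothesis
error-rate checks use a 36 × 72 (5°) grid for ≥ 2000 cells, and the
acceptance script mirrors these sizes. Exactness claims (trend-budget
closure, S1/S2 recovery, LMG-oracle agreement) are asserted at 10⁻⁹–10⁻¹⁰
absolute; statistical claims use Monte-Carlo bands wide enough for their
replication counts. Degenerate inputs are defined, not accidental: constant
series have zero trend and zero se, zero-variance regressors and empty
regions raise, and all-zero trend maps refuse normalization.

## Known limitations

* Trend significance ignores residual autocorrelation; an AR-corrected
  option would be the natural extension.
* The per-calendar-month S1 trend removal assumes the CO2 response is
  adequately linear (or quadratic) in time over the window.
* The vegetated mask is a GPP-floor heuristic, not a land-cover product.
* Seasonal-scale sensitivity fits reuse the annual machinery per season;
  cross-season covariance is not modelled.
* The LMG decomposition is exact only for the three fixed regressors; the
  implementation does not generalise to arbitrary regressor counts.
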