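# gppclim

Climate-driven variability and trend attribution for gridded gross primary
productivity (GPP).

## The problem

Terrestrial GPP — the carbon plants fix by photosynthesis — cannot be observed
directly at global scale. Long (multi-decade) GPP estimates come from
fundamentally different families of products: machine-learning upscalings of
flux-tower observations, satellite-driven light-use-efficiency (LUE) models,
and process-based vegetation model ensembles. Understanding whether these
products agree on *where* GPP varies from year to year, *which climate driver*
(temperature, precipitation, or radiation) controls that variability, and
*what drives their long-term trends* is a prerequisite for trusting any of
them.

`gppclim` packages that comparison workflow as a tested, reusable pipeline for
anyone working with monthly `time x lat x lon` carbon-flux and climate grids:

* **LUE GPP model** — `GPP = FPAR x PAR x LUE_max x f(T_min) x f(VPD)` with
  biome-dependent parameters and a two-parameter-set structural ensemble;
* **climate-only signal extraction** — given paired simulations (CO2-only
  "S1" vs CO2-plus-climate "S2"), remove S1's per-calendar-month trend from
  S2 to isolate the climate-driven GPP component;
* **anomaly / trend machinery** — monthly, seasonal, and annual anomalies
  from the multi-year mean; OLS trends; detrending; interannual variability
  (IAV) as the 1σ of the detrended annual series; ensemble means and spreads;
* **sensitivity attribution** — the three-driver regression

  GPP_y = γ·TEMP_y + λ·PREC_y + δ·RAD_y + ε_y

  fitted per region or per grid cell (detrended for IAV work, raw for trend
  attribution), with Lindeman–Merenda–Gold (LMG) relative-importance shares
  of R² computed by exact enumeration of the 3! orderings, driver-wise trend
  contributions (the OLS trend of γ·TEMP etc.), and trend normalization;
* **comparison diagnostics** — per-cell cross-product Pearson correlations
  with analytic critical-r thresholds, relative-IAV hotspot maps, biome-
  grouped IAV distributions, trend-sign agreement fractions, and areal
  fractions of significant sensitivities, all area-weighted on the sphere;
* **a synthetic-data generator** — gridded climate with seasonal cycles,
  prescribed linear trends and AR(1) interannual anomalies, FPAR coupled to
  precipitation, and multi-member GPP ensembles built from *known* per-cell
  sensitivities — so every stage of the pipeline can be validated against
  ground truth.

The regression core follows the statsmodels idiom: build a
`ClimateSensitivityModel` from four series (or a DataFrame), call `fit()`,
and read coefficients, standard errors, p-values, R², confidence intervals,
LMG shares and trend decompositions off the returned
`ClimateSensitivityResults`.

## Worked example

Generate a 35-year synthetic world on an 18 x 36 grid, fit the sensitivity
regression at one northern-hemisphere cell, and compare with the generator's
truth:

```python
import numpy as np
from gppclim import (Grid, ClimateScenario, GPPScenario, gen_climate,
                     gen_gpp_ensemble, fit_climate_regression, critical_r)

grid = Grid.global_grid(10.0)
climate = gen_climate(ClimateScenario(grid=grid, seed=42))
ensemble, truth = gen_gpp_ensemble(climate, GPPScenario.default(grid, seed=42))

years, gpp, _ = ensemble.mean().annual_means()
_, temp, _ = climate.temperature.annual_means()
_, prec, _ = climate.precipitation.annual_means()
_, rad, _ = climate.radiation.annual_means()

i, j = 15, 20  # a northern-hemisphere cell
res = fit_climate_regression(gpp[:, i, j], temp[:, i, j], prec[:, i, j],
                             rad[:, i, j], detrend_first=True, years=years)
print(res.summary())
```

prints

```
Climate sensitivity regression (OLS)
==========================================================
n = 35    df_resid = 31    R^2 = 0.9221    detrended = True
----------------------------------------------------------
                   coef         se        t    P>|t|
       gamma      45.79      2.417     18.9 1.33e-18
      lambda     0.7706     0.1375      5.6  3.8e-06
       delta      1.127     0.2691     4.19 0.000215
   intercept     -212.3      71.16    -2.98  0.00552
----------------------------------------------------------
LMG shares of R^2: temp=0.8560  prec=0.0466  radi=0.0196
```

Reading this: at this cell GPP gains ≈ 45.8 gC/m²/yr per °C of temperature
anomaly (the generator's true effective value is 46.7 — inside the 95%
confidence interval), temperature explains ≈ 86% of the interannual variance
(LMG share 0.856 of R² = 0.922), and all three sensitivities are significant
at P < 0.01. For correlation maps, `critical_r(35, 0.05)` → `0.33`: any
35-year cross-product correlation above |0.33| is significant at P < 0.05.

A command-line interface mirrors the pipeline stages
(`gppclim simulate | lue | climate-only | anomalies | attribute | diagnose`);
see `gppclim --help`.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and what it does (and does not) emulate, the numerical conventions
(detrending, intercepts, tie-breaks), and known limitations.
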