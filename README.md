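# panicov

Rice panicle-coverage dynamics from nadir RGB imagery, and yield prediction
from the fitted dynamics.

After heading, the fraction of a rice canopy occupied by panicles — the
*panicle coverage*, PC = PA / (PA + BA) over the pixels of a segmented
1 m² plot image — rises sigmoidally, plateaus, and declines as grains fill
and panicles droop out of nadir view. `panicov` models one plot's coverage
time series with a piecewise function

```
f(x) = K / (1 + exp(-g (x - d0)))                      x <= d1
f(x) = K / (1 + exp(-g (d1 - d0))) - a (x - d1)^2      x >  d1
```

whose five parameters summarize the whole trajectory: **K** the maximum
coverage, **g** the growth rate (day⁻¹), **d0** the day of maximum growth
rate (inflection, where f = K/2), **d1** the growth→decline transition day,
and **a** the decline curvature (day⁻²). These parameters, fitted per plot
by bounded nonlinear least squares, then predict yield and its components
(Yield, GN, PN, GNP, TGW, FGR) with four regressors — PLSR (3 components),
random forest, gradient boosting and XGBoost (100 estimators, learning
rate 0.05) — scored by leave-one-out cross-validation (pooled RMSE and R²)
and explained by exact Shapley feature attribution.

The package is aimed at crop-phenotyping researchers who have (or want to
prototype against) segmented canopy image time series. Because field
imagery of this kind is rarely public, a first-class synthetic-data module
generates canopy images with known panicle masks, coverage series with
controlled observation noise, and yield tables with a realistic correlation
structure, so every pipeline stage is testable offline.

## Modules

| module | what it does |
|---|---|
| `synthetic_data` | scenario configs; synthetic images+masks, coverage series, yield tables |
| `dataset_prep` | 512×512 tiling, augmentation (brightness/contrast, noise, rescale), 7:2:1 splits |
| `segmentation_eval` | pixel accuracy, precision, recall, F1, per-class IoU and mIoU |
| `coverage_extraction` | resize→9-tile→segment→average pipeline; pluggable segmenter contract |
| `piecewise_model` | evaluate / initial-guess / fit / fit-table for the five-parameter model |
| `yield_prediction` | Pearson screen, LOOCV for the four regressors, Shapley attribution |

## Worked example

```python
import numpy as np
from panicov import synthetic_data as sd, piecewise_model as pm, yield_prediction as yp
from panicov.reference_params import treatment_params

# simulate one plot under the zero-nitrogen 2023 field conditions and refit
truth = treatment_params("23-F-0N")           # K=0.2512, g=0.2738, d0=9.9412, ...
cfg = sd.ScenarioConfig(true_params=truth, noise_sd=0.01, seed=7)
(series,) = sd.generate_coverage_series(cfg)  # 15 visits, days 0..56
res = pm.fit(series.days, series.coverage)
print(res.params.as_dict(), res.r_squared)
# {'K': 0.2563, 'g': 0.2435, 'd0': 10.5098, 'a': 0.0003, 'd1': 27.6021}  R²=0.9964

# a 200-plot synthetic campaign: correlation screen and LOOCV yield model
params = sd.sample_params_envelope(200, seed=42)
table = sd.generate_yield_table(params, seed=43)
r, p, stars = yp.correlation_screen(table)
print(r.loc[["K", "d0", "d1"], ["Yield", "GN", "FGR"]].round(2))
#     Yield    GN   FGR
# K    0.87  0.87  0.33
# d0  -0.30 -0.29 -0.62
# d1  -0.30 -0.35 -0.66
cv = yp.loocv(table, "rfr", "Yield", seed=0)
print(cv.r_squared, cv.rmse)   # 0.873  302.8 kg/ha
```

With 1% observation noise on a 15-day series the five parameters come back
close to the truth (K within ~2%, the timing parameters within about a
day) and the fit explains >99% of the variance. On the synthetic campaign
the maximum coverage K dominates yield prediction, the timing parameters
d0/d1 correlate negatively with the filled-grain ratio, and a random
forest under LOOCV explains ~87% of yield variance — the qualitative
behaviour the method is designed to expose.

There is also a CLI (`panicov simulate|prep|eval|coverage|fit|predict`);
run `panicov --help` for the surface.

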