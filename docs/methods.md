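# Methods

## The model

Panicle coverage after heading is modelled as a sigmoid growth phase that
hands over to a quadratic decline at a transition day `d1`:

    f(x) = K / (1 + exp(-g (x - d0)))                     x <= d1
    f(x) = K / (1 + exp(-g (d1 - d0))) - a (x - d1)^2     x >  d1

The two branches agree at `x = d1` by construction, so the curve is
continuous; it is monotone increasing up to `d1` and (for `a > 0`)
monotone decreasing after. `f(d0) = K/2` is an exact identity of the
logistic branch and is used as a model self-check throughout the tests.
The function value is *not* clamped: far past `d1` the quadratic goes
negative, which is the honest model value; physical-coverage consumers
clamp at the boundary where they need to.

Parameters, units, and the defaults/bounds used in fitting:

| parameter | meaning | unit | fit bounds |
|---|---|---|---|
| K  | maximum coverage | fraction | (0, 1] |
| g  | sigmoid steepness | day⁻¹ | (0, 5] |
| d0 | day of maximum growth rate | days | [0, max observed day] |
| d1 | growth→decline transition | days | d0 + δ, δ ∈ (0, max day + 10] |
| a  | decline curvature | day⁻² | [0, 0.05] |

Coverage is a fraction in [0, 1] everywhere inside the package; percent
appears only at report boundaries. The day axis convention is day 0 =
first post-heading observation (published transition days of ~17–40 under
this convention sit inside a 0–60 day observation window).

## Fitting

`piecewise_model.fit` minimizes the residual sum of squares with SciPy's
trust-region-reflective bounded least squares (`xtol/ftol/gtol = 1e-15`,
so the solver runs to numerical stationarity). The ordering constraint
`d1 > d0` is enforced by reparameterization — the solver works with
`δ = d1 − d0 > 0` — rather than an inequality constraint, which keeps the
problem a plain box-bounded one. Non-convergence is reported via
`converged=False` with the best parameters found; parameters pinned at a
bound are listed in `bounds_hit`.

Initial guesses are taken from the observed trend: `K₀` = max coverage,
`d1₀` = day of the max, `d0₀` = interpolated first crossing of `K₀/2`,
`g₀ = 4·max-slope/K₀` (the logistic maximum-slope identity
`f'(d0) = gK/4`), and `a₀` = the least-squares coefficient of
(peak − coverage) on (day − d1₀)² over post-peak points, floored at 0. A
series with no rise (constant or decreasing) fails fast with `FitError`
rather than returning a meaningless fit.

Goodness of fit is `R² = 1 − SSres/SStot` against the series mean; it can
be negative for a terrible fit and is not clipped. Fitted curvature is
reported at full precision (some published treatments print `a = 0`,
which recovery shows to be rounding of values ≈ 1e-4).

Recovery behaviour, measured by the test suite: from noiseless curves
sampled at integer days 0–60, all 18 published treatment parameter sets
are recovered to better than 1e-7 relative; with Gaussian observation
noise of sd 0.01 on 15 observation days, the median relative error of K
across the published parameter envelope is ≈ 2%.

## Coverage extraction

An image is resized to 1536 × 1536 (bilinear; masks always nearest-
neighbor so they stay binary), cut into nine 512 × 512 tiles in row-major
order, each tile is segmented by a pluggable callable (RGB tile → binary
mask of the same shape), per-tile coverage is `PC = PA/(PA+BA)`, and the
plot value is the arithmetic mean of the nine tiles. For equal-area tiles
this mean equals the stitched-mask coverage exactly (a rational-arithmetic
identity on pixel counts), which the tests assert bitwise.

Trained segmentation networks are out of scope by design; the segmenter is
a contract. Two reference implementations ship: a deterministic color-rule
segmenter (axis-aligned RGB box) sufficient for synthetic imagery, and a
`MaskDirectorySegmenter` adapter that serves precomputed masks (e.g. deep
model outputs) through the identical tiling/averaging path. Duplicate
same-day images of a plot are averaged; plots with fewer than 5
observations are flagged, since 5 observations cannot constrain 5
parameters.

## Segmentation metrics

`segmentation_eval` computes, from exact pixel confusion counts with
panicle as the positive class: pixel accuracy (TP+TN)/total, precision
TP/(TP+FP), recall TP/(TP+FN), F1 (harmonic mean), IoU_panicle
TP/(TP+FP+FN), IoU_background TN/(TN+FP+FN), and mIoU = mean of the two
class IoUs. Averaging over the two classes (rather than foreground-only
IoU) is the convention that makes pixel accuracy ≈ 0.98 coexist with
mIoU ≈ 0.6–0.8 on background-dominated canopy images. Zero-denominator
metrics are defined as 0 and flagged, keeping dataset aggregation total.
Dataset aggregation supports micro (sum counts, then compute) and macro
(mean of per-image metrics); whether a published number is micro or macro
is often unstated, so both are first-class and the report records which
was used. The identity `IoU = F1/(2−F1)` and an exhaustive per-pixel-loop
oracle over all 3×3 mask pairs guard the implementation.

## Dataset preparation

Tiling requires dimensions divisible by the tile size and reconstructs the
input exactly. Augmentation draws one operation per variant: Gaussian
noise (sd = 0.02 of the 0–255 range by default; the source protocol leaves
it unstated), brightness/contrast with factors uniform in [0.8, 1.2],
or up/down rescaling (factors in [1.1, 2.0] / [0.6, 0.9]) followed by
center crop/pad back to the original canvas so tensor shape is constant.
Masks follow geometric ops by nearest-neighbor and ignore photometric
ops; the mask value set {0, 1} is invariant. Multiplicity 2 (originals
plus two variants) triples a dataset — 867 sources → 2,601 items.

Splits use largest-remainder apportionment of the unit count by the
(0.7, 0.2, 0.1) ratios with a seeded shuffle. By default splitting happens
at the *source* level so augmented copies of one photograph can never
land in different partitions — stricter than splitting the augmented pool
itself, which risks leakage; item-level splitting remains available by
omitting the source map.

## Yield prediction

The screen reports Pearson r with two-sided p per (parameter, component)
pair, with the usual 0.05/0.01/0.001 star convention; zero-variance
columns are flagged, not silently dropped. The four regressors are fixed
configurations (PLSR with 3 latent components and in-fold
standardization; RFR with 100 trees; GBR and XGBR with 100 stages at
learning rate 0.05); no hyperparameter search is re-run since the search
space behind those choices is not recorded. LOOCV trains n models of n−1
records and scores the pooled out-of-fold predictions once — per-fold R²
is undefined for singleton folds, so pooling is the only coherent
convention, and RMSE = sqrt(mean squared error) with the `1/2`-divisor
variant available behind `literal_half=True` for comparison with reports
that print that form.

Feature attribution for the tree ensembles computes **exact interventional
Shapley values** by enumerating all 2⁵ = 32 feature coalitions and
marginalizing absent features over a background sample. With five
features exhaustive enumeration is cheap and exact, so the efficiency
property — base value + contributions = prediction — holds to machine
precision for every record, and that additivity is asserted as an
invariant. XGBoost's built-in tree-path contributions serve as an
independent cross-check route in the tests (the two algorithms condition
differently, so they are compared on additivity and dominant-feature
agreement, not value-for-value). The PLSR pipeline, being linear, is
attributed by coefficients: φⱼ = wⱼ(xⱼ − x̄ⱼ).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical skeleton* of a field campaign:

- **Coverage series** follow the piecewise model exactly, plus additive
  Gaussian noise truncated to [0, 1] (noise sd 0.01 by default; the
  observation-error model of real segmented imagery is not published, and
  Gaussian is the least-structured choice that keeps least squares
  well-posed). Default sampling: 15 visits at 4-day spacing over days
  0–56, consistent with a 3–7-day revisit interval and covering every
  transition day in the published envelope.
- **Multi-plot scenarios** draw each parameter uniformly and independently
  within its published min–max envelope across 18 treatments, rejecting
  draws with d1 ≤ d0.
- **Images** are flat-color canvases with elliptical panicle blobs and
  per-pixel Gaussian color jitter (sd 8 intensity units). Blob area is
  scaled to the remaining coverage deficit, so target coverage is hit
  within ±0.01 (exactly at 0 and 1), and the stored `true_coverage` is the
  exact mask pixel fraction.
- **Yield tables** draw each component as a fixed linear combination of
  the standardized parameters plus Gaussian noise, scaled to realistic
  units (Yield ~6500 ± 800 kg/ha, GN ~32000 grains/m², PN ~380 /m²,
  TGW ~21.5 g, FGR ~0.85), with GNP derived as GN/PN. The default
  loadings were chosen once from the target correlation structure — e.g.
  a K-loading of 0.9 against total sd ≈ 1.03 yields r(K, Yield) ≈ 0.87 —
  so that at n ≥ 100 plots the sample correlations reproduce the field
  sign pattern (K strongly positive with Yield/GN, d0 and d1 negative
  with Yield and FGR, K mildly negative with TGW).

What the generator deliberately does **not** emulate: photorealistic
canopies, occlusion, illumination fields, weather or stress dynamics,
spatial correlation between plots, or heteroscedastic segmentation error.
Consequently, passing tests demonstrate that the *pipeline mathematics*
(tiling, metric formulas, fit, CV, attribution) is correct and that
recovery works under idealized noise — they do not certify segmentation
accuracy or yield-model skill on real imagery, which depend on a trained
segmenter and field data outside this package's scope.

## Numerical choices and degenerate inputs

- Fits run at tolerance 1e-15 with ≤ 20000 function evaluations;
  deterministic for fixed data and guess.
- Ties/edge cases: a series peaking on its last day gets `a₀ = 0`; a
  constant or decreasing series raises `FitError`; `fit_table` records
  per-series failures as flagged rows and continues.
- Problem sizes in the standard checks: 61-point day grids for noiseless
  recovery; 100-seed Monte Carlo at 15 days for noisy recovery; 200-plot
  yield tables for the correlation screen and LOOCV — large enough that
  the sampling error of every asserted statistic is far from its
  threshold, small enough to run on one CPU in minutes.

## Known limitations

- The quadratic decline is unbounded below; extrapolation far past d1 is
  meaningless and the package does not pretend otherwise.
- Interventional Shapley by enumeration is exponential in the number of
  features; it is the right tool for exactly this 5-feature problem, not
  a general explainer.
- The color-rule segmenter is a reference implementation for synthetic
  imagery; on real canopies a trained model plugged into the segmenter
  contract is required.
- Envelope sampling treats parameters as independent, which ignores the
  correlation between d0 and d1 seen across real treatments; the d1 > d0
  rejection step is the only dependence imposed.
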