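# Methods

## The modelling chain

The package treats per-tree productivity — the one-year output value of a
tree, fresh leaf harvested (kg) times unit price (RMB/kg) — as the
endpoint of a three-stage chain: where a tree stands (environmental
suitability), how it has grown (ground diameter, crown width and other
size attributes), and how it is managed (ordinal harvest-intensity and
protection scores). Each stage is a standard model class; the package's
contribution is wiring them into one tested, reproducible pipeline with a
synthetic ground truth rich enough to validate every stage.

## Maximum-entropy suitability stage

**Model.** Over a background sample of grid cells, suitability is the
Gibbs density `P_w(x) ∝ exp(f(x)·w)` with features
`f(x) = (z₁, z₁², …, z_K, z_K²)`, `z_k` the k-th variable standardized by
background mean and standard deviation. Quadratic features suffice here
because the downstream index reduces each response to a quadratic bump;
hinge/product features are deliberately omitted (configurable by passing
a different feature set is a non-goal). Fitting maximizes the regularized
training gain

```
G(w) = mean_presence f(x)·w − log Σ_bg exp(f(x)·w) + log N_bg − (λ/2)|w|²
```

with `λ = regularization / √(n_presence)` (the conventional sample-size
scaling; default `regularization = 1.0` per feature). The ridge, rather
than the historical lasso, keeps `G` smooth so (a) per-coordinate Newton
steps are exact and (b) the optimum is verifiable against a generic
quasi-Newton optimizer — the test suite checks agreement to 1e-4 on a
50-cell problem. One consequence worth knowing: exactly duplicated
variables *share* weight under a ridge, so removing a duplicate costs a
small but nonzero amount of regularized gain (the redundancy tests assert
"most gain retained", not "zero drop").

**Contribution accounting.** Fitting is cyclic coordinate ascent with
damped Newton steps; every accepted update's gain increase is credited to
the variable whose feature moved, and the per-variable credits are
normalized to sum to 100. This mirrors the heuristic accounting of the
classical maxent program. Permutation importance shuffles one variable
across presences + background jointly and normalizes the training-AUC
drops (floored at zero) to 100. Jackknife gains refit with each variable
alone and excluded.

**Outputs.** The raw output is the Gibbs density; the logistic output is
`r·e^H / (1 + r·e^H)` with `H` the entropy of the fitted background
distribution, so a typical background cell scores 0.5 and all values lie
in [0, 1]. Response curves sweep one variable across its observed range
with the others held at presence means.

**Evaluation.** The default protocol is 10-fold cross-validation over
presences (each fold's held-out presences are scored against the full
background). A random-subsample protocol with a configurable test
fraction is also provided: the two conventions are genuinely different
and the field's tooling historically conflated them ("random test
percentage" is ignored when cross-validation is selected), so both are
exposed and cross-validation is the default.

## Covariance-structure stage

**Model.** `Σ(θ) = Λ(I−B)⁻¹Ψ(I−B)⁻ᵀΛᵀ + Θ` over recursive latent paths
environment → {management, growth, productivity},
management → {growth, productivity}, growth → productivity. The sample
input is the unbiased (n−1 denominator) covariance matrix; estimation
minimizes `F_ML` by L-BFGS-B from a deterministic scale-aware start plus
10 random restarts (3 in the pipeline driver), with variances optimized
on a log scale floored at 1e-6 of the matching sample variance (this
floor also absorbs Heywood cases, which are reported as warnings);
`χ² = (n−1)·F_ML` at the optimum, `AIC = χ² + 2q` exactly. GFI, AGFI and
CFI follow the conventional trace-based definitions with the
independence model (free variances, zero covariances — ML solution
`diag(S)` in closed form) as CFI baseline.

**Pinned specifications.** The final model has 7 indicators (annual
precipitation, coldest-month minimum temperature, ground diameter, crown
width, harvest intensity, protection, total value), one fixed
scale-setting loading per latent, and q = 20 free parameters, giving
df = 28 − 20 = 8. The initial model has 17 indicators (seven
environmental, seven tree-growth, two management, total value), equates
productivity with total value (loading 1, residual 0), and has q = 39,
df = 153 − 39 = 114. Residual covariances of the management indicators
with total value can be switched on, but are off by default: freeing them
changes df and no standard identification reproduces df = 8 with them
included.

**Single-indicator latents.** With productivity measured by total value
alone and the loading fixed, only the *sum* of the latent disturbance
variance and the indicator residual variance is identified; the
likelihood is flat along their difference. After optimization the engine
canonicalizes this ridge by moving all unexplained variance into the
disturbance (the indicator residual drops to its floor). This leaves
Σ(θ), χ² and df untouched and makes standardized coefficients
deterministic, at a price: the fitted latent is effectively the indicator
itself, so when data are generated with a *noisy* productivity indicator,
standardized paths into productivity are attenuated by the generating
loading. Parameter-recovery experiments therefore use the identified
regime (generating loading 1, zero indicator residual); the pipeline's
default generator keeps the noisy indicator because that is the realistic
field situation.

## Productivity index

`y = 0.24 y₁ + 0.71 y₂ + 0.05 y₃`, components in [0, 1], weights from
normalizing the standardized path coefficients 0.325 / 0.982 / 0.075
into productivity. (The source material prints the environment
coefficient both as 0.325 and as 0.32; only 0.325 normalizes to the
published 0.24/0.71/0.05 at two decimals — 0.32 gives 0.23 — so 0.325 is
used as the normalization input and 0.32 retained merely as a display
constant.)

* `y₁ = Σ cᵢ sᵢ(xᵢ)` with `sᵢ(x) = max(0, 1 − ((x−μᵢ)/ρᵢ)²)` (plateau
  variants are flat between the two published edge values with the same
  quadratic shoulders, used for isothermality and solar radiation). The
  optima μ are the published most-suitable values (1245 mm annual
  precipitation; 4.2 °C coldest-month minimum; 47.5 mm driest-quarter
  precipitation; 49.9–50.4 % isothermality; 89.2 precipitation
  seasonality; 391 temperature seasonality; 12 250–13 250 kJ m⁻² day⁻¹
  solar radiation). The exact quadratic coefficients were never printed;
  the default half-widths ρ reach from the optimum to the nearer end of
  the observed value range (e.g. bio12: min(1245−916, 1616−1245) =
  329 mm), so suitability hits zero exactly at the edge of observed
  conditions. Both μ and ρ are user-overridable through the JSON
  constants file. The weights cᵢ are the published contributions
  28.73 / 18.25 / 14.45 / 14.11 / 6.77 / 4.46 / 3.28 normalized over
  their sum 90.05 (sum-normalization rather than /100 keeps `max y₁ = 1`
  and hence `y ∈ [0, 1]`, which the class thresholds require).
* `y₂ = 0.54·GD/71.5 + 0.46·CW/11.5`; measurements above the study
  maxima 71.5 cm / 11.5 m clip per-term to 1 with a warning (new data
  may exceed the study's observed maxima).
* `y₃ = 0.57·harvest + 0.43·protection` on the grids {0, 0.5, 1} and
  {0, 0.1, 0.5, 1}; off-grid values in [0, 1] are accepted with a
  warning.
* Classes partition [0, 1] as [0, 0.3), [0.3, 0.5), [0.5, 0.8],
  (0.8, 1]. The published interval labels overlap at 0.3, 0.5 and 0.8;
  the closure above is the package's deterministic resolution.

The pipeline can also *re-derive* every constant from its own fits: top
and submodel weights from the standardized path model (negative
coefficients floored at zero before normalizing — a negative effect
cannot carry index weight), quadratic optima from response-curve maxima,
contributions from the maxent accounting, denominators from the observed
growth maxima. This is the end-to-end construction the frozen constants
came from.

## Synthetic ground truth

* **Surfaces.** Gaussian-smoothed white noise, min-max rescaled into each
  variable's observed range (28 variables available; the seven dominant
  ones by default). The smoothing length scale (default 8 cells)
  controls spatial autocorrelation; an infinite scale degenerates to a
  constant layer. Real terrain has anisotropy, cross-variable
  correlation and elevation structure that this deliberately does not
  emulate — passing suitability tests shows the estimator works on
  smooth autocorrelated fields, not that it handles real topography.
* **Presences.** Cells drawn without replacement with probability
  proportional to a known weighted-quadratic-bump suitability surface;
  coordinates are cell centers. The "strong-signal" test world (120×120
  cells, length scale 2, bump half-width 0.2 on a [0, 10] variable, 500
  presences) is calibrated so the Bayes-optimal AUC of the generating
  surface itself — computed exactly over the cell distribution — exceeds
  0.95; the fitted model is then required to exceed 0.9.
* **Trees.** Indicators are latent scores times loadings plus Gaussian
  residuals, from a generating truth pinned to the study's standardized
  coefficients (paths −0.619, 0.068, 0.325, 0.32, 0.075; loadings 0.826,
  0.693, 0.866, 0.651, 0.241). One printed value is adjusted: with the
  published covariance structure, a growth→productivity path of 0.982
  explains 100.06 % of the productivity latent's variance (inadmissible),
  so the generator uses 0.96, the nearest admissible round value. The
  productivity residual is a mean-zero shifted-lognormal with the same
  variance (total value is strongly right-skewed in the field; the
  distributional form was never stated, so log-normal is a package
  choice, flagged here). Field units come from affine rescaling (e.g.
  annual precipitation 1245 ± 140 mm, ground diameter 33 ± 11 cm);
  management scores and growth vigor are optionally discretized onto the
  field grids at empirical tertiles/quartiles (the ordinal grids'
  genesis was never recorded; quantile thresholding is the package's
  choice). Default n = 1282 mirrors the study's sample size.

## Numerical choices and problem sizes

Nearest-cell (not interpolated) raster extraction, matching the GIS
tooling convention; WGS84 lon/lat assumed. Background = all cells,
uniformly thinned to 10 000 with a fixed seed. Coordinate-ascent
tolerance 1e-8 on the gain; ML-fit tolerance 1e-8 on F_ML. Rasters are
exchanged as single-band ESRI ASCII grids (file name = variable name) —
a plain-text format that round-trips exactly through `repr`.
Listwise deletion (with logged counts) precedes covariance computation;
a zero-variance column is an error naming the column. The test suite and
acceptance script run the recovery experiment at n = 1282 × 20 seeds,
the Monte-Carlo covariance oracle at n = 10⁶, and suitability worlds of
3 600–14 400 cells with 150–500 presences — sizes at which every check
completes in seconds while keeping Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

* The maxent stage is a desk-scale analogue of the classical Java
  program, not a dial-for-dial replication: no cloglog output, bias
  files, clamping or hinge features; percent contribution is
  path-dependent by construction (as in the original).
* The ridge (not lasso) penalty never zeroes weights exactly, so
  "unused variable" means near-zero, not exactly-zero, weight.
* Standardized paths into a noisy single-indicator latent are attenuated
  (see above); with field data this bias is inherent to the published
  identification, not an artifact of this implementation.
* The synthetic world cannot validate claims about real occurrence data
  (none are deposited); published fit statistics (AUC 0.938, χ² 34.088,
  GFI 0.993, …) are estimates from the undeposited field sample and are
  treated as reference constants, not reproduction targets.
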