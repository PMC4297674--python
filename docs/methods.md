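# Methods

## Model

`freeknot` fits logistic regression models in which the log-odds of a
binary outcome are piecewise linear in one continuous predictor `x` (BMI in
the motivating application), with the breakpoints — the knots — estimated
as free parameters. For subject `q` with covariates `Z_q` (constant column
plus `p` covariates),

    logit P(Y_q = 1) = Z_q beta + s(X_q),

where `s` is an order-2 spline on `[a, b] = [min x, max x]` with `K`
interior knots `zeta_1 < ... < zeta_K`. Fitting maximizes the
sample-weighted pseudo-log-likelihood

    log L(theta) = sum_q w_q [ y_q eta_q - log(1 + exp(eta_q)) ],

with the survey weights `w_q` entering raw (unnormalized). Raw weighting is
deliberate: it is what design-based point estimation requires, and it is
also what breaks AIC/BIC model selection (below). An optional diagnostic
mode normalizes weights to sum to `n`.

### Parameterizations

Three equivalent parameterizations of `s` are used for different jobs:

* **B-splines** (doubled boundary knots, de Boor hat functions) for
  optimization — numerically stable, locally supported, partition of unity.
  The standard order-2 basis on `K` interior knots has `K + 2` columns; the
  left-boundary column (the only one equal to 1 at `a`) is dropped so the
  model keeps a free intercept, leaving coefficients `b_1 ... b_{K+1}`.
* **Truncated power** `[x, (x - zeta_1)_+, ...]` — algebraically
  transparent; retained for cross-checks only, since it is the less stable
  basis for optimization.
* **Intercept + local slopes** `(a_0, a_1, ..., a_{K+1})` — the reported,
  human-readable form. Slopes are extracted by evaluating the fitted spline
  at consecutive knots and differencing, which is exact for piecewise
  linear functions and basis-agnostic; for truncated-power coefficients it
  reproduces the cumulative identity `a_l = a_1 + sum_{i<l} b_i`.

Intervals are half-open `[zeta_i, zeta_{i+1})` with `x = b` closed into the
last interval so no observation is lost; for the continuous spline the
convention only affects the domain check.

## Optimization

For *fixed* knots the coefficient problem is an ordinary weighted logistic
regression — concave, solved exactly by damped Newton/IRLS (ridge-guarded
against collinear basis columns, with divergence detection for separated
data). The knots are therefore the only genuinely non-linear parameters,
and the package maximizes the *profile* likelihood over them:

* ordering and minimum-separation constraints
  (`zeta_1 >= a + delta`, gaps `>= delta`, `zeta_K <= b - delta`) hold at
  every evaluated point through a monotone reparameterization: the slack
  beyond the mandatory `delta` gaps is allocated by a softmax over
  unconstrained logits, so the optimizer cannot propose an invalid vector;
* the outer search is quasi-Newton (BFGS) with finite-difference gradients
  on the reparameterized knots;
* each one-knot grid cell is a 1-D subproblem and is solved by bounded
  Brent minimization within an overlapping window around its grid
  candidate;
* the grid-search winner gets a short Nelder–Mead polish, kept only when it
  improves the likelihood. The profile surface has derivative kinks where a
  knot crosses an observation, and a gradient method can stall in a shallow
  secondary basin there; the simplex probe escapes these at modest cost
  (without it, a direct-search refit can beat the gradient optimum by ~1
  log-likelihood unit on a 200-point dataset).

Profiling returns the same optimum as joint maximization over
`(beta, b, zeta)` — the argmax over the knots of the inner-maximized
likelihood is the joint argmax — while being lower-dimensional, faster and
far less prone to false convergence.

Starting values: covariate coefficients from a one-slope weighted logistic
fit (IRLS; zero fallback under separation), spline coefficients on that
fitted straight line, and knot starts from a combinatorial grid search over
`C` candidate locations evenly spaced on `[a + delta, b - delta]` (every
size-`K` combination; combinations leaving an empty inter-knot segment are
skipped). Ties in achieved likelihood break toward the lexicographically
smallest knot vector.

### Numerical defaults

| parameter | default | meaning |
|---|---|---|
| `min_separation` (delta) | 1% of predictor range | minimum gap between any two knots, boundaries included |
| `grid_points` (C) | 6 | candidate start locations per predictor range |
| outer gradient tolerance | 1e-5 (on the weight-normalized objective) | BFGS `gtol` |
| finite-difference step | 1e-6 relative | outer gradients |
| inner Newton tolerance | 1e-10 relative | coefficient subproblem |
| `max_iterations` | 500 | outer quasi-Newton cap |

The likelihood is evaluated through `log1p`/`logaddexp` so linear
predictors up to ±500 do not overflow.

## Knot-number selection: the parametric-bootstrap 2-df test

Adding a knot adds two parameters (a location and a slope). Free-knot
models with `K` and `K + 1` knots are *not nested* (only `K = 0` nests in
everything), so the LR statistic has no standard reference distribution.
The test builds one by parametric bootstrap: fit both models to the data,
record `LR = (-log L_null) - (-log L_alt)` (clamped at 0 with a warning if
the non-nested alternative fits worse), simulate `D1` replicate outcome
vectors `y* ~ Bernoulli(pi_hat)` from the *null* fit holding `x`, `Z` and
weights fixed, refit **both** models on every replicate with the same full
grid search, and compute

    p_boot = (1 + #{LR_rep >= LR_obs}) / (D1 + 1),

which lies in `[1/(D1+1), 1]` by construction. The null is rejected when
`p_boot < alpha`. Forward selection tests 0 vs 1, 1 vs 2, ... and stops at
the first retained null; if every test through `Kmax - 1` rejects, `Kmax`
is chosen. Defaults: `alpha = 0.10`, `D1 = 200` (1000 for
publication-grade runs), `Kmax = 4`. Replicates are independent, each
drawing from its own spawned seed, so results are bit-reproducible and
invariant to execution order (and parallelizable). A replicate whose fits
fail is redrawn up to 3 times, then counted as statistic 0 with a warning.
A cheaper mode warm-starts replicate fits at the observed-data knots; it is
not the default because the reference procedure re-runs the grid search per
replicate.

The F-ratio of the least-squares variant,
`F = [(SSE_red - SSE_full)/2] / [SSE_full / (N - (p + 2K + 2))]`, is
exposed as a statistic for completeness; fitting here is likelihood-based
throughout. The parameter count `r = p + 2K + 2` (covariates + intercept +
`K` knots + `K + 1` slopes) is used consistently in the F-ratio degrees of
freedom and in AIC/BIC.

### Why AIC/BIC fail under survey weights

`AIC = -2 log L + 2r` and `BIC = -2 log L + r log n` are computed on the
raw weighted likelihood — deliberately not normalized. With national-survey
weights (thousands of population units per subject) the likelihood is on
the scale of the *population* size, so likelihood differences between
candidate models dwarf any penalty of order `r` or `r log n`: both criteria
then select `Kmax` essentially always ("penalty wipe-out"). The bootstrap
test is immune because observed and replicate statistics live on the same
weighted scale. This is the framework's central comparative claim, and it
reproduces deterministically in character at reduced scale.

## Design-based inference

Survey designs are the usual public-use triple (stratum, PSU, weight),
with PSUs resampled with replacement within strata (Rao–Wu): draw
`d_h` of the `n_h` PSUs in stratum `h` (default `d_h = n_h - 1`) and
rescale every subject's weight by

    w* = w [1 - sqrt(d_h/(n_h-1))] + w sqrt(d_h/(n_h-1)) (n_h/d_h) r_hi,

where `r_hi` counts the draws of the subject's PSU. `E[w*] = w`, and in the
common 2-PSU-per-stratum design one PSU's subjects double their weight
while the other's get zero. Zero-weight subjects are carried (not dropped)
so replicate datasets keep stable row indexing; their likelihood
contribution vanishes. Resampling requires `n_h >= 2` everywhere;
single-PSU strata are flagged at validation and fatal only when resampling
is requested.

For a chosen-`K` model, `D2` replicate refits (default 1000; warm-started
at the chosen knots) yield, per parameter on the interpretable piecewise
scale: the bootstrap SE (replicate standard deviation) and a bootstrap-t
interval from the studentized pivot `T_i* = (theta_i* - theta_hat)/se_i*`,
with per-replicate SEs from a finite-difference observed-information matrix
at each replicate optimum (condition numbers logged; non-positive-variance
replicates dropped; fewer than 50 usable replicates is an error).
Equal-tail empirical critical values give

    ( theta_hat - T*_(1-alpha/2) se_hat,  theta_hat - T*_(alpha/2) se_hat ),

which need not be symmetric. Replicates whose knots migrate within the
minimum separation of a boundary are kept but flagged, and the flag rate is
reported. Non-converging replicates are dropped; losing more than 10%
triggers a hard warning.

Odds ratios between predictor values use only the spline part:
`OR(x1, x2) = exp(s(x1) - s(x2))`, so covariates cancel and one curve
serves any covariate profile. Log-OR is exactly antisymmetric and
path-independent, and the curve is piecewise linear with breakpoints at the
knots. Pointwise curve CIs studentize the replicate log-OR with
delta-method SEs from the replicate covariances. Simultaneous (curve-wide)
bands are out of scope.

## Synthetic data generator

The generator emulates the study conditions of the motivating BMI-mortality
setting:

* **Predictor**: log-normal, median 25.5, log-SD 0.18, truncated to
  `[17, 45]` — a right-skewed adult-BMI-like stand-in chosen to put most
  mass between 20 and 33 with a long right shoulder. Any user-supplied
  predictor vector (e.g. real survey BMI records) can replace it, which is
  the faithful plasmode mode.
* **True model**: knots (25, 32), slopes (-0.4, 0.0, 0.2) on `[17, 45]` —
  log-odds falling below BMI 25, flat to 32, rising above — with the
  intercept recalibrated *per dataset* by bracketed root-finding (tolerance
  1e-10; the mean event probability is strictly increasing in the
  intercept, so the root is unique) to hit a target prevalence
  `p0 ∈ {0.10, 0.33}` at sample sizes `n ∈ {500, 5000}`.
* **Outcomes**: independent Bernoulli draws at the true-model
  probabilities.
* **Design**: `H = 49` strata × `n_h = 2` PSUs (near-equal sizes),
  log-normal weights with coefficient of variation 1 and mean 10,000
  population units per subject (the scale of a national survey), optionally
  correlated with the predictor to mimic tail oversampling. Weights are
  independent of the outcome given the predictor by default.

What the generator does *not* emulate: the empirical BMI histogram of any
real survey (so selection frequencies carry an unquantified
predictor-distribution caveat), within-PSU outcome correlation, certainty
PSUs and masked pseudo-strata semantics, and mortality follow-up/censoring.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative selection behavior, not exact selection frequencies on real
survey data.

## Desk-scale study sizes

The shipped tests and the acceptance script run the full pipelines at
sizes chosen once as desk-scale defaults: the selection-ordering study at
`n = 1000`, 10 replicates, `D1 = 49`, `Kmax = 3`; the weighted wipe-out at
`n = 2000`, 10 replicates (AIC/BIC only — the claim concerns those
criteria); type-I calibration at `n = 250`, 100 datasets, `D1 = 99`;
bootstrap-t coverage at `n = 500`, 200 datasets, `D2 = 79`; parameter
recovery at `n = 20,000`. Full-scale selection-frequency replication
(`n = 5000`, 100 replicates, `D1 = 200`) uses the same harness and is a
matter of runtime, not code.

## Known limitations

* One non-linear predictor only; covariates enter linearly.
* Order-2 (piecewise linear) splines only — knots of higher-order
  free-knot fits resist the threshold interpretation that motivates this
  framework.
* Coalescent knots are prevented by hard separation constraints rather
  than penalties; knots attracted to the same location surface as
  boundary/separation-saturated solutions rather than merging.
* Selection operates on non-nested candidates; the LR clamp and the
  parametric bootstrap make the procedure well-defined, but the forward
  path offers no optimality guarantee.
* BRR, jackknife and linearization variance estimation are not
  implemented (the PSU bootstrap covers the intended designs).
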