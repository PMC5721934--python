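# Methods

## Model

The conditional distribution of a positive continuous outcome `Y`
(BMI in the motivating application) given two crossed stratifying
factors and a covariate vector `x` is modelled through a link-transform
of its CDF:

    g( P(Y ≤ b | stratum, x) ) = r(b | stratum, x) = α(b)_stratum + xᵀβ

with `g = logit` by default and `g = cloglog` optionally (the latter
turns the same structure into a fully parameterized proportional-hazards
model; in the stratified covariate-free case the two links fit the same
distributions and only the interpretation of β changes).

Per stratum, `α(·)` is a Bernstein polynomial of order `M` on a finite
support window `[L, U]`:

    α(b) = Σ_k θ_k B_{k,M}( (b − L)/(U − L) )

Because the Bernstein basis is a partition of unity with the derivative
identity `B'_{k,M} = M (B_{k−1,M−1} − B_{k,M−1})`, non-decreasing
coefficients `θ_0 ≤ … ≤ θ_M` imply a non-decreasing `α`, so the
monotonicity of the CDF reduces to `M` linear difference constraints
per stratum.  The constraint also acts as implicit regularization: the
effective number of free parameters is below `M + 1`, and no smoothing
penalty is added.

A step-function basis at fixed cut-offs replaces the polynomial when the
data are purely categorical; with one cut-off the model *is* binary
logistic regression, with several it is proportional-odds (cumulative
logit) regression.  The step basis is only defined at its cut-offs;
evaluating it elsewhere raises an error by design.

### Support window and extrapolation

Default support: the 1st and 99th percentiles of the observed outcome
values (interval midpoints for coarsened rows), widened by −5/+5
outcome units and clipped to the hard bounds `(0, ∞)`; both the
percentiles and the widening are user-overridable.  Outside `[L, U]`
the transformation continues linearly with the endpoint value and
endpoint slope, which preserves monotonicity and defines the CDF for
every `b > 0`.  At the hard bounds the CDF is pinned to 0 and 1.  A
consequence worth knowing: `expit(α(0))` is small but not exactly zero,
so the model carries a point mass of that size at the hard lower bound;
for fitted models it is far below 1e-3 and the reported densities
integrate to 1 within that tolerance.

## Likelihood

Each subject contributes, with optional nonnegative weight as a
log-likelihood multiplier:

* interval `(lo, hi]` (categories, rounding intervals, half-lines):
  `w · log[ F(r(hi)) − F(r(lo)) ]`, with `F(r(·))` replaced by 0/1 at
  the hard bounds;
* exact value `b`: `w · log[ F'(r(b)) · α'(b) ]`, the narrow-interval
  limit of the above (the package verifies the two agree to 1e-4 at
  half-width 1e-4).

Scales mix freely across subjects, which is what permits joint fits of
studies with different outcome codings.  Probabilities (and density
slopes) are floored at `prob_floor = 1e-12` before the log; every
floored contribution is counted and reported on the fit result rather
than silently producing −∞.

## Estimation

* **Constraints.** Each stratum block is reparameterized as
  `θ_0` free and `θ_{k+1} = θ_k + softplus(γ_k)`, making the admissible
  set the whole of ℝ^p.  Ties (flat segments, zero density) are
  approached as `γ → −∞` but never violated.
* **Optimizer.** L-BFGS with the analytic gradient (chain rule through
  the softplus map), followed by modified-Newton polishing on a central-
  difference Hessian (step `1e-5·(1+|param|)`) whose eigenvalues are
  floored at `1e-6` of the largest; steps are capped at norm 20 and
  Armijo-backtracked.  Covariate columns are rescaled to unit spread
  internally and mapped back afterwards.
* **Convergence** is declared when the inf-norm of the free-space
  gradient falls below `gtol · (1 + |negloglik|)` with `gtol = 1e-6`
  (a relative form: the log-likelihood is O(n), so an absolute 1e-6 is
  not meaningful in double precision).  Non-convergence is flagged on
  the result, not raised.
* **Starting values.** `θ` from the link transform of the pooled
  empirical CDF at the basis knots (monotone by construction), `β = 0`.
* **Covariance.** Inverse of the numeric Hessian in the free
  parameterization, with eigenvalues floored at `1e-9` of the largest
  so that weakly identified directions yield large positive variances
  instead of an indefinite matrix.  Wald intervals for `exp(β)` use it
  directly (free = natural for β); stratum-OR contrasts, linear in the
  natural `θ`, are propagated through the softplus Jacobian (delta
  method).  The delta-method SE was checked against a parametric
  bootstrap in the test suite (agreement within 15%).
* **Weak tail identification.** When no data fall near a support-window
  endpoint, the likelihood increases toward a supremum as the extreme
  coefficient drifts to ±∞ while the CDF over the data range is stable
  (differences ~1e-3).  This is expected for monotone transformation
  MLEs; the fit stops at the gradient criterion.  For *step* bases a
  runaway intercept means true separation (a category with no events)
  and is flagged as divergence.
* **Degenerate inputs.** Empty strata, rank-deficient designs (e.g.
  covariates collinear with the stratum intercepts), empty datasets and
  NaN parameters raise immediately; zero-probability intervals are
  floored and counted as above.

## Post hoc quantities

`proportional_or` returns `exp(β̂)` with Wald intervals (cut-off-free by
construction).  `stratum_or(A, B, b)` returns
`exp(α(b)_A − α(b)_B)` — the odds ratio of `Y ≤ b` between strata
sharing the same covariates — for any `b > 0`, with delta-method
intervals; at step-basis cut-offs it reduces exactly to coefficient
differences of the categorical fit.  `cdf_table` evaluates the fitted
CDFs at chosen cut-offs (default 18.5/25/30) for baseline covariates,
taken to mean reference categories and zero (centered) continuous
values.  `residuals` computes `U = F̂(b | stratum, x)`, uniform under a
correct model (Cox–Snell style), with a KS summary; interval
observations are scored at their window-clipped midpoint and counted as
approximate, since `U` is only defined for subjects with a known
outcome value.

## Synthetic cohorts

The survey data the method was developed around is only available by
application, so the generator emulates its structure from a known
ground truth *inside* the fitted family: per-stratum intercept
coefficients are read off the logit of a skew-normal CDF at the
Bernstein knots (location 18.4 for females, 20.9 for males, shifts of
+0.6 to −0.6 across smoking levels, scale 4.4, shape 4), giving
right-skewed distributions with means near 23 (females) and 25.5
(males).  These are presets of this package, not estimates from any
survey.  Ten strata (five smoking levels × two sexes, never-smokers
most frequent), plausible covariate distributions (age normal 47±16
clipped to 18–74 and centered at 40; alcohol exponential mean 8 g/d;
five categorical covariates) and effect sizes with odds ratios between
0.77 and 1.8 round out the default configuration.

Outcomes are drawn by inverse-CDF sampling: `α(b) = logit(u) − xᵀβ` is
solved on a dense grid within the widened window and in closed form in
the linear extrapolation region.  Heights are normal per sex, weights
follow as `BMI · height²`, and the rounding scale reports height to
1 cm and weight to 1 kg, from which the consistent BMI interval
`((w−0.5)/(h+0.005)², (w+0.5)/(h−0.005)²]` is formed — the steps are
configurable to emulate coarser self-report.  All intervals are
half-open `(lo, hi]`; a value exactly on a boundary belongs to the
lower category.  Draws happen in fixed order (strata, covariates in
declared order, outcome uniforms, heights) so appending covariates
does not perturb earlier columns for the same seed.

What the generator does *not* emulate: survey sampling design and
nonresponse, exclusion rules on extreme height/weight, measurement
error beyond rounding, and any dependence of covariates on the outcome
or on each other.  Passing tests therefore demonstrate correctness of
the estimator under the model, not robustness to real-survey
complications.

## Problem sizes used in the checks

The shipped checks run at reduced scale chosen to give stable
verdicts: oracle-equivalence fits at n = 1,000–2,000; recovery at
n = 10,000 with 200 replicate fits of n = 2,000 for Wald coverage;
scale insensitivity on one n = 5,000 ten-strata cohort (exact vs
rounding-interval likelihoods); PIT uniformity over 100 replicates of
n = 1,000; a 500-replicate parametric bootstrap at n = 800 for the
delta-method cross-check.

## Known limitations

* β is constant in `b` (proportional odds); outcome-varying
  coefficients are out of scope, as are smoothing penalties, automatic
  order selection, and truncation adjustments.
* The Hessian is numeric; for very large parameter counts (many strata
  × high order) fits are slower than an analytic-Hessian implementation
  would be.
* Residuals for interval observations are midpoint approximations.
* Weights are plain per-observation multipliers; no design-based
  variance correction is attempted.
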