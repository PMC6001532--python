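# Methods

## The imputation model

Let Y = (Y_1, …, Y_p) be incomplete variables on n subjects, X fully
observed covariates, and M_j the binary missingness indicator of Y_j
(1 = missing). Plain chained-equations imputation (FCS) cycles through
univariate models P(Y_j | X, Y_−j). The not-at-random variant replaces
these with

    P(Y_j | X, Y_−j, M_j, M_−j),

represented as a GLM. The coefficient of the variable's own indicator
M_j cannot be estimated (on the fitting rows M_j ≡ 0) and is supplied by
the user: the conditional sensitivity parameter (CSP) δ_j, the assumed
mean shift (gaussian) or log-odds shift (binomial) of missing relative
to observed subjects *conditional on everything else in the model*. Each
cycle fits the estimable part of the model on the rows with Y_j observed
and adds δ_j to the linear predictor of the missing rows before drawing.
Setting every δ_j = 0 is not the same as FCS: the M_−j terms remain, and
only when they are removed as well does the engine reduce to plain FCS
(an exact, bit-level reduction under our seed policy, verified in tests).

Imputation is proper: for the gaussian family the residual variance is
drawn from RSS/χ²_{n−p} and the coefficients from their conditional
normal posterior under the noninformative prior, then the predictive
draw is taken. The binomial family uses the standard normal
approximation to the logistic posterior at the MLE, as mainstream
chained-equations software does; it is provided as an extension and is
exercised only by basic distributional tests, not by the Gaussian
oracle machinery.

Engine conventions (the procedure's definition leaves them open; these
are this package's choices, each configurable or at least explicit):

- **Initial fill**: each variable's missing cells are filled by sampling
  its observed values with replacement.
- **Visit order**: variables are updated in spec declaration order.
- **Seed policy**: a master seed spawns one independent random
  sub-stream per imputation (`numpy` `SeedSequence.spawn`), so runs are
  bit-reproducible and the m imputations are schedulable in any order.
- **Residual-variance floor**: 1e−10, a numerical guard for degenerate
  fits (constant outcomes), not a statistical device.

## Predictor sets and estimability

Each incomplete variable's model includes every other substantive
variable and, following the recommendation to capture all estimable
correlation with the missingness process, every *other* incomplete
variable's indicator whose coefficient is estimable on the target's
observed rows. Estimability is decided mechanically: an indicator is
dropped when it is constant on those rows (as under monotone dropout) or
when adding it pushes the design matrix's condition number beyond 1e8.
The threshold is a conservative default for double precision; removals
are recorded on the returned predictor set, never fatal. The target's
own indicator is always retained as the CSP term.

## Pooling

Rubin's rules: Q̄ = mean of the m estimates, W = mean within-imputation
variance, B = between-imputation sample variance, T = W + (1 + 1/m)B.
Inference uses a t distribution with the Barnard–Rubin small-sample
degrees of freedom (with B = 0 collapsing to the observed-data df), the
modern default in the MICE ecosystem. The nominal level is 95% by
default and configurable. Per-imputation regressions use closed-form
least squares inside the package for speed — the harness fits hundreds
of thousands of them — and the tests verify coefficient and variance
agreement with `statsmodels` OLS.

## The Gaussian pattern-mixture test bed

The analytic module covers two jointly normal incomplete variables with
pattern-specific means

    E(Y1|M) = μ10 + μ11 M1 + μ12 M2,   E(Y2|M) = μ20 + μ21 M1 + μ22 M2,

common covariance (σ1, σ2, ρ) across patterns, and independent Bernoulli
missingness (π1, π2). Here μ11 and μ22 are the MSPs, and the implied
full conditionals give the CSPs in closed form, e.g. for Y1:
μ11 − ρ(σ1/σ2)μ21, with residual sd σ1√(1−ρ²). Marginal means are
E(Y1) = μ10 + μ11π1 + μ12π2 and symmetrically for Y2. Every coefficient
is written out symbol by symbol rather than via generic multivariate-
normal conditioning code, so each one is separately testable against a
simulation-plus-regression oracle. A special restriction (no pattern
shifts on the second variable, μ21 = ρ(σ2/σ1)μ11) yields the dampening
identity CSP = (1−ρ²)·MSP, explaining the classical observation that
conditional offsets appear "inflated" marginally.

The simulator draws (M1, M2), then (Y1, Y2) from the pattern-specific
bivariate normal, and masks Y_j where M_j = 1. It retains the
pre-masking truth for oracle checks only; the engine never sees it.
By construction the generator matches the analytic module exactly — so
passing tests demonstrate correctness of the machinery *under this
process*: bivariate, gaussian, pattern-mixture missingness independent
of Y given the pattern. Real cohort data add features the generator does
not emulate (covariate-dependent missingness, non-normality, more
variables, monotone dropout), so test results quantify algorithmic
correctness, not robustness to those features.

## Calibration

The MSP model for Y_j is the pooled regression of Y_j on its own
indicator (optionally plus conditioning terms); its M_j coefficient is
the achieved MSP. All calibration sweeps impute with the *same* fixed
seed at every test vector, making the achieved-MSP surface a
deterministic function of the CSPs; searches therefore converge cleanly,
and a final substantive imputation may use a different seed at the cost
of ordinary Monte Carlo variation.

- **Grid sweep (elicited ranges)**: every combination of per-variable
  test values is imputed; achieved MSPs and the effect of interest are
  recorded; the result flags whether achieved MSP ranges cover the
  elicited ranges and recommends widening/recentring when not. Default
  granularity is 10 test values per range; guidance is to keep grids
  coarse (the sweep costs one full imputation per vector).
- **One-at-a-time check**: for each variable, the spread of
  (CSP − achieved MSP) across settings of the other CSPs; the default
  pass threshold is 0.1 on the MSP scale — a configuration value chosen
  to sit above Monte Carlo noise at desk scale, not a theoretical
  constant.
- **Joint search (elicited points)**: repeated grid sweeps contracting
  around the best vector until all achieved MSPs fall within their
  tolerances; all qualifying vectors are returned (multiplicity is
  possible), with the one minimizing the maximum tolerance-standardized
  deviation designated primary; default budget 10 rounds, unconverged
  results flagged with the nearest vector.
- **One-at-a-time search**: for a single variable, others fixed (by
  default at their elicited MSPs), evaluate the achieved MSP over a
  regular grid, bracket the elicited value between the two nearest
  achieved MSPs, re-grid inside the bracket, and stop when the bracket's
  achieved MSPs agree within tolerance (default 0.001 on the MSP scale).
  Evaluations are cached by test value, which the fixed-seed policy
  makes exact.
- **Generalized curve**: the same sweep with any user summary of a
  completed dataset replacing the MSP fit, for plotting the effect of
  interest against an interpretable statistic.

## Tipping-point analysis

The sensitivity grid is swept as above; the baseline cell holds every
axis at its smallest-magnitude value. Along each axis, the tipping point
is the first grid value (in order of increasing distance from baseline)
whose pooled p-value crosses α relative to the baseline conclusion.
Tipping CSPs are mapped to achieved MSPs when MSP models are supplied,
and the full p-value surface is returned for contour plotting.
Single-value axes are flagged as undetectable rather than erroring.

## The simulation harness

`run_simulation_study` scores three ways of setting the offsets on data
from the Gaussian process: the exact CSPs, the MSPs inserted directly as
CSPs (the misuse the calibration exists to prevent), and calibrated
CSPs. Per replicate and arm it imputes (both cross-indicators included),
fits intercept-only models for Y1 and Y2, pools, and records estimate
and 95% CI; rows report bias, empirical SE, coverage and Monte Carlo
errors (bias MCE = empSE/√R, empSE MCE = empSE/√(2(R−1)), coverage
MCE = 100·√(p̂(1−p̂)/R), with the max-row coverage entry at worst-case
p = 0.5). Default scale is 1000 replicates of n = 1000 with m = 10 and
10 cycles; the acceptance script runs this full scale in a few minutes,
and the test suite uses a 200-replicate version of the same harness,
which preserves the qualitative arm ordering with coverage MC error
≈ 3.5 percentage points. The calibrated arm calibrates once on a single
large auxiliary replicate (default n = 100 000, tolerance 0.01) and
reuses the result across replicates; per-replicate recalibration is
available behind a flag but costs two extra searches per replicate, and
with a shared data-generating process the one-shot mode is the natural
reading of the design. Replicates that fail to impute are excluded and
counted, with a warning above 1% failures.

## Known limitations

- Only continuous and binary 0/1 variables; no ordinal/categorical
  handling, survey weights, or predictive mean matching.
- The analytic module is strictly bivariate; calibration itself is
  dimension-agnostic but has closed-form oracles only for p = 2
  Gaussian data.
- The binomial family's posterior draw is an MLE-based normal
  approximation, and no analytic CSP↔MSP conversion exists for it; the
  one-at-a-time assumption is expected to fail for logistic models and
  should be checked empirically with the grid machinery.
- Missingness in the generator is independent of Y given the pattern;
  MAR-by-covariate or longitudinal dropout mechanisms are not modelled.
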