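# Methods

## The two-stage model

Stage 1 treats the seven observed items per wave as congeneric indicators of
two occasion-level latent states, general fluid cognition (COG) and
functional limitation (FNC).  The longitudinal CFA over the three waves
imposes strong factorial invariance: each item's loading and intercept is a
single free parameter shared across waves, latent means are fixed to zero at
the first wave and free afterwards, the 6×6 latent covariance is fully free,
and residual variances are free per item-wave.  Identification uses marker
scaling (numeracy and mobility loadings fixed at 1); standardized loadings
are computed post hoc and are invariant to that choice.  Items are
standardized against their first-wave (2010) means and SDs before fitting —
a pure linear transform that stabilises the optimisation without changing
the model.  Items are treated as continuous throughout; categorical or
log-transformed variants of the limitation items are out of scope.

Bartlett scoring is applied per wave over that wave's two factors, using the
observed-indicator subset of (ν, Λ, Θ) for each missing pattern.  Scores for
a factor with no observed indicator at a wave are missing, not zero.  The
score-error covariance (Λ_oᵀΘ_o⁻¹Λ_o)⁻¹ is stored per pattern.  Scoring per
wave (rather than jointly over all six factors) is deliberate: stage 2
treats waves as separate occasions, and cross-wave smoothing would leak
longitudinal information into the trajectory fits.  Bartlett scores are
conditionally unbiased for the occasion state *on the model's factor scale*;
with marker scaling that scale is the standardized marker's unit, which is
why stage 2 re-standardises at the age-70/71 bin before interpretation.

Stage 2 converts the wave-based panel to chronological age: floor(age) maps
each score into one of eighteen 2-year bins from 50/51 to 84/85
(observations outside are dropped and counted; a person's second occasion
landing in an occupied bin is averaged in, with a logged count).  Time is
coded in decades from the lower edge of the centering bin,
s_b = (bin_lower − 70)/10, so bin 70/71 is exactly the zero point.  The
candidate growth models per process are intercept-only, intercept + linear
slope, and intercept + two-piece spline with knot bins 60/61, 64/65, 70/71
or 74/75.  Residual variances are homogeneous across bins within process;
the bivariate model adds a single within-bin cross-process residual
covariance shared across all 18 bins.  Cumulative changes are reported as
slope-per-decade × 2.0 (ages 50–70) and × 1.5 (ages 70–85) — the decade
arithmetic is defined on ages, not on bin codes.

## Estimation

The engine (`hrsgrowth.sem`) evaluates the casewise FIML log-likelihood over
missing-data patterns using per-pattern sufficient statistics (count, sum,
sum of outer products), so cost is independent of sample size.  Analytic
gradients are propagated through the moment structure per free parameter.
Optimisation is L-BFGS on an unconstrained internal parameterisation:
variance parameters as log-SDs, a fully free latent covariance as its
log-Cholesky factor; an infeasible (non-PD) point returns a large penalty
rather than crashing.  A fit is declared **converged** only when the
inf-norm of the mean-log-likelihood gradient is below 1e-5 and the observed
information matrix is positive definite; anything else is flagged and
reported in the comparison tables and the run manifest — never silently
accepted, since the method's model selection depends on spotting
non-convergent candidates.  A multi-start option records every terminal
point.

Standard errors are computed in the natural parameterisation at the optimum
(so they refer to the reported variances/covariances): naive SEs from the
inverse observed information (central differences of the analytic gradient;
expected/Fisher information available as an option), robust SEs from the
Huber–White sandwich A⁻¹BA⁻¹ with B the average outer product of analytic
casewise scores.  Wald tests are two-sided with α = 0.005 as the default
flagging level, reflecting the large samples this design targets.
Correlations reported from covariance parameters carry delta-method SEs.

The model χ² is 2(ℓ_saturated − ℓ_model).  The saturated (unrestricted μ, Σ)
log-likelihood under missingness is maximised by a short EM warm-up followed
by a quasi-Newton polish on (μ, log-Cholesky Σ); plain EM can need tens of
thousands of iterations on bin matrices where ~85% of cells are missing and
some bin pairs are never co-observed.  The solver standardises columns
internally (available-case mean/SD) and corrects by the exact Jacobian term,
which makes the saturated value exactly equivariant to linear rescalings —
fit statistics are invariant to `rescale_at_bin` to ~1e-9.  The TLI baseline
is the independence model (free means and variances, zero covariances) under
the same FIML handling; with a diagonal covariance the casewise likelihood
factorises, so its available-case means and 1/n variances are exact MLEs in
closed form.  RMSEA uses n = number of analysis cases with a **95%** CI by
inverting the noncentral χ² distribution (the convention was pinned by
back-computing a published fit row, χ² = 670 on 179 df at N = 14,489 →
RMSEA .014).  AIC = −2ℓ + 2·(free parameters).

## The synthetic-data generator

The generator emulates the HRS 2010/2012/2016 panel: baseline ages drawn
from Normal(64.9, 9.6) truncated to [50, 83] (so all three waves can fall
inside the 50–85 analysis range) and floored to whole years, matching HRS's
age-in-years reporting; waves at +0/+2/+6 years; monotone attrition with
per-wave conditional retention (.916, .821 — the published wave counts
14,489 → 13,277 → 10,900), optionally missing-at-random via a logistic
dropout model on the person's current functional-limitation state (log-odds
coefficient per unit FNC; 0 = MCAR).  The default growth configuration *is*
the published bivariate spline+linear solution — means (.031, −.047, −.230,
.115, .229), variances (.777, .142, .413, .769, .150), the full 5×5 latent
correlation matrix (verified positive definite), occasion residual variances
(.313, .475) and their .007 cross-correlation — in age-70-standardized
units with slopes per decade.  Univariate defaults use the published
univariate spline means and variances; their within-process correlations and
occasion residuals are not printed anywhere, so they default to the
bivariate-solution values (FNC reuses its intercept–slope correlation for
both slopes), a choice that matters only for second-order properties of the
univariate recovery experiments.

Items are generated linearly from the occasion states, y_j = ν_j + λ_j·state
+ ε_j; count-type items are rounded and clipped to their scale range.  The
zero floor produces the positive skew characteristic of ADL/IADL counts
(generated wave-1 ADL mean ≈ 0.24, skewness ≈ 2.8).  Item parameters were
calibrated so the fitted LFA reproduces the published standardized-loading
pattern (numeracy ≈ .85 high / recall ≈ .445 low for cognition; ADL ≈ .82 /
IADL ≈ .578 for limitation) and roughly the published wave-1 descriptives.
What the generator does **not** emulate: survey weights, retest/practice
effects, dementia/depression screening, non-normal latent distributions, or
any real-data idiosyncrasies beyond the printed moments — so passing
recovery tests demonstrates internal consistency of the method, not fidelity
to HRS microdata.

## Recovery experiments and their problem sizes

`hrsgrowth.experiments` (used by `scripts/acceptance.py` and the acceptance
tests) simulates factor-score panels of 3,000 persons without attrition,
bins them, refits the generating model by FIML, and averages estimates over
10 seeds.  Slope means recover within ±0.01–0.02 at this size.  Two
discretisation effects of the time-window method are visible and documented
rather than hidden: intercept means shift by roughly (mean within-bin age
offset) × (post-knot slope), ≈ 0.01–0.02 SD with whole-year ages, and slope
*variances* attenuate slightly because a person's true age sits up to two
years above the bin code.  The weakly identified slope–slope correlations
are the fragile quantities: with ≤3 occasions per person their ML estimates
are noisy (per-seed SD ≈ 0.2) and skew toward ±1 when a slope variance
estimate collapses, so 10-seed averages of the FNC-slope × pre-70-COG-slope
correlation typically land between −.39 and −.62 around a large-n value of
≈ −.48.  The engine was cross-validated against an independent
mixed-model ML implementation (glmmTMB) on identical bin data:
log-likelihood, fixed effects, variance components and residual variance
agree to at least five decimals.

## Known limitations

- Two-stage estimation propagates no scoring uncertainty into stage 2; the
  Bartlett score error is absorbed by the occasion residual (by design,
  matching the method being implemented).
- Bin time codes use the lower bin edge; the resulting half-bin age offset
  slightly biases intercept means and attenuates slope variances (see
  above).  Modeling stops at age 85.
- The saturated model on bin matrices has flat directions (never co-observed
  bin pairs); the attained maximum is well-defined but the fitted saturated
  covariance is not unique in those directions.
- No survey weights, covariates, retest adjustment, categorical-indicator
  estimation, or multi-group invariance testing.
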