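# Methods

## Scope and data flow

The package analyses the effect of heat stress on growth in a captive
red deer herd monitored through lactation: daily station weather →
heat-stress indices → per-weighing exposure covariates → (a) a nonlinear
mixed growth model for calf weight and (b) an additive model for mother
weight, with AIC-based model selection over nested covariate sequences.
A synthetic herd generator reproduces the study design so every stage is
testable end to end.

## Heat indices and exposure

THI combines temperature and humidity (the humidity term changes sign at
14.4 °C: humid air is stressful only when warm); THIWS subtracts a
convective-cooling wind term (−1.992 per m s⁻¹) and adds a radiative
heat-load term (+1.887 per MJ m⁻²). Both are dimensionless daily values.

How daily weather maps onto a weighing record is an analysis choice, not
a property of the data. The default assigns each weighing the **mean
over the interval since the calf's previous weighing** — body-weight
change integrates the conditions experienced since the last measurement
— with the first interval anchored at birth; the interval is treated as
(previous weighing, weighing], so the weighing day itself counts and the
previous weighing day does not. `same-day` and `fixed-window(k)` modes
are available for sensitivity analysis. Missing weather days inside a
window are linearly interpolated when the gap is ≤ 3 days and are an
error otherwise: short station dropouts are routine, long gaps should
not be silently filled. Monthly climatologies report the across-year
mean and standard error of per-year monthly means and maxima; a month
contributed by a single year reports SE = 0 with a warning rather than
NaN. Quantiles of pooled index values (default 0.1/0.5/0.9) define the
low/median/high stress prediction scenarios; the convention is linear
interpolation of order statistics (numpy default).

## Calf growth model

Weight follows `f(t) = Asym + (R0 − Asym)·exp(−exp(lrc)·t)`. Writing
`s = 1 − exp(−exp(lrc)·t)`, the model is `y = (1−s)·R0 + s·Asym + ε`
— a convex path from birth weight to the asymptote — and random
intercepts on `Asym` (cohort, mother, calf; crossed, independent) enter
the mean as `s·b`. The marginal covariance is therefore

    V = σ²I + Σ_g σ_g² (D_s Z_g)(D_s Z_g)ᵀ,  D_s = diag(s),

and the marginal Gaussian likelihood is exact; no Laplace or
linearisation step is needed because the random effects are linear in
the mean.

**Estimation.** Given the lrc-block coefficients, the model is linear in
the Asym and R0 blocks, which are profiled out by generalised least
squares. The outer quasi-Newton (L-BFGS-B) search runs over the lrc
coefficients and log standard deviations; each evaluation uses the
Woodbury identity with a sparse indicator matrix, costing O(n + q³) for
q total random-effect levels (q ≈ 1.2·10³ at the full design, a few
hundredths of a second per evaluation). Maximum likelihood is the
default and is used whenever models are compared by AIC (fixed-effect
structures differ across the candidate set). For REML fits, the
restricted likelihood is treated as a criterion for the **variance
parameters only**: the mean parameters come from the ML maximisation,
the σ's are then re-estimated by REML at that mean, and the Asym/R0
blocks are re-profiled by GLS under the REML variances. (Maximising the
restricted likelihood jointly over mean parameters is improper — the
−½log|XᵀV⁻¹X| term rewards means that inflate their own uncertainty —
and demonstrably drifts on simulated data.)

Starting values use the classical self-start for asymptotic regression:
`asym₀ = 1.05·max(y)`, regress `log(asym₀ − y)` on `t`, `lrc₀ = log(−slope)`,
`r0₀ = asym₀ − exp(intercept)`; covariate coefficients start at zero and
σ's at sd(y)/4. Convergence uses relative likelihood change ~1e−11 and
gradient norm 1e−6 within at most 500 outer iterations; a refit started
from its own solution reproduces it to well below 1e−6. Variance
parameters are optimised on the log scale with a lower boundary at
exp(−10)·sd(y); a σ on the boundary is reported as 0 with a flag.

**Inference.** Standard errors for the Asym/R0 blocks come from the GLS
covariance (XᵀV⁻¹X)⁻¹; for the lrc block from a central-difference
Hessian of the profiled likelihood with the variance parameters held at
their estimates (a conditional approximation — σ-uncertainty is not
propagated, the standard practice for mixed models). t-tests use
df = n − (#calf levels) − (#fixed coefficients); this convention is
declared, not canonical — longitudinal df accounting has no unique
answer. AIC counts all fixed coefficients, the random-effect sds and the
residual sd. Covariates are not centred or scaled by default (an
optional flag exists); calf age may appear both as the curve's time axis
and as an ordinary covariate inside the linear predictors, and the
machinery treats the latter like any other per-record covariate.

## Model selection

Akaike weights are computed with the max-subtraction trick, so a ΔAIC of
several hundred underflows to an exact 0 (formatted `<1e-300`) rather
than NaN. The Kullback–Leibler column is the pairwise-normalised weight
between **adjacent columns** of the selection sequence, reported as the
probability that the model in column i+1 is preferred over column i —
this is the convention that reproduces every self-consistent reference
value. AIC values are only comparable across fits on the identical
record set; the comparison refuses models with differing record counts.

## Mother-weight additive model

Spline smooths use the cubic-regression-spline construction: k knots at
covariate quantiles, cardinal natural-cubic-spline basis (coefficients
are the function values at the knots), and the curvature penalty
S = DᵀB⁻¹D from the standard divided-difference (D) and bending (B)
matrices, whose null space spans constants and linears. Every spline
smooth carries a sum-to-zero constraint absorbed by a QR
reparameterisation, so a k = 3 smooth contributes exactly two free
coefficients. Knot placement at quantiles is a declared choice.

Factor-by smooths give each sex its own deviation curve, sharing the
main-effect smooth's knots. Their blocks are **fully penalized**
(curvature plus a ridge on the penalty null space, one λ per block):
a deviation's linear part would otherwise be exactly collinear with the
main smooth's unpenalized linear part (female-deviation + male-deviation
= main effect), and full penalization both restores identifiability and
gives the right semantics — at λ→∞ the deviation vanishes rather than
persisting as a line. Random-effect ("re") smooths penalize factor-level
coefficients with the identity, equivalent to Gaussian random intercepts
with σ_b² = σ²/λ.

Smoothing parameters are selected jointly by Gaussian REML with σ²
profiled analytically: the score is
`(n−M_p)·log(2πσ̂²) + RSS_p/σ̂² + log|XᵀX+S_λ| − log|S_λ|₊`, with M_p the
total penalty null-space dimension, minimised by L-BFGS-B over log λ
from three seeded restarts (the REML surface can be multimodal). A λ
pinned at +∞ drops a term's penalized range exactly (the λ→∞ limit used
by the oracle tests). Effective degrees of freedom are
`diag((XᵀX+S_λ)⁻¹XᵀX)` summed per block; smooth significance uses a
Wald-type F with the edf as numerator df — approximate by construction.
Predictions are reported centred (training-mean response subtracted)
with pointwise SEs from the penalized-coefficient covariance σ̂²(XᵀX+S_λ)⁻¹;
random-effect smooths predict 0; out-of-range covariates warn
(extrapolation) rather than error.

## Synthetic herd generator

The generator's defaults are the study conditions: 583 pairs over 19
cohorts from a pool of 150 mothers (reused across, never within, a
cohort), births N(23 May, 10.2 d), weighing from birth (day 0) in
truncated-normal steps (mean 8.2 d, sd 3.52, clipped to 1–22) until
weaning at day 143 — giving ≈ 17.7 weighings per calf — mother ages from
a truncated normal on 1–17 (mean 5.9, sd 3.64), 1:1 sex ratio, singleton
births only. Weather follows sinusoidal annual cycles plus daily
Gaussian noise calibrated to July means of ≈ 24.5 °C, 46 % humidity and
28.1 MJ m⁻², with annual-mean wind ≈ 2.35 m s⁻¹ dipping to ≈ 1.9 in
summer.

Calf weights come from the growth model itself, with true coefficients
set to the final-model magnitudes (random-intercept sds 5.40, 5.93,
8.04 kg; residual 1.41 kg), so a refit is a direct parameter-recovery
experiment. Mother weight has no accepted generating model, so the
package declares a stand-in: Normal(99, 12) kg baseline at parturition,
a quadratic lactation trend peaking near +0.7 kg around day 46 and
reaching −2.3 kg at weaning, a sex-of-calf penalty (−0.45 kg plus an
extra −0.5 kg by weaning for male calves), a piecewise-linear THIWS
response (+1.2 kg over 65→107, −0.5 kg over 107→130) and Gaussian noise
(sd 1.5 kg). Mother age is drawn independently per lactation rather
than aging mothers consistently across cohorts — the models treat it as
a per-record covariate, so this simplification does not change the
fitted structure. All randomness derives from one seed through named
CRC-keyed substreams, so adding a generator leaves existing streams
untouched.

What the generator does **not** emulate: within-calf serial correlation
beyond the shared intercepts, heteroscedastic or non-Gaussian weighing
error, mortality and drop-out, seasonal feed effects, twins, and
measurement-occasion clustering (whole cohorts weighed on shared days).
Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the declared model, not robustness to those
real-data features.

## Problem sizes used in the tests

The likelihood oracle compares against a dense multivariate-normal
density on random instances of ≤ 50 records; parameter recovery runs at
the full design (583 pairs, ≈ 10⁴ records) across five seeds with a
majority criterion — individual coefficients are allowed to miss the
3-SE band on occasional seeds, as t-statistics should; GAM and pipeline
tests use reduced herds (18–80 pairs) chosen to exercise every code path
while keeping the suite fast.

## Known limitations

- The growth model fixes random effects to the asymptote; random slopes
  or rate heterogeneity are out of scope, as are autocorrelated or
  heteroscedastic residuals.
- The lrc-block SEs condition on the variance estimates; intervals are
  slightly anti-conservative in small herds.
- The GAM's F-tests and edf are approximations; they order terms
  sensibly but should not be read as exact p-values.
- The df convention for coefficient t-tests is declared, not derived;
  alternative conventions shift printed df by a handful of units without
  changing any conclusion.
- The energy calculator exposes the allometric formula
  (226·W^0.837 kcal d⁻¹, ×4.184 for kJ) only; it does not attempt
  lactation-aggregate energy accounting.
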