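# Methods

This note documents the models, numerical choices and known limitations of
`cd4cvl`, in the spirit of a statistical package's model documentation.

## The cVL₂ metric

cVL₂ is the composite trapezoid of `log₁₀(VL/limit)` floored at zero, in
log₁₀ copy-year/mL. Design choices:

* **Raw-scale input.** The module contract takes viral loads in copies/mL
  and applies the log inside the formula; anything else is dimensionally
  incoherent.
* **Flooring at zero.** The metric is the area *above* the detection limit;
  sub-limit values contribute nothing. This guarantees monotonicity: cVL₂ is
  non-decreasing in time for every patient.
* **Missing visits.** Visits with missing VL contribute no trapezoid node;
  adjacent observed nodes are bridged over the longer interval. Every visit
  still receives the running cumulative at the most recent observed node at
  or before it — no interpolation into a bridging interval — because the
  regressions need a per-visit covariate value. A leading run of missing
  VLs after baseline is anchored at the baseline VL (an observed node).
* **Detection limit as a parameter.** Default 400 copies/mL (excludes
  blips); the 50 copies/mL assay limit or a 1000 copies/mL variant are
  reachable through the `detection_limit` argument.

## Model structure

Both families share fixed effects (intercept, sex 0/1, standardized baseline
age / CD4 / log₁₀ VL, a time basis, optionally in-care × cVL₂) and a
bivariate random intercept + slope on *raw* time; spline bases change only
the fixed part. Standardization uses the sample sd (ddof = 1) computed on
the post-exclusion analysis sample over observed cells; imputed draws live
on that standardized scale. cVL₂ itself is left unstandardized by default so
its coefficient reads "cells/μL per log₁₀ copy-year/mL"; a configuration
switch standardizes it with the other continuous covariates.

B-spline bases are cubic, with fixed inner knots (1.250, 2.5, 3.751) or
(0.833, 1.666, 2.5, 3.334, 4.167) years and boundary knots at (0, 5), the
follow-up window; the basis column absorbed by the model intercept is
dropped.

**Skew-normal blocks** use the stochastic representation ξ + δ·|w| + u with
w standard normal truncated to the positives and u the Gaussian kernel —
the classic BUGS-style construction. Marginally this is the skew-normal
with scale ω² = σ² + δ² and shape α = δ/σ, reducing exactly to the Gaussian
at δ = 0. "Zero" in SN(0, Σ, Δ) is interpreted as the *location*; the mean
is then δ√(2/π), which the model intercept absorbs. A configuration switch
(`sn_mean_correction` in the simulator) applies the mean correction instead.
The per-observation error skewness is tied to a single shared δ_ε by
default; the formally per-visit skewness matrix has no covariate structure
to identify separate entries.

## Priors

Vague defaults (stated as assumptions, all overridable): coefficients
N(0, precision 10⁻⁶); residual sd uniform on (0, 100) cells/μL; Σ_b
inverse-Wishart with identity scale and q+1 = 3 df; skewness parameters
N(0, variance 100).

Informative priors exist only for Gaussian polynomial slope models (the
historical studies fitted that form; threshold models used heterogeneous
CD4 cutoffs). The variance comes from inverting the upper-CI formula,
`s² = n·((uCI − x̄)/1.96)²`, with 1.96 hard-coded (not a higher-precision
quantile) so elicited cells match published arithmetic at printed rounding;
the prior mean is the historical estimate plus the simple→full model change
estimated on current data. Elicited values are stored unrounded.

## Sampler

Component-wise MCMC, three chains by default, per-chain RNG streams spawned
deterministically from one seed (same seed ⇒ bitwise-identical draws):

* Gaussian-linear blocks (fixed effects, random-effect kernels, skew-normal
  latents and skewness in the slope family, linear imputation models,
  variances, Σ_b) are conjugate Gibbs updates. The uniform-on-σ prior yields
  an inverse-gamma full conditional for σ² truncated at 100.
* Logistic blocks (asymptote fixed and random effects, asymptote skewness,
  the sex imputation model) use random-walk Metropolis: the fixed-effects
  proposal is preconditioned by the no-random-effects IRLS covariance;
  per-patient proposals are scaled Cholesky steps; positive latents use
  reflective walks (symmetric). Step sizes adapt by Robbins–Monro toward
  0.23–0.25 acceptance **during burn-in only**, so retained draws form a
  valid Markov chain.
* The contract is the posterior, not the kernel: the test suite cross-checks
  the posterior and the conditional DIC against JAGS (via rjags) on a small
  mixed model with identical priors.

**Imputation** follows the two-stage data-augmentation scheme at every
iteration: baseline CD4 and baseline log VL are drawn from linear models on
(1, sex, age); sex is then drawn from a logistic model on (1, age, baseline
CD4, baseline log VL) using the just-imputed values; missing CD4 outcomes
are drawn from the outcome model's predictive. The covariate draws condition
on the imputation models only (not additionally on the outcome likelihood),
matching the stated procedure; under MCAR this is valid, under MAR it
slightly attenuates covariate effects. Observed cells are never altered.

**Diagnostics.** BGR potential scale reduction per parameter (threshold
1.1 — a conventional cutoff, chosen here since only the diagnostic itself is
prescribed), floored at 1 since the population quantity is ≥ 1, with the
degenerate zero-within-variance case mapped to 1 (agreeing chains) or ∞.
Monte Carlo error uses batch means (≥ 20 batches) against the 5%-of-
posterior-sd rule. Credible intervals are 2.5/97.5 empirical percentiles
with linear interpolation; odds-ratio summaries exponentiate draws before
averaging (posterior mean OR).

**Conditional DIC.** D(θ, b) = −2·log-likelihood of the *observed* outcomes
given the random effects (so skew-normal random effects leave the deviance
Gaussian, skew-normal errors change it); cDIC = D̄ + pD with
pD = D̄ − D(θ̄, b̄) at posterior means, imputed covariate cells plugged in at
their posterior-mean imputations (the cDIC conditions on imputations rather
than integrating them; this is documented as the implementation's
convention). Differences < 10 are labelled "no clear choice".

**Iteration schedules.** The original-scale schedules (20K/45K up to
500K/500K, three chains) are available as presets; tests and the acceptance
study run deliberately scaled-down schedules (3 chains × 1–2K post-burn-in
after ~1–1.5K burn-in), which the conjugate Gibbs core mixes well enough
for (BGR ≈ 1.01 on the slope family). All problem sizes used in tests
(150-patient recovery replicates, a 300-patient imputation cohort) are the
package's own choices for a dense simulation study.

## Synthetic cohorts

The generator emulates the *structure* the analysis assumes, not any real
cohort: ~750 patients (default), 6-monthly visits over 5 years, 69.6%
female, baseline age lognormal (median 36, IQR 31–42), baseline CD4 gamma-
matched (median 89, IQR 43–143), baseline log₁₀ VL normal (median 5.1, IQR
4.64–5.48); a two-state suppressed/rebound per-visit Markov VL process
(suppression 0.85, rebound 0.08 per visit, rebound magnitude ~N(4.0, 0.6)
log₁₀) that yields realized 5-year cVL₂ medians around 0.6–1.3 log₁₀
copy-year/mL; CD4 from the slope model with the published adjusted-model
coefficients as default truth (cVL₂ effect −19.6); MCAR missingness (49%
VL, 5% CD4, 3% per baseline covariate) with an optional MAR mode keyed on
the previous CD4; per-visit dropout hazard 0.02 driving the in-care
indicator.

Unprinted parameters were fixed once at realistic values for ART cohorts:
random-effect sds σ₀ = 90, σ₁ = 35 cells/μL, ρ = −0.2, residual σ_ε = 80
cells/μL, slope intercept 105 (≈ mean baseline CD4 of the matched gamma);
asymptote truth on the log-odds scale uses the published odds ratios with
intercept −4.6 and σ₀ = 2.0, σ₁ = 0.6, giving ~39% of patients ever
crossing 500 cells/μL.

Known unrealism, and what passing tests do and do not show:

* The published quadratic time trend (55.7·t − 22.7·t²) turns strongly
  negative late in follow-up, so simulated CD4 values can be negative;
  clamping at zero is opt-in (`truncate_cd4`) because it would distort about
  a third of visits and break correct-specification recovery. Recovery
  results therefore certify the estimation machinery under the stated
  model, not the biological plausibility of that fixed-effect truth.
* The baseline CD4 *covariate* and the simulated CD4 *measurement* at t = 0
  are linked only through the model, not identically equal as in real data.
* Covariates are drawn independently (marginals only); VL dynamics are a
  two-state caricature, not a mechanistic viral model.
* In the asymptote generator the binary outcome is encoded through the CD4
  column (650/350 cells/μL), so thresholding at 500 recovers it exactly.

## Reporting

Stratified summaries (baseline CD4 ≤100/101–200/>200, sex, age ≤50/>50,
log VL ≤5/>5) are posterior-*predictive*: per draw and patient, predictions
at grid times include random effects and (for slope models) fresh residual
noise; the median and 2.5/97.5 percentiles are taken across patients ×
draws jointly — the documented convention where "across patients, draws, or
both" is ambiguous. Asymptote outputs are probabilities in [0, 1]. cVL₂ at
grid times is carried forward step-wise from the visit series.

## Limitations and non-goals

* No missing-not-at-random sensitivity analysis; the imputation layer
  assumes MCAR/MAR.
* Marginal DIC is not computed (no general implementation exists for these
  models); model choice relies on conditional DIC with the ≈10-point rule,
  which conditions on random effects and can be conservative for nested
  exposure effects (random slopes absorb part of a time-varying exposure).
* cVL₁ (area under the raw VL curve, log-transformed afterwards) is
  deliberately not implemented.
* No time-to-event models, no second-line-regimen modelling, no
  bit-compatibility with any particular BUGS engine.
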