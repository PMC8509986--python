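# Methods

This note records the statistical model implemented in `censmed`, the
numerical and design choices that were genuinely open, what the simulation
engine does and does not emulate, and known limitations.

## Model and estimands

The package targets natural indirect/direct effects of a k-category
exposure on an outcome acting through a right-censored mediator. The
mediator follows a semiparametric AFT model on the log-time scale with
i.i.d. errors of unspecified distribution; the outcome model is linear
(continuous y) or logistic (binary y) in **log t**, the exposure dummies and
covariates. Identification rests on the usual mediation assumptions — no
unmeasured exposure–outcome, exposure–mediator or mediator–outcome
confounding, consistency — plus censoring independent of (t, x, y, z).
These are assumptions of the method, not testable properties the package
checks.

The mediator enters the outcome model on the log scale because that is the
AFT linear-predictor scale on which the censored-mediator integration is
performed, and because the implemented simulation designs (a0 = 6 with
b0 between −5.2 and −1.2, b = 0.4) only produce sensible disease
prevalences (≈9–30%) under that reading; with the mediator in raw time
units (t ≈ e^6 ≈ 400) the same coefficients would saturate the logistic
model.

Per-category effects are combined into overall IE/DE/TE with
exposure-category frequency weights f_j **renormalized to sum to one over
the non-reference categories**. This normalization is what makes the
continuous-outcome reference value reproducible analytically:
(0.42·0.16 + 0.09·0.32)/0.51 = 0.188 at MAF 0.3 with a = b = 0.4, c = 0.5.
Raw (unnormalized) weighting is available via `normalize=False`. Effects
are conditional on a covariate profile z\*, defaulting to the
sampling-weighted covariate mean. PM = IE/TE is reported as `None` when
|TE| ≤ 1e−10.

## Stage 1: IPCW weighted least squares

* Ĝ, the censoring-survival Kaplan–Meier estimate, is evaluated at the
  **left limit** Ĝ(m−). This is the standard IPCW convention and keeps
  events at the largest observed time at positive weight. Weights are
  capped at Ĝ ≥ 1e−8 with a runtime warning.
* Tie rule: mediator events precede censorings at the same time, i.e. tied
  events stay in the risk set of the censoring-process KM.
* The product-limit routine is implemented in `censmed.aft` because the
  pipeline needs sampling-weighted risk sets, the explicit tie rule and
  left-limit evaluation in one place; it is validated against
  `lifelines.KaplanMeierFitter` in the test suite.
* The residual distribution η̂ is the KM estimate on residuals
  (e_i = log m_i − A_i'θ̂, δ_i), with support on the event residuals and
  truncation at the largest event residual τ. Mass the KM leaves beyond τ
  (largest residual censored) is redistributed by renormalizing to 1, so η̂
  is a proper distribution and the effect sums are well defined.
* In case-control mode the sampling weights w_i enter the WLS normal
  equations and, for consistency, both KM estimates (censoring survival
  and residual distribution); `use_weights=False` switches the KMs to
  unweighted.

## Stage 2: pseudo-likelihood

The censored-subject contribution integrates the outcome probability over
η̂ restricted to residuals beyond the subject's censoring residual. Two
conventions were open:

* **Tail renormalization.** The default divides the tail sum by
  P_i = Σ_{e_s > e_i} p_s, i.e. uses the conditional distribution of the
  residual given that it exceeds the censoring residual. The literal
  unnormalized tail sum (`conditional=False`) penalizes heavily censored
  subjects asymmetrically; both are implemented and agree in the uncensored
  limit.
* **Residuals beyond all support** (e_i ≥ τ): the subject contributes
  through the nearest support point τ rather than being dropped.

σ of the continuous outcome model is co-estimated by appending log σ to the
Nelder–Mead vector. Starting values come from the complete-case weighted
regression of y on (log m, dummies, z) — statsmodels WLS/GLM — falling back
to zeros if that regression fails. Optimizer defaults: Nelder–Mead with
xatol = fatol = 1e−6 and a 2000·dim evaluation cap; the fit is
deterministic given the starting values, and a non-convergent fit is
returned with `converged=False`.

Evaluation is vectorized: censored subjects sharing a design row share the
support-point sums (binary family: reverse cumulative sums per distinct
exposure pattern, O(q) per pattern), and the continuous family reuses one
preallocated (n_censored × q) buffer with an underflow-rescue log-sum-exp
pass for extreme parameter values.

## Theoretical-effect oracle

`theoretical_effects` evaluates the same effect formulas with the
generating parameters and a standard normal error law: closed form in the
continuous family (IE_j = b·a_j, DE_j = c_j), 40-node Gauss–Hermite
quadrature in the binary family (node count configurable; results are
stable to 1e−12 against 120 nodes and agree with 10^7-draw Monte-Carlo
integration to better than 1e−4). For the binary designs with ~30% and ~9%
prevalence the oracle gives overall IE 0.0418 and 0.0198; it is the
package's internal ground truth for coverage and consistency checks.

## Inference

BCa intervals use z0 from the fraction of bootstrap replicates below the
point estimate (ties counted half, proportion clamped to
[1/(B+1), B/(B+1)] with a warning) and jackknife-skewness acceleration;
`acceleration="none"` gives the faster bias-corrected-only variant (used
for simulation-scale coverage runs; leave-one-out refits are O(n) full
pipelines). Resampling is of whole subjects, stratified by case/control
status in binary designs so the fixed margins of the sampling design are
preserved; Ĝ, η̂ and both stages are re-estimated inside every replicate.
Bootstrap refits warm-start the stage-2 optimizer at the full-data estimate.
Replicates whose fits fail are dropped and counted; more than 10% failures
is an error. B defaults to 200 (application grade); a warning flags
B < 999. Significance uses the closed-interval convention: an interval
touching the null value is not significant.

## Simulation engine

The generator mirrors the validation designs: Hardy–Weinberg genotypes at a
given MAF with per-allele coefficients (a_j = j·a, c_j = j·c), log-normal
mediator via the AFT model, logistic or linear outcome generated from the
**latent uncensored** log t, optional single covariate
z ~ N(0, 0.5²) entering both models with γ = γ̃ = 0.4, and equal-margin
case-control ascertainment from an adaptively sized population pool (three
times the expected requirement) with inverse-prevalence weights computed at
the Monte-Carlo population prevalence.

Censoring is independent **log-uniform**: log c ~ U(L, U) with L fixed at
a0 − 4 and U calibrated by bisection on a 200k-draw Monte-Carlo sample to
hit the target censoring rate within a fraction of a percentage point. A
time-scale uniform law U(0, U) cannot reach 20–40% censoring of a
log-normal mediator without pulling U below the mediator's upper tail;
events beyond U would then be unobservable, the censoring support would not
cover the mediator support, and IPCW-WLS would be structurally attenuated
(observed: â1 ≈ 0.19 instead of 0.4 at 39% censoring). The log-uniform law
reaches any censoring rate with negligible truncation (P(log t > U) ~ 1e−11
at 39%).

σ of the continuous outcome error defaults to 1 (not dictated by the
designs; configurable). Randomness derives from one master seed through
`SeedSequence.spawn`, one stream per replicate, so studies are bit
reproducible.

What the generator does **not** emulate: linkage disequilibrium or
multi-variant genomes, population stratification, covariate-dependent or
informative censoring, measurement error, missing data. Passing tests
therefore demonstrate correctness of the estimator under its own
assumptions, not robustness to their violation.

## Problem sizes

Replicate counts are chosen for desk-scale runs as a Monte-Carlo precision
trade-off: the acceptance script uses 500 replicates for the binary
studies and 300 for the continuous study (Monte-Carlo SE of the mean IE
≈ 0.002); the test suite uses 100–200 replicates with tolerance bands of
3 SD/√R plus the published means' own 3 SE/√500. The coverage experiment in
the tests is run at n = 200 with 40 outer replicates and B = 199, checked
against nominal 95% within three binomial standard errors.

## Known limitations

* No exposure–mediator interaction in the outcome model, and no effect
  decompositions on odds-ratio scales.
* Right censoring only; no left/interval censoring, no time-dependent
  covariates, no Cox-type mediator models.
* IPCW requires the censoring support to cover the mediator support; data
  violating this are estimated over the observable region only.
* The pseudo-likelihood treats θ̂ and η̂ as fixed; all parameter
  uncertainty is propagated through the bootstrap rather than analytic
  variance formulas.
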