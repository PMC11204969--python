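# Methods

## Model and estimand

The package targets the intention-to-treat effect of one surgical
procedure versus another on overall survival in an emulated trial.  The
outcome model is a Weibull proportional-hazards regression

    h(t | x, A) = k · λ · t^(k−1) · exp(xᵀβ + A·β_A),

with shape k > 0, baseline rate λ = exp(intercept), covariate log-hazard
effects β and treatment log hazard ratio β_A.  For the Weibull family
this is the same model as the accelerated-failure-time formulation
(β_AFT = −β/k), so the treatment prior — elicited on the log-HR scale —
is placed directly on β_A with no transformation.  This is a deliberate
design choice: an AFT-parameterized sampler plus a transform would
target the identical posterior, and the PH scale is the one reported.

Confounding is addressed by inverse-probability-of-treatment weighting.
The propensity model is Bayesian logistic regression with independent
N(0, 100) coefficient priors.  Rather than collapsing the propensity
posterior to a point estimate, the retained posterior draws each induce
a stabilized, truncated weight vector (a pseudo-population); the outcome
model is fitted to every pseudo-population and the per-set posteriors
are concatenated.  The pooled credible interval for β_A therefore
propagates propensity-estimation uncertainty — the test suite verifies
it is, on average, at least as wide as the interval from a single
pseudo-population built on the posterior-mean score.

The weights enter the outcome likelihood as frequency-style multipliers
on per-subject log-likelihood terms.  The resulting object is a
pseudo-posterior (no curvature correction is applied); its credible
intervals are interpreted in that light and cross-checked against
replicate-based coverage in the tests.

## Prior elicitation

A table of published hazard ratios is summarized by its median and its
*unscaled* median absolute deviation (no 1.4826 normal-consistency
factor: the summary describes the literature, it does not estimate a
normal scale).  The treatment prior is

    β_A ~ N( log(median_HR), (inflation · MAD/median_HR)² ),

with the spread transferred to the log scale by the delta method.  The
inflation factor (default 3) is the single most consequential constant
the elicitation leaves open; it is an explicit configuration knob,
echoed into every run report, and the prior SD is floored at 0.1 so the
prior is always proper.  Defaults consume the summary inputs
median HR = 1.631, MAD = 0.497 (the 17 underlying study-level HRs are
not shipped; the elicitation operates on any user-supplied evidence
CSV).  Remaining priors: covariate and intercept effects N(0, 10²),
shape k ~ Exp(1) sampled on log k with the Jacobian included.

## Sampling

Both models use a preconditioned Gaussian random-walk Metropolis
sampler.  The proposal covariance is the inverse observed information at
the maximum-likelihood estimate scaled by 2.38²/d; a scalar step size is
adapted by Robbins–Monro toward acceptance 0.234 during burn-in and
frozen afterwards, so the post-burn-in chain has the exact target as its
stationary law.  Chains initialize at the ML estimate (diagnostic chains
are jittered by one ML-covariance draw); initialization and
preconditioning affect efficiency only, never the target.  If the
logistic ML fit detects separation, a warning is raised and a
ridge-stabilized fit initializes the chain — the N(0, 100) prior keeps
the posterior proper.

Protocol defaults: propensity model 10,000 iterations, 5,000 burn-in,
thinned to every 10th draw (500 retained score sets); outcome model
20,000 iterations, 10,000 burn-in at full scale.  Desk-scale pipeline
defaults use 50 weight sets × 2,000 retained outcome draws (4,000
iterations, 2,000 burn-in per set), which one CPU completes in ~25 s at
n ≈ 1,100; the full 500 × 10,000 protocol is a configuration change.
Production score draws come from one long chain; convergence is judged
separately from five independent chains via the classic (non-split)
Gelman–Rubin PSRF,

    R̂ = sqrt( ((n−1)/n · W + B/n) / W ),

computed per parameter from post-burn-in, unthinned chains.  The
diagnostic outcome chains default to the full 20,000/10,000 protocol
regardless of the per-set desk-scale settings, so convergence is
assessed at the lengths the analysis prescribes.  Identical chains give
R̂ = sqrt((n−1)/n) slightly below 1; values under 1.02 are treated as
converged.  (This classic statistic is deliberately hand-implemented:
modern rank-normalized split-R̂ is a different, stricter diagnostic.)

## Weighting and balance

Raw weights are 1/e for the arm coded 1 (ablation) and 1/(1−e)
otherwise; stabilization multiplies by the empirical marginal arm share.
Truncation replaces any weight above the 99.5th percentile with that
percentile, computed over the combined cohort *within each weight set*
(not per arm, and not pooled across sets — the least-stratified reading
of "the upper 99.5% percentile", applied per pseudo-population because
each is analysed separately).  Sums of stabilized weights per arm equal
the arm sizes in expectation only; finite-sample deviation of a few
percent in the smaller arm is normal and is what the balance tests
allow.

Balance uses the absolute standardized mean difference
d_j = |x̄₁ − x̄₀| / sqrt((s₁² + s₀²)/2) with weighted means and
frequency-weight variances (Σw(x−x̄)²/Σw); zero pooled variance yields 0
when the arm means agree and infinity otherwise.

## Trial emulation rules

Exclusions are attributed to the *first* failing rule in a fixed order
(malformed record, enrollment, age, accrual window, missing
month/stage/size, stage, tumor size, surgery window, same-day dual
procedure), the way selection flowcharts report sequential attrition.
"Within one year" means surgery date ≤ diagnosis date + 365 days, a
closed interval; the day-count convention is a documented choice, since
calendar-year arithmetic is equally defensible.  Time zero is the first
qualifying surgery (first session, for repeated ablations).  Follow-up
ends at min(death, first receipt of the other procedure type, study
end); ties break death > second procedure > administrative end, and only
death is an event.  Same-day deaths receive half a day of follow-up so
event times stay positive for the Weibull likelihood.  Deaths recorded
before surgery raise an error (corrupt record) rather than being
silently dropped.  Continuous covariates (age, tumor size, comorbidity
score) are standardized by the eligible cohort's mean/SD — model
coefficients read per SD — with the scaling stored for
back-transformation.  Marital status is excluded from the propensity
model and included in the outcome model only (it is balanced by design
in the emulated population and serves purely to improve precision).

## Synthetic registry generator

The generator emulates the registry population the analysis assumes:

- **Covariate marginals** default to the target population's totals
  (age 73.6 ± 5.64 y truncated to the eligible band 66–100; tumor size
  29.3 ± 10.5 mm truncated to (0, 50]; Elixhauser score 22.59 ± 8.89;
  prevalences for sex, race, marital status, stage II and eight
  liver-condition flags).  The eight liver flags share one latent
  severity factor through a Gaussian copula (loading 0.5), preserving
  each marginal prevalence while inducing the co-occurrence chronic
  liver disease shows; the joint dependence of real confounders is not
  otherwise reported, so a single-factor structure is the modelled
  choice.
- **Treatment assignment** is Bernoulli(logit⁻¹(xᵀγ)) with γ defaulting
  to the published per-SD assignment coefficients; the intercept (−0.37)
  was set once so the marginal ablation share is ≈ 0.74 under the
  default marginals.
- **Survival** follows the Weibull PH law above with per-SD log-hazard
  defaults, treatment log HR 0.30, shape 1.1, and baseline log-rate
  −2.55 chosen once so the reference-arm median survival is ≈ 5.7 years;
  sampling is inverse-CDF from seeded uniforms, censored at the study
  end date (2019-12-31) given each patient's surgery date.
- **Calendar machinery** works in days: diagnoses uniform over 2007–2017,
  waiting times to surgery lognormal with median 71 days (> 90% within
  200 days), a 10% chance of a repeat ablation session and a 0.5% chance
  of crossover to the other procedure within the first year.
- **Ineligible records**: a configurable fraction is injected in equal
  shares across five violation types (age out of range, missing
  month/stage/size, both procedures same day, surgery beyond one year,
  enrollment gap), each labelled with its ground-truth rule so the
  emulation stage's attrition accounting is testable record by record.

What the generator does **not** emulate: claims-level billing codes,
registry geography, dependence between covariates beyond the liver-flag
factor, non-administrative loss to follow-up, or treatment-effect
heterogeneity.  Passing tests therefore demonstrate that the machinery
is correct under the assumed data-generating law, not that the
assumptions hold in any particular registry.

## Numerical choices and degenerate inputs

- Equal-tailed 95% credible intervals (2.5th/97.5th posterior
  percentiles), the standard reporting convention; HPD intervals are not
  used.  HR summaries exponentiate the log-scale summaries.
- Weight truncation uses linear-interpolation percentiles
  (`numpy.percentile` default), matched exactly by the brute-force
  oracle in the tests.
- Propensity scores are clipped to the open unit interval at machine
  tiny; exact 0/1 inputs to the weighting stage raise.
- Nonpositive Weibull shape returns log-likelihood −∞ (sampler
  rejection), not an exception; all-censored cohorts warn and return a
  prior-dominated posterior.
- Zero-time censored subjects contribute nothing to the likelihood.
- Every stage seed derives from one run seed via `SeedSequence` spawning
  (kept below 2³¹), making full runs bit-reproducible.

## Known limitations

- The weighted posterior is a pseudo-posterior; nominal coverage is
  checked empirically on synthetic replicates, not guaranteed
  analytically.
- Random-walk Metropolis is adequate for these mildly correlated,
  unimodal posteriors but would scale poorly to many more covariates;
  the sampler contract (any correct MCMC targeting the same posterior)
  allows swapping in gradient-based samplers without touching the rest
  of the pipeline.
- The frequentist comparator reports Wald intervals from the observed
  information of a single weighted fit and ignores weight-estimation
  uncertainty — that is its point, as the baseline the Bayesian pipeline
  improves on.
- Subgroup analyses (e.g. tumor ≤ 3 cm) reuse the main-cohort machinery
  via the size cap; no subgroup-specific prior elicitation is performed.
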