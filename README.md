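# bayestte — Bayesian target-trial emulation for survival outcomes

`bayestte` estimates the comparative effectiveness of two treatments on
overall survival from observational registry data by emulating a
randomized trial and running a fully Bayesian analysis pipeline.  It was
built around the motivating question of partial hepatectomy versus
ablation in elderly patients with early-stage hepatocellular carcinoma
(HCC), where the registry linkage that supports such analyses is
restricted by data-use agreements — so the package ships a synthetic
registry generator with the same statistical structure, and every stage
is tested against it.

It is aimed at biostatisticians and epidemiologists who want a
propensity-weighted survival analysis that carries *propensity
estimation uncertainty* into the treatment-effect interval, something a
single point-estimate weight vector cannot do.

## The method

1. **Trial emulation.** Registry records pass a fixed sequence of
   eligibility rules (age 66–100 at diagnosis, accrual window 2007–2017,
   stage I–II, tumor ≤ 5 cm — or ≤ 3 cm for the subgroup — first
   qualifying surgery within one year of diagnosis, no same-day receipt
   of both procedures, continuous enrollment).  The arm is
   intention-to-treat (first procedure received); time zero is the
   surgery date; follow-up runs to death, receipt of the other procedure
   type, or administrative end of study.

2. **Prior elicitation.** Published hazard ratios are condensed to a
   median and raw median absolute deviation, here consumed as the
   summary inputs median HR = 1.631, MAD = 0.497; the treatment log-HR
   prior is N(m₀, s₀²) with m₀ = log(median) and
   s₀ = inflation × MAD / median (default inflation 3, floor 0.1).

3. **Bayesian propensity scores.** A logistic model of treatment on the
   baseline confounders with independent N(0, 100) priors is sampled by
   adaptive random-walk Metropolis (10,000 iterations, 5,000 burn-in,
   thin 10 → 500 retained draws), giving 500 propensity-score vectors
   e⁽ᵈ⁾(x) = P(A = 1 | x).

4. **Weighting.** Each score draw yields stabilized IPT weights
   swᵢ = P̂(A = aᵢ) / P(aᵢ | xᵢ), truncated at the cohort's upper 99.5th
   percentile — one pseudo-population per draw.  Balance is checked via
   absolute standardized mean differences (target < 0.1).

5. **Weighted Bayesian Weibull survival model.** For each
   pseudo-population, the Weibull proportional-hazards model
   h(t | x) = k λ t^(k−1) exp(xᵀβ) — identical to the Weibull AFT model
   up to β_AFT = −β/k — is sampled with the weights entering as
   frequency-style multipliers on the per-subject log-likelihood
   (priors: treatment β_A from step 2, other β ~ N(0, 10²), k ~ Exp(1)).
   Per-set posteriors are pooled by concatenation; the pooled 95%
   equal-tailed credible interval for β_A therefore reflects both
   outcome-model and propensity-model uncertainty.

6. **Diagnostics and reporting.** Five independent chains per model are
   checked with the classic Gelman–Rubin PSRF; Kaplan–Meier curves,
   log-rank test, a Table-1-style descriptive summary, and a frequentist
   comparator (one ML propensity fit → one weight vector → weighted ML
   Weibull fit with Wald intervals) complete the run report.

## Worked example

```sh
bayestte run-all --n 1146 --seed 42 --out results/demo
```

simulates a registry of 1,146 patients (the size of the motivating
cohort), emulates the trial, and runs the desk-scale pipeline
(50 pseudo-populations × 2,000 retained outcome draws; ~25 s on one
CPU).  It prints:

```
ablation vs hepatectomy: log HR 0.27 (95% CrI 0.11, 0.42); HR 1.30 (1.11, 1.53)
```

meaning the posterior median log hazard ratio of ablation versus partial
hepatectomy is 0.27 — ablation is associated with a 30% higher mortality
hazard (HR 1.30), and the credible interval excludes no effect.  The run
directory contains `report.json` (prior, exclusion log, arm sizes,
KM medians — 5.9 vs 4.1 years here — log-rank p, PSRF per parameter),
`posterior_summary.csv`, `balance.csv` (mean SMD dropped from 0.20 to
0.06, all covariates < 0.1), the comparator table, KM/love/trace plots,
and the simulated registry itself.  Every stage is also available as its
own subcommand (`simulate`, `emulate`, `elicit-prior`, `fit-ps`,
`weight`, `fit-outcome`, `report`) or as library functions.

The generating log HR of the synthetic registry is 0.30, so the interval
should (and does) cover the truth; interval calibration is verified
across replicate pipelines in the test suite.

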