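# Methods

## Net benefit and the threshold grid

A decision strategy treats patient *i* when their predicted risk exceeds the
decision threshold *t* (strictly: `prediction > t`, so a tie at the threshold
counts as negative — this keeps a 0/1 test positive for every t in (0, 1)
and keeps `w_t = t/(1−t)` finite across the grid; the tie rule is a package
convention, as ties have probability zero for continuous predictions).
Net benefit at *t* is `NB_t = (TP_t − FP_t·w_t)/n`: each false positive
costs `w_t` of a true positive, which is exactly the exchange rate a
clinician accepts by choosing threshold *t*. The default grid is 0.00–0.50
in steps of 0.01 — thresholds above 50% mean false positives cost more than
false negatives, which is rarely the regime of interest for the screening
and diagnosis problems this package targets — and is fully overridable.
Validation data must be complete-case: rows with missing values are rejected
with their indices, because the tabulated counts are the sufficient
statistics of everything downstream and imputation would silently change the
model.

## Binary outcomes: conjugate factorized posterior

Writing net benefit in terms of prevalence p, sensitivity Se_t and
specificity Sp_t,

    NB_t = Se_t · p − (1 − Sp_t) · (1 − p) · w_t,

the joint Bernoulli model of (disease, positivity) makes (p, Se, Sp)
orthogonal, so with independent Beta(α, β) priors the posterior is a product
of Betas updated by (D, ND), (TP, FN) and (TN, FP) respectively. Sampling
the joint posterior is just sampling the three marginals — no MCMC, and an
entire decision curve costs milliseconds. Defaults are uniform Beta(1, 1)
priors and M = 4,000 draws.

Design choices that matter:

* **Specificity is parameterized directly** (not its complement): priors are
  specified in the terms users actually reason about.
* **One prevalence posterior is shared** by every strategy and every
  threshold in an analysis. This is what makes decision curves strongly
  positively correlated, so differences between curves are much more precise
  than the marginal bands suggest, and draw-wise comparisons (P(best),
  pairwise, EVPI) are only valid on these index-aligned draws. Re-sampling a
  strategy independently would destroy that structure, so the interrogation
  functions only accept a jointly sampled curve set.
* **Case-control designs**: the in-sample case fraction is fixed by design,
  so the prevalence posterior can be replaced by Beta(cases+α, noncases+β)
  built from external cross-sectional counts, propagating the external
  uncertainty instead of plugging in a point estimate.
* **Empty cells do not collapse**: when no prediction clears a threshold,
  the Se/Sp posteriors are proper but prior-dominated; the cell is flagged
  and a warning emitted rather than forcing the curve to zero. (The
  percentile bootstrap, provided as a test comparator, degenerates to {0}
  in exactly this situation.)
* **Per-threshold priors** for Se/Sp are accepted as sequences over the
  grid, as a hook for informative priors encoding that sensitivity falls
  and specificity rises with the threshold; no default informative
  construction is shipped.

## Survival outcomes: Beta × censored-Weibull

For a prognostic model predicting event risk by horizon τ, net benefit at
threshold *t* is

    NB_t = (1 − S(τ|Z=1)) · p − S(τ|Z=1) · p · w_t,

with p = P(positive prediction) and S(τ|Z=1) the survival probability at the
horizon among positive-prediction patients. The likelihood factorizes into a
Bernoulli block for Z, a censored-Weibull block for the positives, and a
nuisance Weibull block for the negatives that never enters the net benefit
and is not sampled. p gets a conjugate Beta update; the positive-group
Weibull shape α and scale σ are sampled by MCMC, and S(τ) = exp(−(τ/σ)^α)
per draw. The horizon must be supplied explicitly — it is a scientific
choice, not a default. Treat-all is the special case p ≡ 1 with a single
cohort-wide Weibull fit shared across thresholds (one fit, not one per
threshold, since the positive set is the whole cohort regardless of t).

Default priors: Half-Student-t(5, 0, 1.5) on the shape — near-equal mass on
increasing (α > 1) and decreasing (α < 1) hazards — and Half-Student-t(30,
0, 100) on the scale, vague over plausible time scales in months. A Gamma
(shape, rate) family is available with no canonical defaults.

**Sampler.** The two-parameter posterior is sampled on the log scale with an
affine-invariant ensemble sampler (emcee) using differential-evolution and
snooker moves; defaults are 16 walkers, 500 warm-up steps, thinning 4, and
4,000 total retained draws. Split-R̂ and bulk ESS are computed over walkers
with arviz; any R̂ > 1.01 flags the fit (warn by default, raise with
`strict=True`). Divergence counts are an HMC-specific diagnostic and are
reported as 0 for completeness of the record. Short-chain configurations
(used in quick studies) produce noisier R̂ estimates and may be flagged even
when summaries are stable. With no positive-prediction patients at all the
prior itself is returned, with a prominent warning.

The posterior survival uses the standard Weibull survival function
exp(−(τ/σ)^α), the form consistent with the censored-Weibull likelihood and
the shape–scale parameterization throughout.

## Interrogation statistics

All statistics are strict-inequality, draw-wise functionals of the
index-aligned draws:

* `p_useful(s, t)` = mean over draws of `NB_s > max(NB_treat-all, 0)`;
* `p_best(s, t)` compares against the per-draw maximum of all other
  strategies (including both defaults); with a single model it coincides
  with `p_useful`, and with several models `p_best ≤ p_useful`;
* `pairwise_superiority(s1, s2, t, c)` returns P(ΔNB > c) plus the full
  delta vector for density/interval displays (66% and 95% levels in the
  plots);
* `evpi(t) = E[max_s NB_s] − max_s E[NB_s]` ≥ 0 by Jensen; reported per
  threshold with no smoothing across thresholds.

Strictness makes the degenerate identical-strategy comparison well defined
(probability 0) and is immaterial otherwise since the posteriors are
continuous. Reported probabilities have Monte-Carlo standard error at most
`sqrt(0.25/M)` (≈ 0.008 at the default M = 4,000).

## Simulation engine

The generators define the benchmark conditions:

* **Binary**: covariates x₁, x₂ ~ iid Exp(1); true risk
  `logit⁻¹(β₀ + β₁x₁ + β₂x₂)`; outcome Bernoulli. The model under
  validation uses the same covariates with exaggerated coefficients
  (`beta_hat`), emulating overfitting: predictions too close to 0/1 with
  near-maximal discrimination. Six canonical settings cross maximum AUC
  {0.65, 0.85} with prevalence {1%, 5%, 30%} (`settings.yaml`).
* **Survival**: x₁, x₂ ~ iid N(0, 1); Weibull proportional-hazards event
  times with hazard `γ·λ·t^(γ−1)·exp(x'β)` (scale convention λ = σ^(−γ);
  the conversion to the shape–scale form used by the posterior model is
  exact), censoring Uniform(0, 24) months, horizon 12 months. The model's
  predicted risk uses the true baseline with exaggerated coefficients:
  `1 − exp(−λ·τ^γ·exp(x'β̂))` — miscalibration purely through the
  coefficients, mirroring the binary design. Nine canonical settings cross
  maximum C-statistic {0.60, 0.90, 0.95} with 1-year survival
  {10%, 20%, 50%}. One caveat: the printed parameters of the C = 0.95 /
  S(1) = 50% setting actually imply a marginal 12-month survival of ≈ 0.475;
  the generator implements the parameters as given, so calibration checks
  against the nominal 0.50 fail for that row by ≈ 0.025.
* **Validation studies** draw `round(100 / event_rate)` subjects without
  replacement (~100 expected events; n ≈ 333 / 2,000 / 10,000 at
  prevalence 30% / 5% / 1%). For survival settings the event rate is the
  population's observed (non-censored) event fraction.
* **Oracles**: true binary net benefit plugs exact population Se/Sp/
  prevalence into the rate form (identical to the count form on a finite
  population); true survival net benefit uses the latent uncensored event
  times among positive predictions. Coverage, bias and MAPE are always
  measured against these oracles, never against sample quantities.
* **Seeding**: per-replicate seeds are spawned from the master seed via
  `numpy.random.SeedSequence`, so replicates are independent and
  individually re-runnable; identical (setting, seed) inputs reproduce
  reports bit-for-bit. Per-rep failures are recorded in the report rather
  than aborting the study.

Problem sizes used by the shipped studies: populations of 10⁵ subjects for
the binary coverage study (500 replicates, M = 4,000) and 2×10⁶ for the
survival population-calibration checks; these sizes keep the population
oracle's own Monte-Carlo error a small fraction of the tolerances being
checked.

What passing these studies shows — and does not show: the generators share
the structural form of the fitted models (logistic / Weibull-PH), so the
benchmarks measure sampling-uncertainty calibration, not robustness to model
misspecification, covariate shift, measurement error or non-proportional
hazards.

## Known limitations

* No competing risks, time-varying predictions, repeated measures, or
  alternative survival likelihoods (piecewise exponential, splines).
* Survival credible intervals can undercover slightly in small samples via
  the known positive bias of Weibull shape estimation; the coverage check
  is correspondingly set at ≥ 88% rather than nominal.
* The multi-setting random-effects (meta-analysis) formulation is out of
  scope; the models here are single-setting.
* EVPI is a per-threshold summary of the current posterior; no
  sample-information (EVSI) extension is provided.
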