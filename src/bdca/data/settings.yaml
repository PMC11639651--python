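# Canonical simulation settings.
#
# Binary settings: a logistic-regression population with two iid Exp(1)
# covariates; beta = [intercept, -log(or), +log(or)] generates the data and
# beta_hat = [intercept_hat, -log(or)*multiplier, +log(or)*multiplier] is the
# miscalibrated (overly extreme) model under validation.  max_auc is the AUC
# of the true risk, i.e. the setting's signal-to-noise ceiling.
#
# Survival settings: a Weibull proportional-hazards population with two
# standard-normal covariates, hazard h(t|x) = shape*scale*t^(shape-1)*
# exp(x'beta) (scale here is lambda = sigma^-alpha), uniform censoring on
# (0, 24) months and a 12-month prediction horizon.  beta = [log(hr1),
# log(hr2)]; the model under validation exaggerates both by `multiplier`.
# surv_1yr is the marginal 12-month survival the parameters target.
binary:
  auc065_prev01: {max_auc: 0.65, prevalence: 0.01, intercept: -4.750, or: 1.50, intercept_hat: -5.000, multiplier: 1.25}
  auc065_prev05: {max_auc: 0.65, prevalence: 0.05, intercept: -3.100, or: 1.50, intercept_hat: -3.900, multiplier: 3.00}
  auc065_prev30: {max_auc: 0.65, prevalence: 0.30, intercept: -0.900, or: 1.55, intercept_hat: -1.200, multiplier: 3.00}
  auc085_prev01: {max_auc: 0.85, prevalence: 0.01, intercept: -5.600, or: 2.57, intercept_hat: -6.900, multiplier: 1.50}
  auc085_prev05: {max_auc: 0.85, prevalence: 0.05, intercept: -3.755, or: 2.95, intercept_hat: -7.300, multiplier: 3.00}
  auc085_prev30: {max_auc: 0.85, prevalence: 0.30, intercept: -1.300, or: 4.50, intercept_hat: -2.250, multiplier: 3.00}
survival:
  c060_surv10: {max_cstat: 0.60, surv_1yr: 0.10, shape: 1.22, scale: 0.12, hr1: 1.30, hr2: 0.70, multiplier: 1.01}
  c060_surv20: {max_cstat: 0.60, surv_1yr: 0.20, shape: 1.07, scale: 0.12, hr1: 1.30, hr2: 0.70, multiplier: 1.01}
  c060_surv50: {max_cstat: 0.60, surv_1yr: 0.50, shape: 0.70, scale: 0.12, hr1: 1.30, hr2: 0.70, multiplier: 1.01}
  c090_surv10: {max_cstat: 0.90, surv_1yr: 0.10, shape: 4.60, scale: 0.0004, hr1: 1.95, hr2: 0.05, multiplier: 1.25}
  c090_surv20: {max_cstat: 0.90, surv_1yr: 0.20, shape: 4.00, scale: 0.0004, hr1: 1.95, hr2: 0.05, multiplier: 1.25}
  c090_surv50: {max_cstat: 0.90, surv_1yr: 0.50, shape: 2.90, scale: 0.0004, hr1: 1.95, hr2: 0.05, multiplier: 1.25}
  c095_surv10: {max_cstat: 0.95, surv_1yr: 0.10, shape: 6.50, scale: 0.0004, hr1: 1.95, hr2: 0.001, multiplier: 1.25}
  c095_surv20: {max_cstat: 0.95, surv_1yr: 0.20, shape: 5.40, scale: 0.0004, hr1: 1.95, hr2: 0.001, multiplier: 1.25}
  c095_surv50: {max_cstat: 0.95, surv_1yr: 0.50, shape: 3.10, scale: 0.0004, hr1: 1.95, hr2: 0.001, multiplier: 1.25}
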