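"""Synthetic populations, oracles, and the coverage harness."""

import numpy as np
import pytest
from scipy import stats

from bdca import (
    BinaryValidationData,
    bootstrap_net_benefit,
    dca_binary,
    generate_binary_population,
    generate_survival_population,
    get_setting,
    load_settings,
    make_threshold_grid,
    run_simulation_study,
    sample_validation_set,
    simulate_binary_test,
    true_net_benefit_binary,
    true_net_benefit_survival,
    true_net_benefit_treat_all,
)
from bdca.data import ValidationError
from bdca.simulation import BinarySimSetting


class TestSettings:
    def test_canonical_counts(self):
        s = load_settings()
        assert len(s["binary"]) == 6
        assert len(s["survival"]) == 9

    def test_binary_row_composition(self):
        s = get_setting("auc085_prev30")
        assert s.prevalence == 0.30 and s.max_auc == 0.85
        assert s.beta == pytest.approx([-1.3, -np.log(4.5), np.log(4.5)])
        assert s.beta_hat == pytest.approx(
            [-2.25, -3 * np.log(4.5), 3 * np.log(4.5)]
        )

    def test_survival_row_scale_conversion(self):
        s = get_setting("c060_surv10")
        assert s.gamma == 1.22 and s.lam == 0.12
        # sigma = lam^(-1/gamma) is the exact shape/scale conversion
        assert s.sigma == pytest.approx(0.12 ** (-1 / 1.22))

    def test_unknown_setting_lists_available(self):
        with pytest.raises(KeyError, match="available"):
            get_setting("nope")


class TestBinaryPopulation:
    @pytest.fixture(scope="class")
    def pop(self):
        return generate_binary_population(get_setting("auc085_prev30"), 100_000, seed=11)

    def test_prevalence_matches_setting(self, pop):
        assert pop.y.mean() == pytest.approx(0.30, abs=0.01)

    def test_max_auc_matches_setting(self, pop):
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(pop.y, pop.p_true) == pytest.approx(0.85, abs=0.01)

    def test_model_is_miscalibrated_but_discriminates(self, pop):
        from sklearn.metrics import roc_auc_score

        # exaggerated coefficients: more extreme predictions, similar AUC
        def logit(p):
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return np.log(p / (1 - p))

        assert np.std(logit(pop.p_model)) > np.std(logit(pop.p_true))
        assert roc_auc_score(pop.y, pop.p_model) > 0.8

    @pytest.mark.parametrize(
        "name",
        [
            "auc065_prev01", "auc065_prev05", "auc065_prev30",
            "auc085_prev01", "auc085_prev05", "auc085_prev30",
        ],
    )
    def test_all_settings_hit_nominal_prevalence_and_auc(self, name):
        from sklearn.metrics import roc_auc_score

        s = get_setting(name)
        # 400k subjects keep enough events for a stable AUC even at 1% prevalence
        pop = generate_binary_population(s, 400_000, seed=17)
        assert pop.y.mean() == pytest.approx(s.prevalence, abs=0.01)
        # printed setting AUCs are rounded targets; low-prevalence rows sit
        # slightly above them, so allow 0.02 here (0.01 checked above for
        # the high-signal/high-prevalence row)
        assert roc_auc_score(pop.y, pop.p_true) == pytest.approx(
            s.max_auc, abs=0.02
        )

    def test_identity_model_when_beta_hat_equals_beta(self):
        base = get_setting("auc085_prev30")
        setting = BinarySimSetting(
            name="ident", max_auc=base.max_auc, prevalence=base.prevalence,
            beta=base.beta, beta_hat=base.beta,
        )
        pop = generate_binary_population(setting, 1000, seed=3)
        assert np.allclose(pop.p_model, pop.p_true)

    def test_reproducible(self):
        s = get_setting("auc065_prev05")
        p1 = generate_binary_population(s, 500, seed=9)
        p2 = generate_binary_population(s, 500, seed=9)
        assert np.array_equal(p1.y, p2.y) and np.array_equal(p1.x, p2.x)


class TestSurvivalPopulation:
    @pytest.fixture(scope="class")
    def pop(self):
        return generate_survival_population(get_setting("c060_surv10"), 50_000, seed=12)

    def test_event_time_distribution_pit_uniform(self, pop):
        # per-subject survival transform of the latent times must be U(0,1);
        # scipy's Weibull survival function is the independent reference
        s = pop.setting
        scale = (s.lam * np.exp(pop.x @ s.beta)) ** (-1 / s.gamma)
        pit = stats.weibull_min.sf(pop.true_time[:10_000], s.gamma, scale=scale[:10_000])
        assert stats.kstest(pit, "uniform").pvalue > 0.01

    def test_censoring_and_observed_time(self, pop):
        assert np.all(pop.censor_time <= 24.0)
        assert np.allclose(pop.time, np.minimum(pop.true_time, pop.censor_time))
        assert np.array_equal(
            pop.event, (pop.true_time <= pop.censor_time).astype(np.int8)
        )

    def test_marginal_survival_matches_analytic(self, pop):
        s = pop.setting
        analytic = np.exp(
            -s.lam * s.horizon**s.gamma * np.exp(pop.x @ s.beta)
        ).mean()
        assert (pop.true_time > s.horizon).mean() == pytest.approx(analytic, abs=0.01)

    def test_model_risk_identity_when_not_miscalibrated(self):
        base = get_setting("c060_surv10")
        from bdca.simulation import SurvivalSimSetting

        setting = SurvivalSimSetting(
            name="ident", max_cstat=base.max_cstat, surv_1yr=base.surv_1yr,
            gamma=base.gamma, lam=base.lam, beta=base.beta, beta_hat=base.beta,
        )
        pop = generate_survival_population(setting, 2000, seed=5)
        true_risk = 1 - np.exp(
            -setting.lam * 12.0**setting.gamma * np.exp(pop.x @ setting.beta)
        )
        assert np.allclose(pop.risk_model, true_risk)


class TestBinaryTestGenerator:
    def test_perfect_test_equals_outcomes(self, rng):
        y = (rng.random(100) < 0.4).astype(int)
        assert np.array_equal(simulate_binary_test(y, 1.0, 1.0, seed=1), y)

    def test_never_positive(self, rng):
        y = (rng.random(100) < 0.4).astype(int)
        assert not simulate_binary_test(y, 0.0, 1.0, seed=1).any()

    def test_large_sample_se_sp(self, rng):
        y = (rng.random(100_000) < 0.3).astype(int)
        z = simulate_binary_test(y, 0.81, 0.88, seed=2)
        se = z[y == 1].mean()
        sp = 1 - z[y == 0].mean()
        assert se == pytest.approx(0.81, abs=0.01)
        assert sp == pytest.approx(0.88, abs=0.01)


class TestTrueNetBenefit:
    def test_rate_form_equals_count_form_exactly(self, rng):
        y = (rng.random(5000) < 0.25).astype(int)
        pred = rng.random(5000)
        for t in (0.05, 0.2, 0.6):
            z = pred > t
            counts_nb = (np.sum(z & (y == 1)) - np.sum(z & (y == 0)) * t / (1 - t)) / y.size
            assert true_net_benefit_binary(y, pred, t) == pytest.approx(
                counts_nb, abs=1e-12
            )

    def test_perfect_test_at_zero_threshold(self, rng):
        y = (rng.random(1000) < 0.3).astype(int)
        assert true_net_benefit_binary(y, y.astype(float), 0.0) == pytest.approx(
            y.mean()
        )
        # strict positivity: a 0/1 test at t=0 treats exactly the positives

    def test_never_positive_is_zero(self, rng):
        y = (rng.random(1000) < 0.3).astype(int)
        assert true_net_benefit_binary(y, np.zeros(1000), 0.2) == 0.0

    def test_treat_all_oracle(self, rng):
        y = (rng.random(1000) < 0.3).astype(int)
        p = y.mean()
        assert true_net_benefit_treat_all(y, 0.25) == pytest.approx(p - (1 - p) / 3)

    def test_survival_oracle_no_positives(self, rng):
        tt = rng.weibull(1.2, 100) * 10
        assert true_net_benefit_survival(tt, np.zeros(100), 0.5, 12.0) == 0.0

    def test_survival_oracle_all_positive_equals_treat_all(self, rng):
        tt = rng.weibull(1.2, 2000) * 10
        nb_all = true_net_benefit_survival(tt, None, 0.3, 12.0)
        nb_everyone = true_net_benefit_survival(tt, np.ones(2000), 0.3, 12.0)
        assert nb_all == pytest.approx(nb_everyone)
        s = (tt > 12.0).mean()
        assert nb_all == pytest.approx((1 - s) - s * 0.3 / 0.7)


class TestSampleValidationSet:
    def test_sample_size_from_nominal_prevalence(self):
        pop = generate_binary_population(get_setting("auc085_prev30"), 20_000, seed=1)
        data = sample_validation_set(pop, expected_events=100, seed=2)
        assert data.n == 333

    def test_subset_without_duplicates(self):
        pop = generate_binary_population(get_setting("auc085_prev30"), 5000, seed=1)
        data = sample_validation_set(pop, expected_events=100, seed=3)
        # each sampled (outcome, prediction) pair must exist in the population
        key_pop = set(zip(pop.y.tolist(), np.round(pop.p_model, 12).tolist()))
        key_sample = list(
            zip(data.outcome.tolist(), np.round(data.predictions["model"], 12).tolist())
        )
        assert set(key_sample) <= key_pop
        assert len(key_sample) == len(set(key_sample))

    def test_sample_larger_than_population_rejected(self):
        pop = generate_binary_population(get_setting("auc085_prev01"), 500, seed=1)
        with pytest.raises(ValidationError, match="exceeds population"):
            sample_validation_set(pop, expected_events=100, seed=2)

    def test_survival_rate_from_observed_events(self):
        pop = generate_survival_population(get_setting("c060_surv10"), 30_000, seed=4)
        data = sample_validation_set(pop, expected_events=100, seed=5)
        assert data.n == round(100 / pop.event.mean())


class TestSimulationStudy:
    def test_single_rep_report_shape(self):
        report = run_simulation_study(
            "auc085_prev30", n_reps=1, seed=7, population_size=5000, m=500
        )
        assert len(report.table) == 9
        assert set(report.table.coverage.unique()) <= {0.0, 1.0}
        assert report.failures == []

    def test_deterministic_given_seed(self):
        kw = dict(n_reps=3, seed=21, population_size=5000, m=400)
        r1 = run_simulation_study("auc085_prev30", **kw)
        r2 = run_simulation_study("auc085_prev30", **kw)
        assert r1.table.equals(r2.table)

    def test_doubling_draws_leaves_coverage_stable(self):
        kw = dict(n_reps=40, seed=5, population_size=20_000)
        r1 = run_simulation_study("auc085_prev30", m=2000, **kw)
        r2 = run_simulation_study("auc085_prev30", m=4000, **kw)
        assert np.all(np.abs(r1.table.coverage - r2.table.coverage) <= 0.15)


class TestBootstrapComparator:
    def test_point_estimate_is_empirical_count_form(self, rng):
        y = (rng.random(300) < 0.3).astype(int)
        pred = rng.random(300)
        data = BinaryValidationData(outcome=y, predictions={"m": pred})
        df = bootstrap_net_benefit(data, "m", np.array([0.1, 0.3]), n_boot=50, seed=1)
        for _, row in df.iterrows():
            assert row.nb == pytest.approx(
                true_net_benefit_binary(y, pred, row.threshold)
            )

    def test_bootstrap_collapses_where_bayes_does_not(self, rng):
        # no prediction above t=0.45: the bootstrap interval degenerates to
        # {0}, while the Bayesian posterior keeps positive width
        y = (rng.random(120) < 0.3).astype(int)
        pred = rng.random(120) * 0.4
        data = BinaryValidationData(outcome=y, predictions={"m": pred})
        boot = bootstrap_net_benefit(data, "m", np.array([0.45]), n_boot=100, seed=2)
        assert boot.nb_lo[0] == boot.nb_hi[0] == 0.0
        with pytest.warns(UserWarning):
            curves = dca_binary(data, make_threshold_grid([0.45]), m=4000, seed=3)
        draws = curves.draws("m", 0.45)
        assert np.percentile(draws, 97.5) - np.percentile(draws, 2.5) > 0.001
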