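"""Synthetic populations, true-net-benefit oracles, and the coverage harness.

The generators emulate external validation of a fixed, miscalibrated
prediction model.  A large population is simulated from a known
data-generating process; each simulated validation study draws a sample
sized for ~100 expected events, runs the full Bayesian decision curve
analysis, and compares its per-threshold estimates and 95% credible
intervals against the population's true net benefit.

Binary populations use a logistic model with two iid Exp(1) covariates.
Survival populations use a Weibull proportional-hazards model with two
standard-normal covariates (hazard h(t|x) = gamma * lam * t^(gamma-1) *
exp(x'beta), i.e. scale lam = sigma^-alpha in shape/scale terms) and
Uniform(0, 24)-month censoring.  The model under validation shares the DGP's
structure but exaggerates its coefficients — the classic overfitting
signature of predictions too close to 0 or 1.

What these populations do not emulate: covariate measurement error,
distribution shift between development and validation, or non-PH hazards.
Calibration results here speak to sampling uncertainty only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .binary import BinaryPriors, dca_binary
from .data import BinaryValidationData, SurvivalValidationData, ThresholdGrid, ValidationError
from .interrogation import summarize_curves

__all__ = [
    "BinarySimSetting",
    "SurvivalSimSetting",
    "BinaryPopulation",
    "SurvivalPopulation",
    "SimulationReport",
    "load_settings",
    "generate_binary_population",
    "generate_survival_population",
    "simulate_binary_test",
    "true_net_benefit_binary",
    "true_net_benefit_treat_all",
    "true_net_benefit_survival",
    "sample_validation_set",
    "run_simulation_study",
    "bootstrap_net_benefit",
]


@dataclass(frozen=True)
class BinarySimSetting:
    """One row of the binary simulation design.

    ``beta`` generates the data; ``beta_hat`` defines the fixed model under
    validation (same structure, exaggerated coefficients).  Both are
    (intercept, coef_x1, coef_x2) with sign-opposed covariate effects.
    """

    name: str
    max_auc: float
    prevalence: float
    beta: np.ndarray
    beta_hat: np.ndarray


@dataclass(frozen=True)
class SurvivalSimSetting:
    """One row of the survival simulation design (shape/rate-style scale).

    ``lam`` is the hazard-scale parameter (lam = sigma^-alpha); the
    conversion to the Weibull scale used by the posterior model is exact:
    sigma = lam^(-1/gamma).
    """

    name: str
    max_cstat: float
    surv_1yr: float
    gamma: float
    lam: float
    beta: np.ndarray
    beta_hat: np.ndarray
    censor_max: float = 24.0
    horizon: float = 12.0

    @property
    def sigma(self) -> float:
        return self.lam ** (-1.0 / self.gamma)


def load_settings() -> dict:
    """Canonical simulation settings shipped with the package."""
    text = resources.files("bdca").joinpath("data/settings.yaml").read_text()
    raw = yaml.safe_load(text)
    binary = {}
    for name, s in raw["binary"].items():
        lo = np.log(s["or"])
        binary[name] = BinarySimSetting(
            name=name,
            max_auc=s["max_auc"],
            prevalence=s["prevalence"],
            beta=np.array([s["intercept"], -lo, lo]),
            beta_hat=np.array(
                [s["intercept_hat"], -lo * s["multiplier"], lo * s["multiplier"]]
            ),
        )
    survival = {}
    for name, s in raw["survival"].items():
        beta = np.array([np.log(s["hr1"]), np.log(s["hr2"])])
        survival[name] = SurvivalSimSetting(
            name=name,
            max_cstat=s["max_cstat"],
            surv_1yr=s["surv_1yr"],
            gamma=s["shape"],
            lam=s["scale"],
            beta=beta,
            beta_hat=beta * s["multiplier"],
        )
    return {"binary": binary, "survival": survival}


_SETTINGS_CACHE: dict | None = None


def get_setting(name: str):
    """Look up a canonical setting by name (binary or survival)."""
    global _SETTINGS_CACHE
    if _SETTINGS_CACHE is None:
        _SETTINGS_CACHE = load_settings()
    for kind in ("binary", "survival"):
        if name in _SETTINGS_CACHE[kind]:
            return _SETTINGS_CACHE[kind][name]
    available = sorted(
        list(_SETTINGS_CACHE["binary"]) + list(_SETTINGS_CACHE["survival"])
    )
    raise KeyError(f"unknown setting {name!r}; available: {available}")


@dataclass(frozen=True)
class BinaryPopulation:
    x: np.ndarray  # (n, 2) covariates
    p_true: np.ndarray  # true risk
    p_model: np.ndarray  # model-predicted risk (miscalibrated)
    y: np.ndarray  # 0/1 outcome
    setting: BinarySimSetting

    @property
    def n(self) -> int:
        return int(self.y.size)


@dataclass(frozen=True)
class SurvivalPopulation:
    x: np.ndarray
    true_time: np.ndarray  # latent event time (uncensored)
    censor_time: np.ndarray
    time: np.ndarray  # observed min(T, C)
    event: np.ndarray  # 1 = event observed
    risk_model: np.ndarray  # model-predicted risk by the horizon
    setting: SurvivalSimSetting

    @property
    def n(self) -> int:
        return int(self.time.size)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_binary_population(
    setting: BinarySimSetting, n: int, seed: int | None = None
) -> BinaryPopulation:
    """Simulate a logistic-model population of size n."""
    if n < 1:
        raise ValidationError("population size must be at least 1")
    rng = np.random.default_rng(seed)
    x = rng.exponential(1.0, size=(n, 2))
    z = np.column_stack([np.ones(n), x])
    p_true = _expit(z @ setting.beta)
    p_model = _expit(z @ setting.beta_hat)
    y = (rng.random(n) < p_true).astype(np.int8)
    return BinaryPopulation(x=x, p_true=p_true, p_model=p_model, y=y, setting=setting)


def generate_survival_population(
    setting: SurvivalSimSetting, n: int, seed: int | None = None
) -> SurvivalPopulation:
    """Simulate a Weibull-PH population with uniform censoring.

    Event times come from inverting S(t|x) = exp(-lam * t^gamma * e^{x'beta});
    the model's predicted risk at the horizon uses the true baseline with the
    exaggerated coefficients: r = 1 - exp(-lam * tau^gamma * e^{x'beta_hat}).
    """
    if n < 1:
        raise ValidationError("population size must be at least 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 2))
    eta = x @ setting.beta
    u = rng.random(n)
    true_time = (-np.log(u) / (setting.lam * np.exp(eta))) ** (1.0 / setting.gamma)
    censor_time = rng.uniform(0.0, setting.censor_max, size=n)
    time = np.minimum(true_time, censor_time)
    event = (true_time <= censor_time).astype(np.int8)
    eta_hat = x @ setting.beta_hat
    risk_model = 1.0 - np.exp(
        -setting.lam * setting.horizon**setting.gamma * np.exp(eta_hat)
    )
    return SurvivalPopulation(
        x=x,
        true_time=true_time,
        censor_time=censor_time,
        time=np.maximum(time, 1e-12),
        event=event,
        risk_model=risk_model,
        setting=setting,
    )


def simulate_binary_test(
    outcomes: np.ndarray,
    sensitivity: float,
    specificity: float,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate a binary diagnostic test with fixed Se/Sp per patient."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValidationError("sensitivity and specificity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    y = np.asarray(outcomes).astype(bool)
    u = rng.random(y.size)
    pos_prob = np.where(y, sensitivity, 1.0 - specificity)
    return (u < pos_prob).astype(np.int8)


def true_net_benefit_binary(
    y: np.ndarray, predictions: np.ndarray, t: float
) -> float:
    """Population-oracle net benefit of a strategy at threshold t.

    Evaluates Se*p - (1-Sp)*(1-p)*w_t with the population's exact Se, Sp and
    prevalence; on a finite population this equals the count form
    (TP - FP*w_t)/n identically.
    """
    y = np.asarray(y).astype(bool)
    z = np.asarray(predictions) > t
    n = y.size
    prev = y.mean()
    w = t / (1.0 - t)
    if prev == 0:
        return float(-(z & ~y).mean() * w)
    se = np.sum(z & y) / np.sum(y)
    sp = np.sum(~z & ~y) / np.sum(~y) if prev < 1 else 1.0
    return float(se * prev - (1.0 - sp) * (1.0 - prev) * w)


def true_net_benefit_treat_all(y: np.ndarray, t: float) -> float:
    """Population-oracle treat-all net benefit p - (1-p)*w_t."""
    prev = float(np.asarray(y).mean())
    return prev - (1.0 - prev) * t / (1.0 - t)


def true_net_benefit_survival(
    true_time: np.ndarray,
    predictions: np.ndarray | None,
    t: float,
    tau: float,
) -> float:
    """Population-oracle survival net benefit from uncensored event times.

    ``predictions=None`` gives the treat-all oracle (everyone positive).
    """
    tt = np.asarray(true_time)
    if predictions is None:
        pos = np.ones(tt.size, dtype=bool)
    else:
        pos = np.asarray(predictions) > t
    p = pos.mean()
    if p == 0:
        return 0.0
    s = float((tt[pos] > tau).mean())
    w = t / (1.0 - t)
    return float((1.0 - s) * p - s * p * w)


def sample_validation_set(
    population: BinaryPopulation | SurvivalPopulation,
    expected_events: int = 100,
    seed: int | None = None,
    event_rate: float | None = None,
    strategy_name: str = "model",
) -> BinaryValidationData | SurvivalValidationData:
    """Draw one validation study from the population (without replacement).

    The sample size is round(expected_events / event_rate); for binary
    outcomes the event rate defaults to the setting's nominal prevalence, and
    for survival outcomes to the population's observed (non-censored) event
    fraction.
    """
    if expected_events < 1:
        raise ValidationError("expected_events must be at least 1")
    rng = np.random.default_rng(seed)
    if event_rate is None:
        if isinstance(population, BinaryPopulation):
            event_rate = population.setting.prevalence
        else:
            event_rate = float(population.event.mean())
    n = int(round(expected_events / event_rate))
    if n > population.n:
        raise ValidationError(
            f"requested sample size {n} exceeds population size {population.n}"
        )
    idx = rng.choice(population.n, size=n, replace=False)
    if isinstance(population, BinaryPopulation):
        return BinaryValidationData(
            outcome=population.y[idx],
            predictions={strategy_name: population.p_model[idx]},
        )
    return SurvivalValidationData(
        time=population.time[idx],
        event=population.event[idx],
        predictions={strategy_name: population.risk_model[idx]},
        horizon=population.setting.horizon,
    )


@dataclass(frozen=True)
class SimulationReport:
    """Per-threshold calibration summary of a simulation study.

    Coverage, bias and mean absolute percentage error are computed against
    the population-oracle true net benefit, never against sample quantities.
    """

    table: pd.DataFrame
    setting: str
    n_reps: int
    seed: int | None
    failures: list = field(default_factory=list)


_DEF_STUDY_THRESHOLDS = np.round(np.arange(0.05, 0.46, 0.05), 2)


def run_simulation_study(
    setting: BinarySimSetting | str,
    n_reps: int = 500,
    expected_events: int = 100,
    thresholds: np.ndarray | None = None,
    m: int = 4000,
    seed: int | None = None,
    population: BinaryPopulation | None = None,
    population_size: int = 100_000,
    priors: BinaryPriors | None = None,
) -> SimulationReport:
    """Coverage/error study of Bayesian DCA for one binary setting.

    Draws ``n_reps`` validation sets from a shared population, runs the
    conjugate analysis on each, and records whether the 95% credible
    interval contains the true (population-oracle) net benefit at each
    threshold.  Per-rep seeds are spawned from the master seed so reps are
    independent and individually reproducible; per-rep failures are recorded
    in the report, not fatal.
    """
    if isinstance(setting, str):
        setting = get_setting(setting)
    if not isinstance(setting, BinarySimSetting):
        raise ValidationError("run_simulation_study expects a binary setting")
    if n_reps < 1:
        raise ValidationError("n_reps must be at least 1")
    thresholds = (
        np.asarray(thresholds, dtype=float)
        if thresholds is not None
        else _DEF_STUDY_THRESHOLDS
    )
    grid = ThresholdGrid(thresholds)

    master = np.random.SeedSequence(seed)
    pop_seed, *rep_seeds = master.spawn(n_reps + 1)
    if population is None:
        population = generate_binary_population(
            setting, population_size, seed=pop_seed
        )
    truth = np.array(
        [true_net_benefit_binary(population.y, population.p_model, t) for t in thresholds]
    )

    covered = np.zeros((n_reps, thresholds.size), dtype=bool)
    errors = np.zeros((n_reps, thresholds.size))
    ok = np.zeros(n_reps, dtype=bool)
    failures = []
    for r, ss in enumerate(rep_seeds):
        child = np.random.default_rng(ss)
        try:
            data = sample_validation_set(
                population, expected_events, seed=np.random.default_rng(ss.spawn(1)[0])
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                curves = dca_binary(
                    data,
                    grid=grid,
                    priors=priors,
                    m=m,
                    seed=int(child.integers(2**31 - 1)),
                )
            summary = summarize_curves(curves)
            model = summary[summary.strategy == "model"].set_index("threshold")
            est = model.loc[thresholds, "nb_mean"].to_numpy()
            lo = model.loc[thresholds, "nb_lo"].to_numpy()
            hi = model.loc[thresholds, "nb_hi"].to_numpy()
            covered[r] = (lo <= truth) & (truth <= hi)
            errors[r] = est - truth
            ok[r] = True
        except Exception as exc:  # pragma: no cover - defensive
            failures.append({"rep": r, "error": repr(exc)})
    if not ok.any():
        raise RuntimeError(f"all {n_reps} replicates failed: {failures[:3]}")
    covered = covered[ok]
    errors = errors[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        ape = np.abs(errors) / np.abs(truth)[None, :]
    table = pd.DataFrame(
        {
            "threshold": thresholds,
            "true_nb": truth,
            "coverage": covered.mean(axis=0),
            "bias": errors.mean(axis=0),
            "mape": np.where(np.abs(truth) > 1e-12, np.nanmean(ape, axis=0), np.nan),
            "n_reps": int(ok.sum()),
        }
    )
    return SimulationReport(
        table=table,
        setting=setting.name,
        n_reps=int(ok.sum()),
        seed=seed,
        failures=failures,
    )


def bootstrap_net_benefit(
    data: BinaryValidationData,
    strategy: str,
    thresholds: np.ndarray,
    n_boot: int = 500,
    seed: int | None = None,
    levels: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Minimal percentile-bootstrap net benefit (frequentist comparator).

    Resamples patients with replacement and evaluates the empirical count
    form (TP - FP*w_t)/n on each resample.  Used as an independent oracle in
    tests; it inherits the known failure mode of collapsing to zero when no
    prediction exceeds the threshold in the observed sample.
    """
    rng = np.random.default_rng(seed)
    y = data.outcome.astype(bool)
    pred = data.predictions[strategy]
    n = y.size
    thresholds = np.asarray(thresholds, dtype=float)
    w = thresholds / (1.0 - thresholds)
    point = np.array(
        [
            (np.sum((pred > t) & y) - np.sum((pred > t) & ~y) * wt) / n
            for t, wt in zip(thresholds, w)
        ]
    )
    boot = np.empty((n_boot, thresholds.size))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb, pb = y[idx], pred[idx]
        for k, (t, wt) in enumerate(zip(thresholds, w)):
            z = pb > t
            boot[b, k] = (np.sum(z & yb) - np.sum(z & ~yb) * wt) / n
    lo, hi = np.percentile(boot, levels, axis=0)
    return pd.DataFrame(
        {"threshold": thresholds, "nb": point, "nb_lo": lo, "nb_hi": hi}
    )
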