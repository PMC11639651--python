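"""Conjugate Bayesian net benefit for binary outcomes.

Jointly modelling the disease indicator D and the positivity indicator Z with
Bernoulli likelihoods makes prevalence (p), sensitivity (Se) and specificity
(Sp) orthogonal parameters.  Under independent Beta priors the joint posterior
factorizes into three independent Beta distributions:

    p  | data ~ Beta(D  + a0, ND + b0)
    Se | data ~ Beta(TP + a1, FN + b1)
    Sp | data ~ Beta(TN + a2, FP + b2)

so no MCMC is needed: marginal draws combine into valid joint draws.  Net
benefit at threshold t is then evaluated draw by draw,

    NB_t = Se * p - (1 - Sp) * (1 - p) * w_t,      w_t = t / (1 - t),

giving the full posterior of the decision curve.  Prevalence is a single
parameter shared by every strategy and threshold within one analysis, which
induces the strong positive correlation between decision curves that the
posterior comparisons rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data import (
    BinaryValidationData,
    DiagnosticCounts,
    ThresholdGrid,
    ValidationError,
    make_threshold_grid,
    tabulate_counts,
)
from .interrogation import TREAT_ALL, TREAT_NONE, DecisionCurveSet

__all__ = [
    "BetaPrior",
    "BinaryPriors",
    "BinaryPosteriorDraws",
    "sample_binary_posterior",
    "sample_prevalence_external",
    "net_benefit_binary",
    "net_benefit_treat_all_binary",
    "dca_binary",
]


@dataclass(frozen=True)
class BetaPrior:
    """Beta(shape1, shape2) prior; Beta(1, 1) is uniform on (0, 1)."""

    shape1: float = 1.0
    shape2: float = 1.0

    def __post_init__(self) -> None:
        if self.shape1 <= 0 or self.shape2 <= 0:
            raise ValidationError("Beta prior shapes must be strictly positive")


UNIFORM = BetaPrior(1.0, 1.0)


@dataclass(frozen=True)
class BinaryPriors:
    """Priors for the three binary-model parameters.

    ``se`` and ``sp`` may each be a single :class:`BetaPrior` applied at every
    threshold, or a sequence with one prior per grid threshold (hook for
    threshold-dependent informative priors, e.g. encoding that sensitivity
    falls and specificity rises with the threshold).
    """

    p: BetaPrior = UNIFORM
    se: BetaPrior | Sequence[BetaPrior] = UNIFORM
    sp: BetaPrior | Sequence[BetaPrior] = UNIFORM

    def at(self, which: str, j: int) -> BetaPrior:
        prior = getattr(self, which)
        if isinstance(prior, BetaPrior):
            return prior
        return prior[j]


@dataclass(frozen=True)
class BinaryPosteriorDraws:
    """Joint posterior draws of (p, Se, Sp) for one strategy and threshold."""

    p: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    threshold: float
    strategy: str

    def __post_init__(self) -> None:
        if not (len(self.p) == len(self.se) == len(self.sp)):
            raise ValidationError("draw vectors must share one length")

    @property
    def m(self) -> int:
        return len(self.p)


def sample_prevalence_external(
    cases: int,
    noncases: int,
    prior: BetaPrior = UNIFORM,
    m: int = 4000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Prevalence draws from external (e.g. cross-sectional) case counts.

    In case-control designs the study-sample case fraction is fixed by design
    and cannot estimate prevalence; these draws, p ~ Beta(cases + a, noncases
    + b), replace the in-sample prevalence posterior in all downstream net
    benefit computations while still propagating its uncertainty.
    """
    if cases < 0 or noncases < 0:
        raise ValidationError("case counts must be non-negative")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return gen.beta(cases + prior.shape1, noncases + prior.shape2, size=m)


def sample_binary_posterior(
    counts: DiagnosticCounts,
    priors: BinaryPriors | None = None,
    m: int = 4000,
    rng: np.random.Generator | int | None = None,
    strategy: str = "model",
    p_draws: np.ndarray | None = None,
) -> BinaryPosteriorDraws:
    """Draw m joint posterior samples of (p, Se, Sp) given 2x2 counts.

    ``p_draws`` allows a shared or external prevalence sample to be reused;
    otherwise prevalence is drawn from its own conjugate posterior.  When no
    prediction is positive at the threshold (tp + fp = 0) the sensitivity and
    specificity posteriors are prior-dominated but remain proper; a warning
    is emitted rather than collapsing the net benefit to zero.
    """
    if m < 1:
        raise ValidationError("m must be at least 1")
    priors = priors or BinaryPriors()
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if counts.tp + counts.fp == 0:
        warnings.warn(
            f"no positive predictions at threshold {counts.threshold:.3g}; "
            "posterior is prior-dominated",
            UserWarning,
            stacklevel=2,
        )
    p_prior = priors.p if isinstance(priors.p, BetaPrior) else priors.p[0]
    se_prior = priors.se if isinstance(priors.se, BetaPrior) else priors.se[0]
    sp_prior = priors.sp if isinstance(priors.sp, BetaPrior) else priors.sp[0]
    if p_draws is None:
        p_draws = gen.beta(counts.d + p_prior.shape1, counts.nd + p_prior.shape2, size=m)
    se = gen.beta(counts.tp + se_prior.shape1, counts.fn + se_prior.shape2, size=m)
    sp = gen.beta(counts.tn + sp_prior.shape1, counts.fp + sp_prior.shape2, size=m)
    return BinaryPosteriorDraws(
        p=np.asarray(p_draws), se=se, sp=sp, threshold=counts.threshold, strategy=strategy
    )


def net_benefit_binary(draws: BinaryPosteriorDraws, t: float) -> np.ndarray:
    """Draw-wise net benefit NB = Se*p - (1-Sp)*(1-p)*w_t at threshold t."""
    if not 0 <= t < 1:
        raise ValidationError(f"threshold {t} outside [0, 1)")
    w = t / (1.0 - t)
    return draws.se * draws.p - (1.0 - draws.sp) * (1.0 - draws.p) * w


def net_benefit_treat_all_binary(p_draws: np.ndarray, t: float) -> np.ndarray:
    """Treat-all net benefit NB = p - (1-p)*w_t per prevalence draw.

    Treat-none is identically zero and needs no sampling.
    """
    if not 0 <= t < 1:
        raise ValidationError(f"threshold {t} outside [0, 1)")
    w = t / (1.0 - t)
    p = np.asarray(p_draws)
    return p - (1.0 - p) * w


def dca_binary(
    data: BinaryValidationData,
    grid: ThresholdGrid | None = None,
    priors: BinaryPriors | None = None,
    m: int = 4000,
    seed: int | None = None,
    external_prevalence: tuple[int, int] | None = None,
    strategies: Sequence[str] | None = None,
) -> DecisionCurveSet:
    """Full Bayesian decision curve analysis for a binary outcome.

    Returns a :class:`DecisionCurveSet` holding index-aligned net-benefit
    draws for every strategy (plus Treat-all and Treat-none) at every grid
    threshold.  A single prevalence sample is shared across all strategies
    and thresholds; pass ``external_prevalence=(cases, noncases)`` to replace
    it with a posterior built from external population data.
    """
    grid = grid or make_threshold_grid()
    priors = priors or BinaryPriors()
    strategies = list(strategies) if strategies is not None else data.strategies
    rng = np.random.default_rng(seed)

    p_prior = priors.p
    if external_prevalence is not None:
        cases, noncases = external_prevalence
        p_draws = sample_prevalence_external(cases, noncases, p_prior, m, rng)
    else:
        p_draws = rng.beta(
            data.n_events + p_prior.shape1,
            data.n - data.n_events + p_prior.shape2,
            size=m,
        )

    names = strategies + [TREAT_ALL, TREAT_NONE]
    nb = np.zeros((len(names), len(grid), m))
    flags = np.zeros((len(names), len(grid)), dtype=bool)
    weights = grid.weights
    for j, t in enumerate(grid):
        nb[len(strategies), j] = p_draws - (1.0 - p_draws) * weights[j]
    for i, name in enumerate(strategies):
        for j, t in enumerate(grid):
            counts = tabulate_counts(data, name, t)
            if counts.tp + counts.fp == 0:
                flags[i, j] = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                draws = sample_binary_posterior(
                    counts,
                    BinaryPriors(p=p_prior, se=priors.at("se", j), sp=priors.at("sp", j)),
                    m,
                    rng,
                    strategy=name,
                    p_draws=p_draws,
                )
            nb[i, j] = net_benefit_binary(draws, t)
    if flags.any():
        n_flagged = int(flags.sum())
        warnings.warn(
            f"{n_flagged} strategy/threshold cell(s) had no positive predictions; "
            "their posteriors are prior-dominated",
            UserWarning,
            stacklevel=2,
        )
    return DecisionCurveSet(
        strategies=names, nb_draws=nb, grid=grid, zero_positive_flags=flags
    )
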