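"""Posterior interrogation of decision curves.

Given index-aligned net-benefit draws for a set of decision strategies, the
posterior can be queried for the quantities that actually drive the decision:

* ``p_useful`` — P(NB_strategy > max{NB_treat-all, NB_treat-none}), the
  probability the strategy beats both default policies;
* ``p_best`` — P(NB_strategy > NB of every other strategy considered);
* ``pairwise_superiority`` — P(NB_1 - NB_2 > c) for a margin c >= 0
  (c > 0 accommodates differential test harms);
* ``evpi`` — E[max_s NB_s] - max_s E[NB_s], the expected net-benefit loss
  from deciding under current uncertainty (Expected Value of Perfect
  Information for validation).

All comparisons are strict and computed draw-wise on index-aligned draws:
strategies share the same underlying parameter draws (notably prevalence),
so the correlation structure of the joint posterior is preserved.  Ties
count as non-wins; posteriors are continuous, so ties are null events except
in the degenerate identical-strategy case, where strictness gives 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TREAT_ALL",
    "TREAT_NONE",
    "DecisionCurveSet",
    "InterrogationResult",
    "summarize_curves",
    "p_useful",
    "p_best",
    "pairwise_superiority",
    "evpi",
    "interrogate",
]

TREAT_ALL = "treat_all"
TREAT_NONE = "treat_none"
DEFAULT_STRATEGIES = (TREAT_ALL, TREAT_NONE)


@dataclass(frozen=True)
class DecisionCurveSet:
    """Net-benefit draws indexed [strategy, threshold, draw].

    Always includes the Treat-all and Treat-none rows; the Treat-none row is
    identically zero.  Draws are index-aligned across strategies and
    thresholds (shared parameter draws), which is what makes the draw-wise
    comparisons below meaningful.
    """

    strategies: list[str]
    nb_draws: np.ndarray
    grid: "ThresholdGrid"  # noqa: F821 - imported lazily to avoid a cycle
    zero_positive_flags: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        nb = np.asarray(self.nb_draws, dtype=float)
        if nb.ndim != 3:
            raise ValueError("nb_draws must have shape (strategy, threshold, draw)")
        if nb.shape[0] != len(self.strategies):
            raise ValueError("first axis must match the number of strategies")
        if nb.shape[1] != len(self.grid):
            raise ValueError("second axis must match the threshold grid")
        for name in DEFAULT_STRATEGIES:
            if name not in self.strategies:
                raise ValueError(f"strategy set must include {name!r}")
        if np.any(nb[self.strategies.index(TREAT_NONE)] != 0):
            raise ValueError("treat_none draws must be identically zero")
        object.__setattr__(self, "nb_draws", nb)
        object.__setattr__(self, "strategies", list(self.strategies))

    @property
    def m(self) -> int:
        return self.nb_draws.shape[2]

    @property
    def models(self) -> list[str]:
        return [s for s in self.strategies if s not in DEFAULT_STRATEGIES]

    def index(self, strategy: str) -> int:
        try:
            return self.strategies.index(strategy)
        except ValueError:
            raise KeyError(f"unknown strategy {strategy!r}") from None

    def draws(self, strategy: str, t: float) -> np.ndarray:
        return self.nb_draws[self.index(strategy), self.grid.index_of(t)]


@dataclass(frozen=True)
class InterrogationResult:
    """Tidy per-(threshold, strategy) interrogation summaries."""

    table: pd.DataFrame
    margin: float = 0.0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path=None) -> str | None:
        payload = {
            "margin": self.margin,
            "records": json.loads(self.table.to_json(orient="records")),
        }
        text = json.dumps(payload, indent=1)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def summarize_curves(
    curves: DecisionCurveSet, levels: tuple[float, float] = (2.5, 97.5)
) -> pd.DataFrame:
    """Posterior mean and percentile credible bounds per strategy/threshold."""
    if curves.m < 2:
        raise ValueError("need at least 2 draws to summarize")
    lo, hi = np.percentile(curves.nb_draws, levels, axis=2)
    mean = curves.nb_draws.mean(axis=2)
    records = []
    for i, name in enumerate(curves.strategies):
        for j, t in enumerate(curves.grid):
            records.append(
                {
                    "threshold": float(t),
                    "strategy": name,
                    "nb_mean": mean[i, j],
                    "nb_lo": lo[i, j],
                    "nb_hi": hi[i, j],
                }
            )
    return pd.DataFrame.from_records(records)


def p_useful(curves: DecisionCurveSet, strategy: str, t: float) -> float:
    """Posterior probability the strategy beats both default policies at t."""
    if strategy in DEFAULT_STRATEGIES:
        raise ValueError("p_useful is defined for model/test strategies only")
    nb = curves.draws(strategy, t)
    nb_all = curves.draws(TREAT_ALL, t)
    return float(np.mean(nb > np.maximum(nb_all, 0.0)))


def p_best(curves: DecisionCurveSet, strategy: str, t: float) -> float:
    """Posterior probability the strategy strictly beats every other one at t."""
    i = curves.index(strategy)
    j = curves.grid.index_of(t)
    others = np.delete(curves.nb_draws[:, j, :], i, axis=0)
    return float(np.mean(curves.nb_draws[i, j] > others.max(axis=0)))


def pairwise_superiority(
    curves: DecisionCurveSet, s1: str, s2: str, t: float, c: float = 0.0
) -> tuple[float, np.ndarray]:
    """P(NB_s1 - NB_s2 > c) and the per-draw difference vector at t."""
    if c < 0:
        raise ValueError("margin c must be non-negative")
    if s1 == s2:
        raise ValueError("pairwise comparison requires two distinct strategies")
    delta = curves.draws(s1, t) - curves.draws(s2, t)
    return float(np.mean(delta > c)), delta


def evpi(curves: DecisionCurveSet, t: float) -> float:
    """Expected Value of Perfect Information at threshold t.

    E_max averages the per-draw maximum over strategies; maxE is the best
    posterior-mean net benefit.  Their difference is the expected loss (in
    net true positives per patient) from committing to the apparent best
    strategy under current uncertainty; it is non-negative by Jensen.
    """
    j = curves.grid.index_of(t)
    nb = curves.nb_draws[:, j, :]
    e_max = float(nb.max(axis=0).mean())
    max_e = float(nb.mean(axis=1).max())
    return e_max - max_e


def evpi_curve(curves: DecisionCurveSet) -> pd.DataFrame:
    """EVPI at every grid threshold."""
    values = [evpi(curves, float(t)) for t in curves.grid]
    return pd.DataFrame({"threshold": curves.grid.thresholds, "evpi": values})


def interrogate(
    curves: DecisionCurveSet,
    margin: float = 0.0,
    levels: tuple[float, float] = (2.5, 97.5),
) -> InterrogationResult:
    """Full interrogation table: intervals, P(useful), P(best), deltas, EVPI.

    ``delta_*`` columns summarize the draw-wise difference between each
    strategy and its best competitor (the per-draw maximum over all other
    strategies), so P(best) equals P(delta > margin) when margin = 0.
    """
    records = []
    flags = curves.zero_positive_flags
    for j, t in enumerate(curves.grid):
        nb_t = curves.nb_draws[:, j, :]
        evpi_t = evpi(curves, float(t))
        for i, name in enumerate(curves.strategies):
            draws = nb_t[i]
            others = np.delete(nb_t, i, axis=0).max(axis=0)
            delta = draws - others
            rec = {
                "threshold": float(t),
                "strategy": name,
                "nb_mean": float(draws.mean()),
                "nb_lo": float(np.percentile(draws, levels[0])),
                "nb_hi": float(np.percentile(draws, levels[1])),
                "p_useful": (
                    p_useful(curves, name, float(t))
                    if name not in DEFAULT_STRATEGIES
                    else np.nan
                ),
                "p_best": float(np.mean(delta > margin)),
                "delta_mean": float(delta.mean()),
                "delta_lo": float(np.percentile(delta, levels[0])),
                "delta_hi": float(np.percentile(delta, levels[1])),
                "evpi": evpi_t,
                "zero_positives": bool(flags[i, j]) if flags is not None else False,
            }
            records.append(rec)
    return InterrogationResult(table=pd.DataFrame.from_records(records), margin=margin)
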