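"""Validation-data containers, threshold grids, and per-threshold tabulation.

Decision curve analysis evaluates decision strategies over a grid of decision
thresholds ``t``: a patient is treated when their predicted risk exceeds ``t``.
Every posterior model downstream consumes only the sufficient statistics
tabulated here — diagnostic 2x2 counts for binary outcomes, and the positive
set (with its survival data) for time-to-event outcomes.

Positivity uses the strict rule ``prediction > t``: a tie at the threshold
counts as negative.  This makes a binary 0/1 test positive for every
t in (0, 1) and keeps the weight w_t = t/(1-t) finite on the whole grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdGrid",
    "BinaryValidationData",
    "SurvivalValidationData",
    "DiagnosticCounts",
    "SurvivalSubset",
    "ValidationError",
    "make_threshold_grid",
    "read_validation_csv",
    "tabulate_counts",
    "tabulate_survival",
]

RESERVED_BINARY = ("outcome",)
RESERVED_SURVIVAL = ("time", "event")


class ValidationError(ValueError):
    """Raised when input data violate the container invariants."""


@dataclass(frozen=True)
class ThresholdGrid:
    """Ordered decision thresholds t in [0, 1) with weights w_t = t/(1-t).

    The weight w_t is the relative cost of a false positive implied by
    treating at threshold t; it is 0 at t = 0 and strictly increasing.
    """

    thresholds: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValidationError("threshold grid must be a non-empty 1-D sequence")
        if np.any(t < 0) or np.any(t >= 1):
            raise ValidationError("thresholds must lie in [0, 1); w_t is undefined at t = 1")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", t)

    @property
    def weights(self) -> np.ndarray:
        t = self.thresholds
        return t / (1.0 - t)

    def __len__(self) -> int:
        return self.thresholds.size

    def __iter__(self):
        return iter(self.thresholds)

    def index_of(self, t: float, atol: float = 1e-9) -> int:
        """Index of threshold ``t`` in the grid (tolerant float match)."""
        idx = int(np.argmin(np.abs(self.thresholds - t)))
        if abs(self.thresholds[idx] - t) > atol:
            raise KeyError(f"threshold {t} is not on the grid")
        return idx


def make_threshold_grid(
    values: Sequence[float] | None = None,
    *,
    start: float = 0.0,
    stop: float = 0.5,
    step: float = 0.01,
) -> ThresholdGrid:
    """Build a threshold grid from an explicit list or a {start, stop, step} spec.

    The default grid spans 0.00-0.50 in steps of 0.01: thresholds above 50%
    imply false positives cost more than false negatives, which is rarely the
    regime of interest for the conditions these analyses target.  Duplicates
    are dropped and values sorted.
    """
    if values is not None:
        t = np.unique(np.asarray(list(values), dtype=float))
    else:
        if step <= 0:
            raise ValidationError("step must be positive")
        if start > stop:
            raise ValidationError("start must not exceed stop")
        n = int(np.floor((stop - start) / step + 1e-9)) + 1
        # round away float accumulation so 0.05 + 2*0.05 is exactly 0.15
        t = np.round(start + step * np.arange(n), 12)
    return ThresholdGrid(t)


def _as_binary_indicator(values: np.ndarray, column: str) -> np.ndarray:
    arr = np.asarray(values)
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        rows = np.flatnonzero(bad)[:5].tolist()
        raise ValidationError(
            f"column {column!r} must contain only 0/1; offending rows {rows}"
        )
    return arr.astype(np.int8)


def _check_unit_interval(values: np.ndarray, column: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    bad = (arr < 0) | (arr > 1) | ~np.isfinite(arr)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"column {column!r} row {row}: prediction {arr[row]!r} outside [0, 1]"
        )
    return arr


@dataclass(frozen=True)
class BinaryValidationData:
    """Patient-level validation data for a binary (diagnostic) outcome.

    ``outcome`` holds the 0/1 disease indicators and ``predictions`` maps each
    strategy name to predicted risks in [0, 1] (or 0/1 for binary tests).
    """

    outcome: np.ndarray
    predictions: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        y = _as_binary_indicator(np.asarray(self.outcome), "outcome")
        if y.size == 0:
            raise ValidationError("outcome must be non-empty")
        preds = {}
        for name, p in dict(self.predictions).items():
            arr = _check_unit_interval(np.asarray(p), name)
            if arr.shape != y.shape:
                raise ValidationError(
                    f"strategy {name!r} has length {arr.size}, expected {y.size}"
                )
            preds[name] = arr
        if not preds:
            raise ValidationError("at least one strategy column is required")
        object.__setattr__(self, "outcome", y)
        object.__setattr__(self, "predictions", preds)

    @property
    def n(self) -> int:
        return int(self.outcome.size)

    @property
    def n_events(self) -> int:
        return int(self.outcome.sum())

    @property
    def strategies(self) -> list[str]:
        return list(self.predictions)


@dataclass(frozen=True)
class SurvivalValidationData:
    """Patient-level validation data for a survival (prognostic) outcome.

    ``event`` is 1 when the event was observed and 0 when the follow-up time
    is right-censored.  ``predictions`` hold each strategy's predicted risk of
    the event by the horizon tau, in the same time unit as ``time``.
    """

    time: np.ndarray
    event: np.ndarray
    predictions: Mapping[str, np.ndarray]
    horizon: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValidationError("time must be a non-empty 1-D sequence")
        if np.any(t <= 0) or np.any(~np.isfinite(t)):
            row = int(np.flatnonzero((t <= 0) | ~np.isfinite(t))[0])
            raise ValidationError(f"column 'time' row {row}: time must be positive")
        e = _as_binary_indicator(np.asarray(self.event), "event")
        if e.shape != t.shape:
            raise ValidationError("time and event must share one length")
        if not self.horizon or self.horizon <= 0:
            raise ValidationError("prediction horizon must be a positive time")
        preds = {}
        for name, p in dict(self.predictions).items():
            arr = _check_unit_interval(np.asarray(p), name)
            if arr.shape != t.shape:
                raise ValidationError(
                    f"strategy {name!r} has length {arr.size}, expected {t.size}"
                )
            preds[name] = arr
        if not preds:
            raise ValidationError("at least one strategy column is required")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        object.__setattr__(self, "predictions", preds)
        object.__setattr__(self, "horizon", float(self.horizon))

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def strategies(self) -> list[str]:
        return list(self.predictions)


@dataclass(frozen=True)
class DiagnosticCounts:
    """Per-threshold 2x2 table plus the case/non-case margins.

    These are the sufficient statistics of the conjugate Beta-Bernoulli model:
    prevalence sees (d, nd), sensitivity sees (tp, fn), specificity (tn, fp).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(f"{name} must be a non-negative integer")

    @property
    def d(self) -> int:
        return self.tp + self.fn

    @property
    def nd(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.d + self.nd


@dataclass(frozen=True)
class SurvivalSubset:
    """Positive-prediction subset feeding the conditional Weibull model."""

    n_pos: int
    n: int
    times: np.ndarray
    events: np.ndarray
    threshold: float
    empty: bool = field(default=False)


def read_validation_csv(
    path,
    schema: str = "binary",
    horizon: float | None = None,
    strategies: Sequence[str] | None = None,
) -> BinaryValidationData | SurvivalValidationData:
    """Read a validation dataset from a headered CSV file.

    Binary schema expects columns ``outcome, <strategy>, ...``; survival
    schema ``time, event, <strategy>, ...`` plus an explicit ``horizon``.
    Rows with missing values are rejected (complete-case data are required
    for the sufficient statistics to be well defined) and their indices
    reported.
    """
    df = pd.read_csv(path)
    if schema not in ("binary", "survival"):
        raise ValidationError(f"unknown schema {schema!r}")
    reserved = RESERVED_BINARY if schema == "binary" else RESERVED_SURVIVAL
    missing_cols = [c for c in reserved if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing required column(s) {missing_cols}")
    strategy_cols = [c for c in df.columns if c not in reserved]
    if strategies is not None:
        unknown = [s for s in strategies if s not in strategy_cols]
        if unknown:
            raise ValidationError(f"{path}: unknown strategy column(s) {unknown}")
        strategy_cols = list(strategies)
    na_rows = df[df[list(reserved) + strategy_cols].isna().any(axis=1)].index.tolist()
    if na_rows:
        raise ValidationError(
            f"{path}: missing values in rows {na_rows[:10]}"
            + ("..." if len(na_rows) > 10 else "")
        )
    preds = {c: df[c].to_numpy() for c in strategy_cols}
    if schema == "binary":
        return BinaryValidationData(outcome=df["outcome"].to_numpy(), predictions=preds)
    if horizon is None:
        raise ValidationError("survival schema requires an explicit horizon")
    return SurvivalValidationData(
        time=df["time"].to_numpy(),
        event=df["event"].to_numpy(),
        predictions=preds,
        horizon=horizon,
    )


def _positives(predictions: np.ndarray, t: float) -> np.ndarray:
    # strict inequality: ties at the threshold are negative
    return predictions > t


def tabulate_counts(
    data: BinaryValidationData, strategy: str, t: float
) -> DiagnosticCounts:
    """Tabulate the diagnostic 2x2 table for one strategy at threshold ``t``."""
    if not 0 <= t < 1:
        raise ValidationError(f"threshold {t} outside [0, 1)")
    if strategy not in data.predictions:
        raise KeyError(f"unknown strategy {strategy!r}")
    z = _positives(data.predictions[strategy], t)
    d = data.outcome.astype(bool)
    return DiagnosticCounts(
        tp=int(np.sum(d & z)),
        fn=int(np.sum(d & ~z)),
        fp=int(np.sum(~d & z)),
        tn=int(np.sum(~d & ~z)),
        threshold=float(t),
    )


def tabulate_survival(
    data: SurvivalValidationData, strategy: str, t: float
) -> SurvivalSubset:
    """Select the positive-prediction patients for one strategy at ``t``.

    A non-fatal warning is raised when no prediction exceeds the threshold;
    downstream models then fall back to prior-only draws.
    """
    if not 0 <= t < 1:
        raise ValidationError(f"threshold {t} outside [0, 1)")
    if strategy not in data.predictions:
        raise KeyError(f"unknown strategy {strategy!r}")
    z = _positives(data.predictions[strategy], t)
    n_pos = int(z.sum())
    empty = n_pos == 0
    if empty:
        warnings.warn(
            f"no predictions above threshold {t:.3g} for strategy {strategy!r}; "
            "posterior will be prior-dominated",
            UserWarning,
            stacklevel=2,
        )
    return SurvivalSubset(
        n_pos=n_pos,
        n=data.n,
        times=data.time[z],
        events=data.event[z],
        threshold=float(t),
        empty=empty,
    )
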