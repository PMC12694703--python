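"""Joint distribution of sequentially-monitored score statistics.

A group-sequential trial observed at looks ``k = 1..K`` yields score
statistics ``S_k`` with Fisher information ``I_k`` for each endpoint.  Under
the canonical asymptotic model the stacked vector

    (S_1^A, ..., S_K^A, S_1^B, ..., S_K^B)

is multivariate normal with mean ``(theta_A I_k^A, ..., theta_B I_k^B, ...)``
and covariance ``Cov(S_j^X, S_k^X) = I_min(j,k)^X`` within an endpoint and
``Cov(S_j^A, S_k^B) = rho * sqrt(I_min^A I_min^B)`` across endpoints, where
``rho`` is the correlation between same-look statistics.

Stopping and rejection events are conjunctions of one-sided threshold
conditions on individual ``(process, look)`` statistics; this module
represents them (:class:`EventSpec`) and computes their probabilities as
standardized-scale rectangle probabilities, including the ``theta_A -> +-inf``
limits needed by the endpoint-switch boundary construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .mvnorm import DEFAULT_POINTS, DEFAULT_SEED, rect_prob

__all__ = [
    "Condition",
    "EventSpec",
    "EffectPair",
    "InformationSchedule",
    "build_covariance",
    "mean_vector",
    "event_probability",
]

Process = Literal["A", "B"]
Direction = Literal["below", "at_or_above"]

RHO_CLIP = 0.999


@dataclass(frozen=True)
class Condition:
    """One-sided threshold condition on a single (process, look) statistic.

    ``threshold`` is on the score-statistic scale.  A ``below`` condition
    with threshold ``+inf`` is vacuous and dropped by :class:`EventSpec`.
    """

    process: Process
    look: int
    direction: Direction
    threshold: float

    def __post_init__(self):
        if self.process not in ("A", "B"):
            raise ValueError(f"unknown process {self.process!r}")
        if self.direction not in ("below", "at_or_above"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.look < 1:
            raise ValueError("look indices are 1-based")
        if math.isnan(self.threshold):
            raise ValueError("threshold must not be NaN")


@dataclass(frozen=True)
class EventSpec:
    """Conjunction of :class:`Condition` terms (an intersection event)."""

    conditions: tuple[Condition, ...]
    impossible: bool

    def __init__(self, conditions: Iterable[Condition]):
        conds = tuple(c for c in conditions
                      if not (c.direction == "below" and np.isposinf(c.threshold))
                      and not (c.direction == "at_or_above" and np.isneginf(c.threshold)))
        # a condition that can never hold makes the whole conjunction null
        impossible = any((c.direction == "below" and np.isneginf(c.threshold))
                         or (c.direction == "at_or_above" and np.isposinf(c.threshold))
                         for c in conds)
        seen = {}
        for c in conds:
            key = (c.process, c.look)
            if key in seen:
                raise ValueError(f"duplicate condition on {key}")
            seen[key] = c
        object.__setattr__(self, "conditions", conds)
        object.__setattr__(self, "impossible", impossible)

    def __len__(self):
        return len(self.conditions)

    @property
    def max_look(self) -> int:
        return max((c.look for c in self.conditions), default=0)


@dataclass(frozen=True)
class EffectPair:
    """Treatment effects on the two endpoints; ``theta_a`` may be ``+-inf``."""

    theta_a: float
    theta_b: float = 0.0

    def __post_init__(self):
        if not math.isfinite(self.theta_b):
            raise ValueError("theta_b must be finite")


@dataclass
class InformationSchedule:
    """Per-look information for both endpoints and their correlation."""

    info_a: np.ndarray
    info_b: np.ndarray
    rho: float

    def __post_init__(self):
        self.info_a = np.asarray(self.info_a, float)
        self.info_b = np.asarray(self.info_b, float)
        for name, info in (("info_a", self.info_a), ("info_b", self.info_b)):
            if np.any(info <= 0):
                raise ValueError(f"{name} must be strictly positive")
            if np.any(np.diff(info) < 0):
                raise ValueError(f"{name} must be nondecreasing across looks")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        # extreme correlations are clipped before matrix construction
        self.rho = float(np.clip(self.rho, -RHO_CLIP, RHO_CLIP))

    @property
    def n_looks(self) -> int:
        return len(self.info_a)

    def info(self, process: Process) -> np.ndarray:
        return self.info_a if process == "A" else self.info_b


def build_covariance(schedule: InformationSchedule) -> np.ndarray:
    """Score-scale covariance of ``(S_1^A..S_K^A, S_1^B..S_K^B)``."""
    ia, ib, rho = schedule.info_a, schedule.info_b, schedule.rho
    K = schedule.n_looks
    cov = np.empty((2 * K, 2 * K))
    cov[:K, :K] = np.minimum.outer(ia, ia)
    cov[K:, K:] = np.minimum.outer(ib, ib)
    m = np.minimum.outer(np.arange(K), np.arange(K))
    cross = rho * np.sqrt(ia[m] * ib[m])
    cov[:K, K:] = cross
    cov[K:, :K] = cross.T
    return cov


def mean_vector(schedule: InformationSchedule, effects: EffectPair) -> np.ndarray:
    """Score-scale mean of the stacked vector under ``effects`` (finite only)."""
    if not math.isfinite(effects.theta_a):
        raise ValueError("mean_vector requires a finite theta_a")
    return np.concatenate([effects.theta_a * schedule.info_a,
                           effects.theta_b * schedule.info_b])


def _condition_correlation(schedule: InformationSchedule,
                           conds: Sequence[Condition]) -> np.ndarray:
    """Correlation matrix of the standardized statistics named by ``conds``."""
    n = len(conds)
    R = np.eye(n)
    for i in range(n):
        ci = conds[i]
        Ii = schedule.info(ci.process)[ci.look - 1]
        for j in range(i + 1, n):
            cj = conds[j]
            Ij = schedule.info(cj.process)[cj.look - 1]
            m = min(ci.look, cj.look) - 1
            if ci.process == cj.process:
                info = schedule.info(ci.process)
                r = math.sqrt(info[m] / max(Ii, Ij))
                if Ii == Ij:  # duplicate-information guard
                    r = min(r, 1.0 - 1e-12)
            else:
                r = schedule.rho * math.sqrt(
                    schedule.info_a[m] * schedule.info_b[m] / (Ii * Ij))
            R[i, j] = R[j, i] = r
    return R


def _standardized_limits(schedule, conds, theta_a, theta_b):
    """Rectangle limits for a batch of finite theta_a values.

    Probabilities are computed on the standardized scale Z = S / sqrt(I);
    a condition ``S >= u`` at drift theta becomes ``Z - theta*sqrt(I) >=
    u/sqrt(I) - theta*sqrt(I)`` for the centred Z.
    """
    theta_a = np.atleast_1d(np.asarray(theta_a, float))
    B, n = len(theta_a), len(conds)
    lower = np.full((B, n), -np.inf)
    upper = np.full((B, n), np.inf)
    for i, c in enumerate(conds):
        sig = math.sqrt(schedule.info(c.process)[c.look - 1])
        mu = theta_a * sig if c.process == "A" else np.full(B, theta_b * sig)
        z = c.threshold / sig - mu
        if c.direction == "at_or_above":
            lower[:, i] = z
        else:
            upper[:, i] = z
    return lower, upper


def _limit_event(event: EventSpec, sign: int) -> EventSpec | None:
    """Event in the ``theta_a -> sign*inf`` limit.

    At ``+inf`` every ``at_or_above`` condition on A holds almost surely and
    every ``below`` condition on A fails almost surely (and conversely at
    ``-inf``).  Returns the reduced B-only event, or None if the event has
    probability zero in the limit.
    """
    if event.impossible:
        return None
    keep = []
    for c in event.conditions:
        if c.process == "B":
            keep.append(c)
        elif not np.isfinite(c.threshold) or \
                (sign > 0) == (c.direction == "below"):
            # an infinite-threshold A-condition kept by EventSpec is
            # impossible at any theta; finite ones fail on the wrong side
            return None
        # else: a.s. satisfied, drop
    return EventSpec(keep)


def _event_probability_batch(event: EventSpec, schedule: InformationSchedule,
                             theta_a, theta_b: float = 0.0, *,
                             n_points: int = DEFAULT_POINTS,
                             seed: int = DEFAULT_SEED) -> np.ndarray:
    """Vectorized event probability over an array of finite theta_a values."""
    conds = event.conditions
    theta_a = np.atleast_1d(np.asarray(theta_a, float))
    if event.impossible:
        return np.zeros(len(theta_a))
    if not conds:
        return np.ones(len(theta_a))
    if event.max_look > schedule.n_looks:
        raise ValueError("event references a look beyond the schedule")
    R = _condition_correlation(schedule, conds)
    lower, upper = _standardized_limits(schedule, conds, theta_a, theta_b)
    return np.atleast_1d(rect_prob(R, lower, upper, n_points=n_points, seed=seed))


def event_probability(event: EventSpec, schedule: InformationSchedule,
                      effects: EffectPair, *,
                      n_points: int = DEFAULT_POINTS,
                      seed: int = DEFAULT_SEED) -> float:
    """Probability of a conjunction event under the joint normal model.

    ``effects.theta_a = +-inf`` is evaluated by the limit rules: conditions
    on endpoint-A statistics become almost sure or null and the remaining
    B-only rectangle is evaluated at drift ``theta_b``.
    """
    if math.isfinite(effects.theta_a):
        return float(_event_probability_batch(
            event, schedule, effects.theta_a, effects.theta_b,
            n_points=n_points, seed=seed)[0])
    reduced = _limit_event(event, 1 if effects.theta_a > 0 else -1)
    if reduced is None:
        return 0.0
    return float(_event_probability_batch(
        reduced, schedule, 0.0, effects.theta_b,
        n_points=n_points, seed=seed)[0])
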