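"""Corrected critical values after an externally-driven endpoint switch.

A trial starts by monitoring endpoint A with an alpha-spending boundary.
At look ``k_switch`` (decided on external grounds) the primary endpoint
changes to endpoint B.  If the trial already stopped at some look
``k < k_switch`` with an endpoint-A rejection, the final analysis is a
single test of ``S_k^B``; otherwise monitoring continues on endpoint B.
The null hypothesis for B is rejected at look ``k`` on the events

    k < k_switch:  (no earlier A-crossing) & (S_k^A >= u_k^A) & (S_k^B >= u_k^B)
    k = k_switch:  (no A-crossing before k_switch) & (S_k^B >= u_k^B)
    k > k_switch:  (no A-crossing before k_switch) &
                   (S_r^B < u_r^B for k_switch <= r < k) & (S_k^B >= u_k^B)

Because the probability of these events depends on the unknown effect
``theta_A`` on the abandoned endpoint, the corrected critical values
``u_k^B`` equalize the *supremum over theta_A* of the cumulative null
rejection probability to the spent alpha at each look.  The supremum can be
attained at ``theta_A -> +-inf`` (evaluated analytically by the limit
rules) or at an interior point of either sign; it is located by a dense
grid plus local refinement, and each ``u_k^B`` is then found by Brent root
finding.  The construction controls the type I error for the test of the
new endpoint whatever the true effect on the original one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import norm

from .joint import (Condition, EffectPair, EventSpec, InformationSchedule,
                    _event_probability_batch, _limit_event, event_probability)
from .mvnorm import DEFAULT_POINTS, DEFAULT_SEED
from .spending import BoundarySet, SpendingFunction
from .whitehead import LookStatistics

__all__ = [
    "SwitchSpec",
    "BoundaryBRecord",
    "SwitchBoundary",
    "SwitchDecision",
    "rejection_event_B",
    "cumulative_rejection_B",
    "sup_theta_A",
    "boundary_B_at_look",
    "solve_switch_boundary",
    "analyze_switch_trial",
]

GRID_SIZE = 81


@dataclass
class SwitchSpec:
    """Design of the endpoint-B boundary construction.

    ``k_switch`` between 2 and K is the first look monitored on endpoint B;
    ``k_switch = K + 1`` encodes a post-trial switch (all looks A-monitored,
    single B test at an A-rejection look).  ``rho`` is the correlation
    between same-look score statistics; pass a sequence for per-look
    re-estimates, in which case the value at look ``k`` is used for every
    cross-term of that look's construction while earlier boundary values
    stay frozen as first computed.
    """

    k_switch: int
    boundary_a: BoundarySet
    info_b: np.ndarray
    imax_b: float
    spending_b: SpendingFunction
    rho: float | Sequence[float]

    def __post_init__(self):
        self.info_b = np.asarray(self.info_b, float)
        K = self.n_looks
        if self.k_switch < 2:
            raise ValueError("k_switch must be at least 2")
        n_a_needed = min(self.k_switch - 1, K)
        if self.boundary_a.n_looks < n_a_needed:
            raise ValueError("boundary_a must cover looks 1..k_switch-1")
        if self.imax_b <= 0:
            raise ValueError("imax_b must be positive")
        rho_arr = np.atleast_1d(np.asarray(self.rho, float))
        if rho_arr.size not in (1, K):
            raise ValueError("rho must be scalar or one value per look")

    @property
    def n_looks(self) -> int:
        return len(self.info_b)

    @property
    def times_b(self) -> np.ndarray:
        return np.minimum(self.info_b / self.imax_b, 1.0)

    def rho_at(self, look: int) -> float:
        rho_arr = np.atleast_1d(np.asarray(self.rho, float))
        return float(rho_arr[0] if rho_arr.size == 1 else rho_arr[look - 1])

    def schedule(self, look: int) -> InformationSchedule:
        """Joint information schedule using the rho in force at ``look``."""
        K = self.n_looks
        info_a = np.asarray(self.boundary_a.info, float)[:K]
        if len(info_a) < K:  # A-looks beyond the switch are never referenced
            info_a = np.append(info_a, np.full(K - len(info_a), info_a[-1]))
        return InformationSchedule(info_a=info_a, info_b=self.info_b,
                                   rho=self.rho_at(look))


@dataclass(frozen=True)
class BoundaryBRecord:
    """One look of the corrected endpoint-B boundary."""

    look: int
    u: float
    z: float
    theta_star: float  # maximizer of the cumulative rejection probability
    rho: float
    spent: float


@dataclass
class SwitchBoundary:
    """Solved endpoint-B boundary chain."""

    spec: SwitchSpec
    records: list[BoundaryBRecord]

    @property
    def u(self) -> np.ndarray:
        return np.array([r.u for r in self.records])

    @property
    def z(self) -> np.ndarray:
        return np.array([r.z for r in self.records])


@dataclass
class SwitchDecision:
    """Outcome of replaying a monitored trial through the switch design."""

    stop_look: int
    stopped_on: str          # "A", "B", or "end"
    reject_b: bool
    trace: list[dict] = field(default_factory=list)


def rejection_event_B(k: int, spec: SwitchSpec,
                      u_b: Sequence[float]) -> EventSpec:
    """Event of reaching look ``k`` and rejecting the endpoint-B null there.

    ``u_b`` must supply boundary values for looks up to ``k``.
    """
    if not 1 <= k <= spec.n_looks:
        raise ValueError("look outside the schedule")
    if len(u_b) < k:
        raise ValueError(f"u_b must cover looks 1..{k}")
    kt = spec.k_switch
    ua = spec.boundary_a.u
    conds: list[Condition] = []
    if k < kt:
        conds += [Condition("A", r, "below", ua[r - 1]) for r in range(1, k)]
        conds.append(Condition("A", k, "at_or_above", ua[k - 1]))
    else:
        conds += [Condition("A", r, "below", ua[r - 1]) for r in range(1, kt)]
        conds += [Condition("B", r, "below", u_b[r - 1]) for r in range(kt, k)]
    conds.append(Condition("B", k, "at_or_above", u_b[k - 1]))
    return EventSpec(conds)


def cumulative_rejection_B(k: int, u_b: Sequence[float], spec: SwitchSpec,
                           theta_a: float, *,
                           n_points: int = DEFAULT_POINTS,
                           seed: int = DEFAULT_SEED) -> float:
    """Null-of-B cumulative rejection probability through look ``k``.

    Sums ``P(R_r^B)`` for ``r <= k`` at treatment effect ``theta_a`` on the
    original endpoint (``+-inf`` allowed) and ``theta_b = 0``, with the
    correlation in force at look ``k`` in every cross-term.
    """
    schedule = spec.schedule(k)
    effects = EffectPair(theta_a=theta_a, theta_b=0.0)
    return sum(
        event_probability(rejection_event_B(r, spec, u_b), schedule, effects,
                          n_points=n_points, seed=seed)
        for r in range(1, k + 1))


def _theta_grid(spec: SwitchSpec, size: int = GRID_SIZE) -> np.ndarray:
    """Interior search grid for the supremum over theta_A.

    Outside ``|theta| > (z_1^A + 8) / sqrt(I_1^A)`` the first-look
    A-crossing probability is within ~1e-15 of its limit, so the objective
    has flattened onto the theta -> +-inf plateaus handled analytically.
    """
    i1 = spec.boundary_a.info[0]
    z1 = spec.boundary_a.u[0] / math.sqrt(i1)
    z1 = min(abs(z1), 10.0) if math.isfinite(z1) else 10.0
    c = (z1 + 8.0) / math.sqrt(i1)
    return np.linspace(-c, c, size)


def _cumulative_grid(k, u_b, schedule, spec, grid, *, n_points, seed):
    """Vector of cumulative rejection probabilities over a theta_A grid."""
    total = np.zeros(len(grid))
    for r in range(1, k + 1):
        total += _event_probability_batch(
            rejection_event_B(r, spec, u_b), schedule, grid,
            n_points=n_points, seed=seed)
    return total


def _limit_value(k, u_b, schedule, spec, sign, *, n_points, seed):
    """Cumulative rejection probability in the theta_A -> sign*inf limit."""
    total = 0.0
    for r in range(1, k + 1):
        reduced = _limit_event(rejection_event_B(r, spec, u_b), sign)
        if reduced is not None:
            total += float(_event_probability_batch(
                reduced, schedule, 0.0, n_points=n_points, seed=seed)[0])
    return total


def _parabolic_peak(grid, vals):
    """Interior maximum via a 3-point parabola around the grid argmax."""
    i = int(np.argmax(vals))
    if i in (0, len(grid) - 1):
        return float(grid[i]), float(vals[i])
    y0, y1, y2 = vals[i - 1], vals[i], vals[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= -1e-300:  # flat or non-concave triple; keep the grid point
        return float(grid[i]), float(vals[i])
    h = grid[1] - grid[0]
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    theta = float(grid[i] + delta * h)
    value = float(y1 - 0.25 * (y0 - y2) * delta)
    return theta, value


def sup_theta_A(k: int, u_b: Sequence[float], spec: SwitchSpec, *,
                n_points: int = DEFAULT_POINTS, seed: int = DEFAULT_SEED,
                refine: bool = True) -> tuple[float, float]:
    """Supremum over theta_A of the cumulative rejection probability.

    Evaluates the two infinite limits analytically, scans a dense interior
    grid, and (by default) polishes the interior maximizer with a bounded
    one-dimensional search.  Returns ``(theta_star, sup_value)`` with
    ``theta_star = +-inf`` when a limit strictly exceeds the best interior
    value.
    """
    grid = _theta_grid(spec)
    schedule = spec.schedule(k)
    vals = _cumulative_grid(k, u_b, schedule, spec, grid,
                            n_points=n_points, seed=seed)
    if refine:
        # polish around the grid argmax, comparing true function values only
        i = int(np.argmax(vals))
        theta_int, best_int = float(grid[i]), float(vals[i])
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda t: -cumulative_rejection_B(k, u_b, spec, t,
                                              n_points=n_points, seed=seed),
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-6})
        if -res.fun >= best_int:
            theta_int, best_int = float(res.x), float(-res.fun)
    else:
        theta_int, best_int = _parabolic_peak(grid, vals)
    lim_pos = _limit_value(k, u_b, schedule, spec, +1,
                           n_points=n_points, seed=seed)
    lim_neg = _limit_value(k, u_b, schedule, spec, -1,
                           n_points=n_points, seed=seed)
    best, theta = best_int, theta_int
    if lim_pos > best:
        best, theta = lim_pos, math.inf
    if lim_neg > best:
        best, theta = lim_neg, -math.inf
    return theta, best


def boundary_B_at_look(k: int, spec: SwitchSpec, u_prev: Sequence[float], *,
                       n_points: int = DEFAULT_POINTS, seed: int = DEFAULT_SEED,
                       refine: bool = True,
                       bracket: tuple[float, float] | None = None,
                       xtol: float | None = None) -> BoundaryBRecord:
    """Solve the corrected boundary value at look ``k``.

    ``u_prev`` holds the frozen values for looks ``1..k-1``.  The supremum
    of the cumulative rejection probability is nonincreasing in ``u_k``, so
    the spending equation has a unique crossing located by Brent's method.
    """
    if len(u_prev) < k - 1:
        raise ValueError("u_prev must cover looks 1..k-1")
    u_prev = list(u_prev[: k - 1])
    t_k = spec.times_b[k - 1]
    target = spec.spending_b(t_k)
    rho_k = spec.rho_at(k)
    sqrt_ib = math.sqrt(spec.info_b[k - 1])

    if k == 1:
        # the supremum is attained as theta_A -> +inf where only the
        # first-look event survives, giving a closed form
        u1 = norm.isf(target) * sqrt_ib
        return BoundaryBRecord(look=1, u=u1, z=u1 / sqrt_ib,
                               theta_star=math.inf, rho=rho_k, spent=target)

    grid = _theta_grid(spec)
    # only the look-k event depends on the candidate u_k: precompute the
    # earlier events' contribution on the grid and in the limits once
    base_vals = _cumulative_grid(k - 1, u_prev, spec.schedule(k), spec, grid,
                                 n_points=n_points, seed=seed)
    base_lim = {s: _limit_value(k - 1, u_prev, spec.schedule(k), spec, s,
                                n_points=n_points, seed=seed) for s in (1, -1)}
    schedule = spec.schedule(k)
    h = grid[1] - grid[0]

    def sup_value(u_k: float) -> float:
        u_b = u_prev + [u_k]
        ev = rejection_event_B(k, spec, u_b)
        vals = base_vals + _event_probability_batch(
            ev, schedule, grid, n_points=n_points, seed=seed)
        center, best = _parabolic_peak(grid, vals)
        if grid[0] < center < grid[-1]:
            # re-estimate the interior peak on a local fine grid: the
            # coarse 3-point parabola can overshoot a flat peak by ~1e-5
            fine = np.linspace(center - h, center + h, 9)
            fvals = _cumulative_grid(k, u_b, schedule, spec, fine,
                                     n_points=n_points, seed=seed)
            _, best = _parabolic_peak(fine, fvals)
        for s in (1, -1):
            reduced = _limit_event(ev, s)
            lim = base_lim[s]
            if reduced is not None:
                lim += float(_event_probability_batch(
                    reduced, schedule, 0.0, n_points=n_points, seed=seed)[0])
            best = max(best, lim)
        return best

    floor = sup_value(math.inf)
    if floor >= target - 1e-7:
        warnings.warn(
            f"look {k}: target spending {target:.6g} is not reachable "
            f"(floor {floor:.6g}); boundary set to +inf", stacklevel=2)
        return BoundaryBRecord(look=k, u=math.inf, z=math.inf,
                               theta_star=math.nan, rho=rho_k, spent=target)

    lo, hi = bracket if bracket is not None else (0.5 * sqrt_ib, 9.0 * sqrt_ib)
    f = lambda u: sup_value(u) - target
    flo, fhi = f(lo), f(hi)
    if flo < 0 or fhi > 0:  # widen a mis-specified warm bracket
        lo, hi = 0.0, 9.0 * sqrt_ib
    u_k = brentq(f, lo, hi, xtol=xtol if xtol is not None else 1e-6 * sqrt_ib)
    theta_star, _ = sup_theta_A(k, u_prev + [u_k], spec,
                                n_points=n_points, seed=seed, refine=refine)
    return BoundaryBRecord(look=k, u=u_k, z=u_k / sqrt_ib,
                           theta_star=theta_star, rho=rho_k, spent=target)


def solve_switch_boundary(spec: SwitchSpec, *, through_look: int | None = None,
                          n_points: int = DEFAULT_POINTS,
                          seed: int = DEFAULT_SEED,
                          refine: bool = True,
                          warm_u: Sequence[float] | None = None,
                          xtol: float | None = None) -> SwitchBoundary:
    """Solve the full endpoint-B boundary chain recursively.

    Earlier boundary values are frozen as computed; with per-look ``rho``
    each look's solve uses its own correlation in every cross-term.
    ``warm_u`` (e.g. a neighbouring chain) narrows the root brackets.
    """
    K = through_look or spec.n_looks
    records: list[BoundaryBRecord] = []
    u_sofar: list[float] = []
    for k in range(1, K + 1):
        bracket = None
        if warm_u is not None and len(warm_u) >= k and np.isfinite(warm_u[k - 1]):
            bracket = (warm_u[k - 1] - 0.2, warm_u[k - 1] + 0.2)
        rec = boundary_B_at_look(k, spec, u_sofar, n_points=n_points,
                                 seed=seed, refine=refine, bracket=bracket,
                                 xtol=xtol)
        records.append(rec)
        u_sofar.append(rec.u)
    return SwitchBoundary(spec=spec, records=records)


def analyze_switch_trial(stats_a: Sequence[LookStatistics],
                         stats_b: Sequence[LookStatistics],
                         spec: SwitchSpec, *,
                         boundary: SwitchBoundary | None = None,
                         n_points: int = DEFAULT_POINTS,
                         seed: int = DEFAULT_SEED) -> SwitchDecision:
    """Replay the monitoring path of an observed trial.

    Endpoint A is monitored at looks ``1..k_switch-1``; if the trial stops
    there with an A-rejection, a single test of ``S_k^B`` against ``u_k^B``
    decides the endpoint-B null.  Otherwise endpoint B is monitored from
    ``k_switch`` until a crossing or the final look.  Statistics must be
    supplied through the stop look.
    """
    if len(stats_a) != len(stats_b):
        raise ValueError("per-look statistics for A and B must align")
    if boundary is None:
        boundary = solve_switch_boundary(
            spec, through_look=len(stats_b), n_points=n_points, seed=seed)
    kt = spec.k_switch
    ua = spec.boundary_a.u
    ub = boundary.u
    trace: list[dict] = []
    n_avail = len(stats_a)

    for k in range(1, min(kt, n_avail + 1)):
        s = stats_a[k - 1].score
        crossed = s >= ua[k - 1]
        trace.append({"look": k, "process": "A", "statistic": s,
                      "threshold": float(ua[k - 1]), "crossed": bool(crossed)})
        if crossed:
            sb = stats_b[k - 1].score
            reject = sb >= ub[k - 1]
            trace.append({"look": k, "process": "B", "statistic": sb,
                          "threshold": float(ub[k - 1]),
                          "crossed": bool(reject)})
            return SwitchDecision(stop_look=k, stopped_on="A",
                                  reject_b=bool(reject), trace=trace)

    for k in range(kt, n_avail + 1):
        sb = stats_b[k - 1].score
        crossed = sb >= ub[k - 1]
        trace.append({"look": k, "process": "B", "statistic": sb,
                      "threshold": float(ub[k - 1]), "crossed": bool(crossed)})
        if crossed:
            return SwitchDecision(stop_look=k, stopped_on="B",
                                  reject_b=True, trace=trace)

    return SwitchDecision(stop_look=n_avail, stopped_on="end",
                          reject_b=False, trace=trace)
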