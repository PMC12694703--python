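"""Alpha-spending boundaries for a single sequentially-monitored endpoint.

An error-spending design allocates the one-sided type I error ``alpha``
across information time ``t = I / Imax`` through a nondecreasing spending
function ``alpha*(t)`` with ``alpha*(0) = 0`` and ``alpha*(1) = alpha``.
At each look the upper critical value ``u_k`` is chosen so that the
cumulative null probability of crossing at or before look ``k`` equals
``alpha*(t_k)``; the values are found recursively by one-dimensional
root-finding on multivariate-normal rectangle probabilities.

Also provided: the information level required for target power with
equally information-spaced looks, and the binary-endpoint sample size
implied by an information level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .mvnorm import DEFAULT_POINTS, DEFAULT_SEED, rect_prob

__all__ = [
    "SpendingFunction",
    "GroupSequentialDesign",
    "BoundarySet",
    "boundary_single_endpoint",
    "design_imax",
    "binary_sample_size",
]

# probability-scale tolerance of the boundary root-finds
SOLVER_TOL = 1e-8


@dataclass(frozen=True)
class SpendingFunction:
    """Spending function ``t -> alpha*(t)``; the default family is linear."""

    alpha: float
    family: str = "linear"
    evaluator: Callable[[float], float] | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.family == "custom":
            if self.evaluator is None:
                raise ValueError("custom spending needs an evaluator")
            grid = np.linspace(0, 1, 101)
            vals = np.array([self.evaluator(t) for t in grid])
            if abs(vals[0]) > 1e-12 or abs(vals[-1] - self.alpha) > 1e-12 \
                    or np.any(np.diff(vals) < -1e-12):
                raise ValueError("custom spending must be nondecreasing with "
                                 "alpha*(0)=0 and alpha*(1)=alpha")
        elif self.family != "linear":
            raise ValueError(f"unknown spending family {self.family!r}")

    def __call__(self, t: float) -> float:
        t = min(max(float(t), 0.0), 1.0)
        if self.family == "linear":
            return self.alpha * t
        return float(self.evaluator(t))


@dataclass
class GroupSequentialDesign:
    """Number of looks, spending function, and realized information."""

    spending: SpendingFunction
    imax: float
    info: np.ndarray

    def __post_init__(self):
        self.info = np.asarray(self.info, float)
        if self.imax <= 0:
            raise ValueError("imax must be positive")
        if np.any(self.info <= 0) or np.any(np.diff(self.info) < 0):
            raise ValueError("information must be positive and nondecreasing")

    @property
    def n_looks(self) -> int:
        return len(self.info)

    @property
    def times(self) -> np.ndarray:
        """Information times, capped at 1."""
        return np.minimum(self.info / self.imax, 1.0)


@dataclass
class BoundarySet:
    """Upper critical values on the score scale with their spent alpha."""

    info: np.ndarray
    u: np.ndarray
    spent: np.ndarray

    @property
    def z(self) -> np.ndarray:
        """Standardized boundary values u_k / sqrt(I_k)."""
        return self.u / np.sqrt(self.info)

    @property
    def n_looks(self) -> int:
        return len(self.u)


def _info_correlation(info: np.ndarray) -> np.ndarray:
    m = np.minimum.outer(info, info)
    M = np.maximum.outer(info, info)
    return np.sqrt(m / M)


def boundary_single_endpoint(design: GroupSequentialDesign, *,
                             n_points: int = DEFAULT_POINTS,
                             seed: int = DEFAULT_SEED) -> BoundarySet:
    """Recursive alpha-spending boundary for one endpoint.

    ``u_1 = Phi^{-1}(1 - alpha*(t_1)) sqrt(I_1)``; for ``k > 1`` the value
    ``u_k`` solves ``P_H0(cross at or before k) = alpha*(t_k)`` given the
    earlier values.  A look with no incremental spend gets ``u_k = +inf``.
    """
    t = design.times
    targets = np.array([design.spending(tk) for tk in t])
    if np.any(np.diff(targets) < -1e-12):
        raise ValueError("spent alpha must be nondecreasing across looks")
    info = design.info
    R = _info_correlation(info)
    z = np.empty(design.n_looks)
    z[0] = norm.isf(targets[0])
    for k in range(1, design.n_looks):
        if targets[k] <= targets[k - 1] + 1e-14:
            z[k] = np.inf
            continue

        def cum_cross(zk: float) -> float:
            bounds = np.append(z[:k], zk)
            p_all_below = rect_prob(R[: k + 1, : k + 1],
                                    np.full(k + 1, -np.inf), bounds,
                                    n_points=n_points, seed=seed)
            return (1.0 - p_all_below) - targets[k]

        z[k] = brentq(cum_cross, 0.0, 9.0, xtol=1e-8)
    u = z * np.sqrt(info)
    return BoundarySet(info=info.copy(), u=u, spent=targets)


def design_imax(alpha: float, power: float, theta: float, n_looks: int, *,
                spending: SpendingFunction | None = None,
                n_points: int = DEFAULT_POINTS,
                seed: int = DEFAULT_SEED) -> float:
    """Maximum information giving target power with equally-spaced looks.

    With looks at information fractions ``k / K`` the standardized boundary
    is scale-free, so the drift ``delta = theta * sqrt(Imax)`` attaining the
    target power is found by root-finding and ``Imax = (delta / theta)^2``.
    """
    if not 0 < alpha < power < 1:
        raise ValueError("need 0 < alpha < power < 1")
    if theta <= 0:
        raise ValueError("theta must be positive")
    spending = spending or SpendingFunction(alpha=alpha)
    frac = np.arange(1, n_looks + 1) / n_looks
    design = GroupSequentialDesign(spending=spending, imax=1.0, info=frac)
    zb = boundary_single_endpoint(design, n_points=n_points, seed=seed).z
    R = _info_correlation(frac)
    lo = np.full(n_looks, -np.inf)

    def power_at(delta: float) -> float:
        return 1.0 - rect_prob(R, lo, zb - delta * np.sqrt(frac),
                               n_points=n_points, seed=seed)

    delta = brentq(lambda d: power_at(d) - power, 0.01, 12.0, xtol=1e-8)
    return (delta / theta) ** 2


def binary_sample_size(imax: float, p_control: float, p_treated: float, *,
                       n_stages: int = 5) -> tuple[int, list[int]]:
    """Total sample size and per-arm stage sizes for a binary endpoint.

    ``N = 4 Imax / (pbar (1 - pbar))`` with ``pbar`` the average response
    rate; the per-arm per-stage size ``N / (2 K)`` is rounded by alternating
    floor/ceiling starting with floor, so near-half-integer stage sizes
    produce the conventional alternating pattern.
    """
    if not (0 < p_control < 1 and 0 < p_treated < 1):
        raise ValueError("response probabilities must lie in (0, 1)")
    pbar = 0.5 * (p_control + p_treated)
    n_raw = 4.0 * imax / (pbar * (1.0 - pbar))
    m = n_raw / (2 * n_stages)
    stages = [math.floor(m) if k % 2 == 0 else math.ceil(m)
              for k in range(n_stages)]
    total = 2 * sum(stages)
    return total, stages
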