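"""Estimating the correlation between the two endpoints' score statistics.

The corrected boundary needs ``rho = corr(S_k^A, S_k^B)``.  For normally
distributed endpoints this equals the within-treatment-group correlation
between the endpoints themselves, so a pooled within-arm Pearson estimate
is used directly.  For other endpoint types (binary, time-to-event) no such
identity holds and ``rho`` is estimated by a within-arm bootstrap: resample
subjects with replacement from each arm, recompute ``(S^A, S^B)`` on every
resample, and take the Pearson correlation of the replicate pairs.

Since assuming a larger correlation yields a more conservative test, an
optional Fisher-z upper confidence limit on the bootstrap estimate is
provided for deliberate use in place of the point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .whitehead import (TwoArmBinaryCounts, TwoArmContinuousData,
                        TwoArmSurvivalData, binary_score_information,
                        logrank_score_information, normal_score_information)

__all__ = [
    "PairedEndpointData",
    "pooled_within_group_correlation",
    "bootstrap_correlation",
]

RHO_CLIP = 0.999
_MAX_RETRIES = 100


@dataclass
class PairedEndpointData:
    """Per-subject paired observations on both endpoints, by arm.

    Endpoint columns are 1-D arrays for continuous or 0/1 binary outcomes,
    or 2-column arrays ``(time, event)`` for time-to-event outcomes; both
    endpoints must be observed for every subject.
    """

    control_a: np.ndarray
    control_b: np.ndarray
    treated_a: np.ndarray
    treated_b: np.ndarray

    def __post_init__(self):
        for name in ("control_a", "control_b", "treated_a", "treated_b"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if len(self.control_a) != len(self.control_b) or \
                len(self.treated_a) != len(self.treated_b):
            raise ValueError("endpoints must be paired within each arm")
        if len(self.control_a) < 2 or len(self.treated_a) < 2:
            raise ValueError("need >= 2 subjects per arm")


def pooled_within_group_correlation(data: PairedEndpointData) -> float:
    """Pooled within-arm Pearson correlation of two continuous endpoints.

    Each arm is centred at its own means before pooling, so constant arm
    effects on either endpoint leave the estimate unchanged.
    """
    num = 0.0
    ss_a = 0.0
    ss_b = 0.0
    for a, b in ((data.control_a, data.control_b),
                 (data.treated_a, data.treated_b)):
        if a.ndim != 1 or b.ndim != 1:
            raise ValueError("direct estimation requires continuous endpoints")
        da, db = a - a.mean(), b - b.mean()
        num += float(da @ db)
        ss_a += float(da @ da)
        ss_b += float(db @ db)
    if ss_a == 0.0 or ss_b == 0.0:
        raise ValueError("zero variance in an endpoint")
    rho = num / np.sqrt(ss_a * ss_b)
    return float(np.clip(rho, -RHO_CLIP, RHO_CLIP))


def _score(values: np.ndarray, other: np.ndarray, kind: str) -> tuple:
    """(S, I) of one endpoint from per-arm value arrays."""
    if kind == "binary":
        stat = binary_score_information(TwoArmBinaryCounts(
            successes_control=int(values.sum()), n_control=len(values),
            successes_treated=int(other.sum()), n_treated=len(other)))
    elif kind == "normal":
        stat = normal_score_information(
            TwoArmContinuousData(control=values, treated=other))
    elif kind == "survival":
        stat = logrank_score_information(TwoArmSurvivalData(
            time_control=values[:, 0], event_control=values[:, 1],
            time_treated=other[:, 0], event_treated=other[:, 1]))
    else:
        raise ValueError(f"unknown endpoint kind {kind!r}")
    return stat.score, stat.information


def bootstrap_correlation(data: PairedEndpointData, *,
                          endpoint_a: str = "binary",
                          endpoint_b: str = "survival",
                          replicates: int = 1000,
                          seed: int = 0,
                          upper_confidence: float | None = None) -> float:
    """Bootstrap estimate of ``corr(S^A, S^B)``.

    Subjects are resampled with replacement within each arm (arm sizes
    preserved); each resampled subject carries its paired observations, so
    the dependence between endpoints is retained.  Degenerate resamples
    (zero information on either endpoint) are redrawn up to a retry cap.
    With ``upper_confidence`` (e.g. 0.95) the Fisher-z upper confidence
    limit across replicates is returned instead of the point estimate.
    """
    if replicates < 200:
        raise ValueError("use at least 200 bootstrap replicates")
    rng = np.random.default_rng(seed)
    nc, nt = len(data.control_a), len(data.treated_a)
    pairs = np.empty((replicates, 2))
    for r in range(replicates):
        for attempt in range(_MAX_RETRIES + 1):
            ic = rng.integers(0, nc, size=nc)
            it = rng.integers(0, nt, size=nt)
            try:
                sa, ia = _score(data.control_a[ic], data.treated_a[it],
                                endpoint_a)
                sb, ib = _score(data.control_b[ic], data.treated_b[it],
                                endpoint_b)
            except ValueError:
                continue
            if ia > 0 and ib > 0:
                pairs[r] = sa, sb
                break
        else:
            raise ValueError("persistent degenerate bootstrap resamples")
    rho = float(np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1])
    rho = float(np.clip(rho, -RHO_CLIP, RHO_CLIP))
    if upper_confidence is not None:
        z = np.arctanh(rho) + norm.ppf(upper_confidence) / np.sqrt(replicates - 3)
        rho = float(np.clip(np.tanh(z), -RHO_CLIP, RHO_CLIP))
    return rho
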