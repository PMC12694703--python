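"""Efficient score statistics and Fisher information per endpoint type.

Sequential monitoring in this package works on the (S, I) scale: at each
look the treatment effect enters only through the score statistic ``S`` and
its Fisher information ``I``, with ``S ~ N(theta * I, I)`` asymptotically.
This module computes the standard two-arm (S, I) pairs:

binary endpoint
    effect parameter = log-odds ratio;
    ``S = s_T - n_T (s_C + s_T) / N`` and ``I = n_C n_T s f / N^3``
    with ``s`` total successes, ``f`` total failures, ``N = n_C + n_T``.

continuous (normal) endpoint
    effect parameter = standardized difference in means;
    ``I = n_C n_T / (n_C + n_T)`` and ``S = I (xbar_T - xbar_C) / sd_pooled``.

time-to-event endpoint
    effect parameter = (signed) log hazard ratio; ``S`` is the log-rank
    observed-minus-expected event count on the treated arm and ``I`` the sum
    of per-event-time hypergeometric variances.  For endpoints where events
    are beneficial (e.g. recovery) the natural sign already makes a positive
    ``S`` favour treatment; for harmful events set ``events_beneficial=False``
    to flip it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LookStatistics",
    "TwoArmBinaryCounts",
    "TwoArmContinuousData",
    "TwoArmSurvivalData",
    "binary_score_information",
    "normal_score_information",
    "logrank_score_information",
    "read_continuous_csv",
    "read_binary_csv",
    "read_survival_csv",
]


@dataclass(frozen=True)
class LookStatistics:
    """Score statistic and Fisher information at one look."""

    look: int
    score: float
    information: float

    def __post_init__(self):
        if self.information < 0:
            raise ValueError("information must be nonnegative")

    @property
    def effect_estimate(self) -> float:
        """S / I, the (asymptotically) natural effect estimate."""
        return self.score / self.information


@dataclass(frozen=True)
class TwoArmBinaryCounts:
    """Cumulative success counts at a look."""

    successes_control: int
    n_control: int
    successes_treated: int
    n_treated: int

    def __post_init__(self):
        if self.n_control < 1 or self.n_treated < 1:
            raise ValueError("both arms must contain at least one subject")
        if not 0 <= self.successes_control <= self.n_control:
            raise ValueError("control successes outside [0, n_control]")
        if not 0 <= self.successes_treated <= self.n_treated:
            raise ValueError("treated successes outside [0, n_treated]")


@dataclass
class TwoArmContinuousData:
    """Per-subject continuous observations, one array per arm."""

    control: np.ndarray
    treated: np.ndarray

    def __post_init__(self):
        self.control = np.asarray(self.control, float)
        self.treated = np.asarray(self.treated, float)
        if len(self.control) < 2 or len(self.treated) < 2:
            raise ValueError("need >= 2 subjects per arm for a pooled spread")


@dataclass
class TwoArmSurvivalData:
    """Per-subject follow-up times with event flags, one pair per arm."""

    time_control: np.ndarray
    event_control: np.ndarray
    time_treated: np.ndarray
    event_treated: np.ndarray

    def __post_init__(self):
        self.time_control = np.asarray(self.time_control, float)
        self.time_treated = np.asarray(self.time_treated, float)
        self.event_control = np.asarray(self.event_control, bool)
        self.event_treated = np.asarray(self.event_treated, bool)
        if np.any(self.time_control < 0) or np.any(self.time_treated < 0):
            raise ValueError("follow-up times must be nonnegative")
        if len(self.time_control) != len(self.event_control) or \
                len(self.time_treated) != len(self.event_treated):
            raise ValueError("time and event arrays must align")


def binary_score_information(counts: TwoArmBinaryCounts, *,
                             look: int = 1) -> LookStatistics:
    """(S, I) for the log-odds ratio from cumulative two-arm counts."""
    nc, nt = counts.n_control, counts.n_treated
    sc, st = counts.successes_control, counts.successes_treated
    N = nc + nt
    s = sc + st
    f = N - s
    score = st - nt * s / N
    info = nc * nt * s * f / N**3
    return LookStatistics(look=look, score=score, information=info)


def normal_score_information(data: TwoArmContinuousData, *,
                             look: int = 1) -> LookStatistics:
    """(S, I) for the standardized mean difference.

    The information depends only on the arm sizes; the pooled standard
    deviation uses the within-arm estimator with N - 2 denominator.
    """
    xc, xt = data.control, data.treated
    nc, nt = len(xc), len(xt)
    ssq = np.sum((xc - xc.mean()) ** 2) + np.sum((xt - xt.mean()) ** 2)
    sd = np.sqrt(ssq / (nc + nt - 2))
    if sd == 0:
        raise ValueError("pooled standard deviation is zero")
    info = nc * nt / (nc + nt)
    score = info * (xt.mean() - xc.mean()) / sd
    return LookStatistics(look=look, score=score, information=info)


def logrank_score_information(data: TwoArmSurvivalData, *,
                              events_beneficial: bool = True,
                              look: int = 1) -> LookStatistics:
    """Log-rank (S, I) from two-arm censored survival data.

    ``S`` is the treated-arm observed-minus-expected event count summed over
    distinct event times; ``I`` sums the hypergeometric variances
    ``d (n1 n2 / n^2) (n - d) / (n - 1)`` (read as ``n1 n2 / n^2`` when the
    risk set has a single subject).  Subjects censored at an event time are
    still at risk for that event.
    """
    times = np.concatenate([data.time_control, data.time_treated])
    events = np.concatenate([data.event_control, data.event_treated])
    treated = np.concatenate([np.zeros(len(data.time_control), bool),
                              np.ones(len(data.time_treated), bool)])
    if not events.any():
        raise ValueError("no events observed; log-rank statistic undefined")

    event_times = np.unique(times[events])
    sorted_all = np.sort(times)
    sorted_treated = np.sort(times[treated])
    n_total, n_treated = len(times), int(treated.sum())

    # at-risk counts: subjects with follow-up >= t (censoring ties at an
    # event time are processed after the event, hence side="left")
    n = n_total - np.searchsorted(sorted_all, event_times, side="left")
    n1 = n_treated - np.searchsorted(sorted_treated, event_times, side="left")
    d = np.searchsorted(np.sort(times[events]), event_times, side="right") - \
        np.searchsorted(np.sort(times[events]), event_times, side="left")
    t_events = np.sort(times[events & treated])
    d1 = np.searchsorted(t_events, event_times, side="right") - \
        np.searchsorted(t_events, event_times, side="left")

    score = float(np.sum(d1 - d * n1 / n))
    base = d * n1 * (n - n1) / n.astype(float)**2
    with np.errstate(invalid="ignore", divide="ignore"):
        tie_factor = np.where(n > 1, (n - d) / (n - 1.0), 1.0)
    info = float(np.sum(base * tie_factor))
    if not events_beneficial:
        score = -score
    return LookStatistics(look=look, score=score, information=info)


def read_continuous_csv(path, *, arm_col: str = "arm", value_col: str = "value",
                        treated_label="treated") -> TwoArmContinuousData:
    df = pd.read_csv(path)
    t = df[arm_col] == treated_label
    return TwoArmContinuousData(control=df.loc[~t, value_col].to_numpy(),
                                treated=df.loc[t, value_col].to_numpy())


def read_binary_csv(path, *, arm_col: str = "arm", success_col: str = "success",
                    treated_label="treated") -> TwoArmBinaryCounts:
    df = pd.read_csv(path)
    t = df[arm_col] == treated_label
    return TwoArmBinaryCounts(
        successes_control=int(df.loc[~t, success_col].sum()),
        n_control=int((~t).sum()),
        successes_treated=int(df.loc[t, success_col].sum()),
        n_treated=int(t.sum()),
    )


def read_survival_csv(path, *, arm_col: str = "arm", time_col: str = "time",
                      event_col: str = "event",
                      treated_label="treated") -> TwoArmSurvivalData:
    df = pd.read_csv(path)
    t = df[arm_col] == treated_label
    return TwoArmSurvivalData(
        time_control=df.loc[~t, time_col].to_numpy(),
        event_control=df.loc[~t, event_col].to_numpy().astype(bool),
        time_treated=df.loc[t, time_col].to_numpy(),
        event_treated=df.loc[t, event_col].to_numpy().astype(bool),
    )
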