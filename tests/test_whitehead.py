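"""Score statistic / information computations per endpoint type."""

import numpy as np
import pytest

from gsswitch import (TwoArmBinaryCounts, TwoArmContinuousData,
                      TwoArmSurvivalData, binary_score_information,
                      logrank_score_information, normal_score_information)
from .conftest import WORKED_COUNTS


@pytest.mark.parametrize("counts,expected_s,expected_i", [
    (WORKED_COUNTS[0], 8.5, 22.75),
    (WORKED_COUNTS[1], 14.5, 45.47),
    (WORKED_COUNTS[2], 25.0, 68.34),
])
def test_binary_worked_example_rows(counts, expected_s, expected_i):
    stat = binary_score_information(TwoArmBinaryCounts(*counts))
    assert stat.score == pytest.approx(expected_s, abs=0.005)
    assert stat.information == pytest.approx(expected_i, abs=0.005)


def test_binary_degenerate_and_symmetric_cases():
    equal = binary_score_information(TwoArmBinaryCounts(50, 100, 50, 100))
    assert equal.score == 0.0
    none = binary_score_information(TwoArmBinaryCounts(0, 100, 0, 100))
    assert none.information == 0.0
    allr = binary_score_information(TwoArmBinaryCounts(100, 100, 100, 100))
    assert allr.information == 0.0
    with pytest.raises(ValueError):
        TwoArmBinaryCounts(1, 0, 1, 10)
    with pytest.raises(ValueError):
        TwoArmBinaryCounts(11, 10, 1, 10)


def test_normal_information_depends_only_on_arm_sizes():
    rng = np.random.default_rng(0)
    data = TwoArmContinuousData(control=rng.normal(size=40),
                                treated=rng.normal(size=60))
    stat = normal_score_information(data)
    assert stat.information == pytest.approx(40 * 60 / 100)


def test_normal_zero_spread_and_identical_means():
    same = TwoArmContinuousData(control=[1.0, 2.0], treated=[2.0, 1.0])
    assert normal_score_information(same).score == pytest.approx(0.0)
    with pytest.raises(ValueError):
        normal_score_information(
            TwoArmContinuousData(control=[1.0, 1.0], treated=[1.0, 1.0]))


def test_normal_estimate_tracks_sample_standardized_difference():
    rng = np.random.default_rng(42)
    control = rng.normal(0.0, 1.0, size=500)
    treated = rng.normal(0.5, 1.0, size=500)
    stat = normal_score_information(
        TwoArmContinuousData(control=control, treated=treated))
    # oracle: standardized mean difference computed directly on the sample
    pooled = np.sqrt((np.var(control, ddof=1) * 499 +
                      np.var(treated, ddof=1) * 499) / 998)
    direct = (treated.mean() - control.mean()) / pooled
    assert stat.effect_estimate == pytest.approx(direct, abs=1e-12)
    assert stat.effect_estimate == pytest.approx(0.5, abs=0.1)


def test_logrank_single_risk_set():
    data = TwoArmSurvivalData(time_control=[2.0], event_control=[False],
                              time_treated=[1.0], event_treated=[True])
    stat = logrank_score_information(data)
    assert stat.score == pytest.approx(0.5)
    assert stat.information == pytest.approx(0.25)


def test_logrank_arm_relabel_flips_score():
    rng = np.random.default_rng(3)
    tc, tt = rng.exponential(1.0, 15), rng.exponential(0.7, 15)
    ec = rng.random(15) < 0.8
    et = rng.random(15) < 0.8
    a = logrank_score_information(TwoArmSurvivalData(tc, ec, tt, et))
    b = logrank_score_information(TwoArmSurvivalData(tt, et, tc, ec))
    assert a.score == pytest.approx(-b.score, abs=1e-12)
    assert a.information == pytest.approx(b.information, abs=1e-12)


def _logrank_oracle(time, event, arm):
    """Independent risk-set tabulation over distinct event times."""
    s = v = 0.0
    for t in sorted(set(time[event])):
        risk = time >= t
        n, n1 = risk.sum(), (risk & (arm == 1)).sum()
        dead = event & (time == t)
        d, d1 = dead.sum(), (dead & (arm == 1)).sum()
        s += d1 - d * n1 / n
        if n > 1:
            v += d * n1 * (n - n1) * (n - d) / (n**2 * (n - 1))
    return s, v


def test_logrank_matches_brute_force_tabulation():
    rng = np.random.default_rng(11)
    tc = np.round(rng.exponential(2.0, 10), 1)  # rounding induces ties
    tt = np.round(rng.exponential(1.2, 10), 1)
    ec = rng.random(10) < 0.7
    et = rng.random(10) < 0.7
    stat = logrank_score_information(TwoArmSurvivalData(tc, ec, tt, et))
    time = np.concatenate([tc, tt])
    event = np.concatenate([ec, et])
    arm = np.repeat([0, 1], 10)
    s, v = _logrank_oracle(time, event, arm)
    assert stat.score == pytest.approx(s, abs=1e-12)
    assert stat.information == pytest.approx(v, abs=1e-12)


def test_logrank_requires_events():
    with pytest.raises(ValueError):
        logrank_score_information(TwoArmSurvivalData(
            [1.0], [False], [2.0], [False]))


def test_information_monotone_in_nested_data():
    """Cumulative looks can only accumulate information, for all types."""
    rng = np.random.default_rng(21)
    xc, xt = rng.normal(size=300), rng.normal(0.2, 1, size=300)
    sc = rng.random(300) < 0.4
    st = rng.random(300) < 0.5
    tc, tt = rng.exponential(1, 300), rng.exponential(0.8, 300)
    ec = rng.random(300) < 0.9
    et = rng.random(300) < 0.9
    cuts = [60, 120, 200, 300]
    for stats in [
        [normal_score_information(TwoArmContinuousData(xc[:n], xt[:n]))
         for n in cuts],
        [binary_score_information(TwoArmBinaryCounts(
            int(sc[:n].sum()), n, int(st[:n].sum()), n)) for n in cuts],
        [logrank_score_information(TwoArmSurvivalData(
            tc[:n], ec[:n], tt[:n], et[:n])) for n in cuts],
    ]:
        info = [s.information for s in stats]
        assert np.all(np.diff(info) >= -1e-12)


def test_large_sample_consistency_all_types():
    """S / I converges to the canonical effect parameter at n = 5000."""
    rng = np.random.default_rng(8)
    n = 5000
    # binary: log-odds ratio
    pc, pt = 0.4, 0.55
    sc = int(rng.binomial(n, pc))
    st = int(rng.binomial(n, pt))
    b = binary_score_information(TwoArmBinaryCounts(sc, n, st, n))
    logor = np.log(pt / (1 - pt) / (pc / (1 - pc)))
    assert b.effect_estimate == pytest.approx(logor, abs=0.05)
    # normal: standardized mean difference
    g = normal_score_information(TwoArmContinuousData(
        rng.normal(0, 1, n), rng.normal(0.3, 1, n)))
    assert g.effect_estimate == pytest.approx(0.3, abs=0.05)
    # survival: log hazard ratio (uncensored exponential)
    hr = 1.3
    s = logrank_score_information(TwoArmSurvivalData(
        rng.exponential(1.0, n), np.ones(n, bool),
        rng.exponential(1 / hr, n), np.ones(n, bool)))
    assert s.effect_estimate == pytest.approx(np.log(hr), abs=0.05)
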