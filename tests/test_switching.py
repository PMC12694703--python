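"""Switch-boundary construction and trial analysis."""

import numpy as np
import pytest
from scipy.stats import norm

from gsswitch import (BoundarySet, Condition, LookStatistics,
                      GroupSequentialDesign, SpendingFunction, SwitchSpec,
                      analyze_switch_trial, boundary_single_endpoint,
                      cumulative_rejection_B, rejection_event_B,
                      solve_switch_boundary, sup_theta_A)
from .conftest import WORKED_INFO_B, WORKED_IMAX_B


def toy_spec(k_switch=2, rho=0.5, n_looks=4):
    info = 10.0 * np.arange(1, n_looks + 1)
    sp = SpendingFunction(alpha=0.025)
    ba = boundary_single_endpoint(GroupSequentialDesign(
        spending=sp, imax=info[-1], info=info), n_points=1 << 12)
    return SwitchSpec(k_switch=k_switch, boundary_a=ba, info_b=info,
                      imax_b=info[-1], spending_b=sp, rho=rho)


def _conds(ev):
    return [(c.process, c.look, c.direction) for c in ev.conditions]


def test_rejection_event_structure_before_switch():
    spec = toy_spec(k_switch=5, n_looks=4)
    ev = rejection_event_B(1, spec, [5.0])
    assert _conds(ev) == [("A", 1, "at_or_above"), ("B", 1, "at_or_above")]


def test_rejection_event_structure_at_switch():
    spec = toy_spec(k_switch=2)
    ev = rejection_event_B(2, spec, [5.0, 6.0])
    assert _conds(ev) == [("A", 1, "below"), ("B", 2, "at_or_above")]


def test_rejection_event_structure_after_switch():
    spec = toy_spec(k_switch=2)
    ev = rejection_event_B(4, spec, [5.0, 6.0, 7.0, 8.0])
    assert _conds(ev) == [("A", 1, "below"), ("B", 2, "below"),
                          ("B", 3, "below"), ("B", 4, "at_or_above")]
    assert ev.conditions[-1].threshold == 8.0


def test_rejection_event_requires_boundaries():
    spec = toy_spec()
    with pytest.raises(ValueError):
        rejection_event_B(3, spec, [5.0])
    with pytest.raises(ValueError):
        SwitchSpec(k_switch=1, boundary_a=spec.boundary_a,
                   info_b=spec.info_b, imax_b=spec.imax_b,
                   spending_b=spec.spending_b, rho=0.5)


def test_cumulative_rejection_limit_keeps_first_look_only():
    """As theta_A -> +inf the trial always stops at look 1, so only the
    first-look rejection term survives."""
    spec = toy_spec(k_switch=3, n_looks=4)
    u_b = [4.0, 6.0, 8.0]
    p1 = 1 - norm.cdf(u_b[0] / np.sqrt(spec.info_b[0]))
    for k in (1, 2, 3):
        p = cumulative_rejection_B(k, u_b, spec, np.inf)
        assert p == pytest.approx(p1, abs=1e-12)


def test_first_look_boundary_closed_form_and_rho_invariance():
    values = []
    for rho in (0.0, 0.3, 0.715):
        spec = toy_spec(rho=rho)
        chain = solve_switch_boundary(spec, through_look=1)
        values.append(chain.u[0])
    t1 = spec.info_b[0] / spec.imax_b
    closed = norm.isf(0.025 * t1) * np.sqrt(spec.info_b[0])
    np.testing.assert_allclose(values, closed, atol=1e-9)


def test_sup_dominates_dense_theta_scan():
    """The returned supremum beats the objective on a 50-point grid and at
    the two infinite limits."""
    spec = toy_spec(k_switch=2, rho=0.6)
    chain = solve_switch_boundary(spec, through_look=3, n_points=1 << 13)
    u_b = list(chain.u)
    theta_star, sup_val = sup_theta_A(3, u_b, spec, n_points=1 << 13)
    candidates = [cumulative_rejection_B(3, u_b, spec, t, n_points=1 << 13)
                  for t in np.linspace(-3, 3, 50)]
    candidates += [cumulative_rejection_B(3, u_b, spec, t, n_points=1 << 13)
                   for t in (np.inf, -np.inf)]
    assert sup_val >= max(candidates) - 2e-5


def test_unreachable_spending_returns_infinite_bound():
    spec = toy_spec(k_switch=2)
    # duplicate information at look 3 leaves no alpha to spend there
    spec.info_b = np.array([10.0, 20.0, 20.0, 40.0])
    chain_12 = solve_switch_boundary(spec, through_look=2, n_points=1 << 12)
    with pytest.warns(UserWarning, match="not reachable"):
        from gsswitch.switching import boundary_B_at_look
        rec = boundary_B_at_look(3, spec, list(chain_12.u),
                                 n_points=1 << 12)
    assert np.isinf(rec.u)


def test_rho_zero_with_unreachable_a_boundary_matches_plain_spending():
    """With rho = 0 and an endpoint-A boundary that can never be crossed,
    the switch construction collapses to ordinary sequential testing of B
    from the switch look on (there are no endpoint-B tests before it)."""
    info = 10.0 * np.arange(1, 5)
    sp = SpendingFunction(alpha=0.025)
    ba = BoundarySet(info=info, u=np.full(4, np.inf), spent=np.zeros(4))
    spec = SwitchSpec(k_switch=2, boundary_a=ba, info_b=info,
                      imax_b=info[-1], spending_b=sp, rho=0.0)
    chain = solve_switch_boundary(spec, n_points=1 << 14)
    plain = boundary_single_endpoint(GroupSequentialDesign(
        spending=sp, imax=info[-1], info=info[1:]), n_points=1 << 14)
    np.testing.assert_allclose(chain.u[1:], plain.u, atol=5e-3)


def test_analyze_stop_on_original_endpoint(worked_boundary_a,
                                           retrospective_chain):
    """Early stop on endpoint A at look 3, then a single decisive test of
    the new endpoint."""
    spec = retrospective_chain.spec
    stats_a = [LookStatistics(k + 1, s, i) for k, (s, i) in enumerate(
        zip([8.5, 14.5, 25.0], worked_boundary_a.info))]
    stats_b = [LookStatistics(k + 1, s, i) for k, (s, i) in enumerate(
        zip([1.60, 7.71, 23.13], WORKED_INFO_B[:3]))]
    d = analyze_switch_trial(stats_a, stats_b, spec,
                             boundary=retrospective_chain)
    assert (d.stop_look, d.stopped_on, d.reject_b) == (3, "A", True)
    assert d.trace[-1]["process"] == "B"


def test_analyze_sequential_monitoring_of_new_endpoint(sequential_chain):
    """Switch at look 2: the new endpoint is monitored onwards; the look-3
    statistic falls short and look 4 crosses."""
    spec = sequential_chain.spec
    stats_a = [LookStatistics(k + 1, s, i) for k, (s, i) in enumerate(
        zip([8.5, 14.5, 25.0, 30.0], np.append(spec.boundary_a.info,
                                               [45.47, 68.34, 91.0])))]
    stats_b = [LookStatistics(k + 1, s, i) for k, (s, i) in enumerate(
        zip([1.60, 7.71, 23.13, 32.25], WORKED_INFO_B))]
    d = analyze_switch_trial(stats_a, stats_b, spec,
                             boundary=sequential_chain)
    assert (d.stop_look, d.stopped_on, d.reject_b) == (4, "B", True)
    look3 = [t for t in d.trace if t["look"] == 3]
    assert look3 and not look3[0]["crossed"]


def test_analyze_no_rejection_when_statistics_stay_low():
    spec = toy_spec(k_switch=2)
    chain = solve_switch_boundary(spec, n_points=1 << 12)
    stats_a = [LookStatistics(k, -1.0, spec.boundary_a.info[k - 1])
               for k in range(1, 5)]
    stats_b = [LookStatistics(k, -1.0, spec.info_b[k - 1])
               for k in range(1, 5)]
    d = analyze_switch_trial(stats_a, stats_b, spec, boundary=chain)
    assert (d.stop_look, d.stopped_on, d.reject_b) == (4, "end", False)


def test_boundaries_conservative_under_overstated_correlation():
    """Boundaries built with rho' > rho_true keep the type I error at or
    below that of boundaries built with the true rho (1e5 paths)."""
    info = np.arange(1, 6) * 9.55
    sp = SpendingFunction(alpha=0.025)
    ba = boundary_single_endpoint(GroupSequentialDesign(
        spending=sp, imax=47.75, info=info), n_points=1 << 14)
    chains = {}
    for rho_b in (0.3, 0.7):
        spec = SwitchSpec(k_switch=3, boundary_a=ba, info_b=info,
                          imax_b=47.75, spending_b=sp, rho=rho_b)
        chains[rho_b] = solve_switch_boundary(spec, refine=False,
                                              n_points=1 << 12, xtol=1e-3).u

    rho_true = 0.3
    rng = np.random.default_rng(77)
    n = 100_000
    dinc = np.diff(info, prepend=0.0)
    za = rng.standard_normal((n, 5))
    zb = rho_true * za + np.sqrt(1 - rho_true**2) * \
        rng.standard_normal((n, 5))
    s_a = np.cumsum(za * np.sqrt(dinc), axis=1)
    s_b = np.cumsum(zb * np.sqrt(dinc), axis=1)

    def type1(u_b):
        crossed_a = s_a[:, :2] >= ba.u[:2]
        early = crossed_a.any(axis=1)
        first = crossed_a.argmax(axis=1)
        rej = np.where(early,
                       s_b[np.arange(n), first] >= u_b[first],
                       (s_b[:, 2:] >= u_b[2:]).any(axis=1))
        return rej.mean()

    assert type1(chains[0.7]) <= type1(chains[0.3]) + 1e-9
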