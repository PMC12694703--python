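"""Shared fixtures: the worked-example designs and simulation caches.

The expensive objects (boundary chains at high QMC resolution, the
rho-grid boundary caches for the scenario driver) are session-scoped so
the acceptance tests and the unit tests share them.
"""

import numpy as np
import pytest

from gsswitch import (BoundaryCache, GroupSequentialDesign, ScenarioConfig,
                      SpendingFunction, SwitchSpec, TwoArmBinaryCounts,
                      binary_score_information, boundary_single_endpoint,
                      solve_switch_boundary)

# cumulative two-arm success counts of the worked-example dataset
WORKED_COUNTS = [(93, 184, 110, 184), (192, 369, 221, 369),
                 (281, 553, 331, 553)]
# endpoint-B (time-to-recovery) information at the four observed looks
WORKED_INFO_B = np.array([35.35, 70.53, 106.49, 139.91])
WORKED_IMAX_A = 114.6
WORKED_IMAX_B = 184.5

HIGH_POINTS = 1 << 16


@pytest.fixture(scope="session")
def spending_025():
    return SpendingFunction(alpha=0.025)


@pytest.fixture(scope="session")
def worked_info_a():
    return np.array([binary_score_information(TwoArmBinaryCounts(*c)).information
                     for c in WORKED_COUNTS])


@pytest.fixture(scope="session")
def worked_boundary_a(spending_025, worked_info_a):
    design = GroupSequentialDesign(spending=spending_025, imax=WORKED_IMAX_A,
                                   info=worked_info_a)
    return boundary_single_endpoint(design, n_points=HIGH_POINTS)


@pytest.fixture(scope="session")
def retrospective_chain(spending_025, worked_boundary_a):
    """Corrected boundary when the switch is decided at the last planned
    look (all three observed looks monitored on endpoint A)."""
    spec = SwitchSpec(k_switch=5, boundary_a=worked_boundary_a,
                      info_b=WORKED_INFO_B[:3], imax_b=WORKED_IMAX_B,
                      spending_b=spending_025, rho=0.715)
    return solve_switch_boundary(spec, n_points=HIGH_POINTS)


@pytest.fixture(scope="session")
def sequential_chain(spending_025, worked_boundary_a, worked_info_a):
    """Corrected boundary for a switch at look 2 with per-look correlation
    re-estimates and frozen earlier boundary values."""
    from gsswitch.spending import BoundarySet
    b1 = BoundarySet(info=worked_info_a[:1], u=worked_boundary_a.u[:1],
                     spent=worked_boundary_a.spent[:1])
    spec = SwitchSpec(k_switch=2, boundary_a=b1, info_b=WORKED_INFO_B,
                      imax_b=WORKED_IMAX_B, spending_b=spending_025,
                      rho=[0.721, 0.721, 0.705, 0.729])
    return solve_switch_boundary(spec, n_points=HIGH_POINTS)


@pytest.fixture(scope="session")
def sim_rho_grid():
    # coarse enough to keep cache construction fast; the interpolation
    # error against direct solves is asserted separately
    return np.arange(0.0, 0.951, 0.05)


@pytest.fixture(scope="session")
def sim_cache_k5(sim_rho_grid):
    cfg = ScenarioConfig(theta_a=0.0, theta_b=0.0, rho_true=0.7, k_switch=5)
    return BoundaryCache(cfg, rho_grid=sim_rho_grid)


@pytest.fixture(scope="session")
def sim_cache_k3(sim_rho_grid):
    cfg = ScenarioConfig(theta_a=0.0, theta_b=0.0, rho_true=0.7, k_switch=3)
    return BoundaryCache(cfg, rho_grid=sim_rho_grid)


@pytest.fixture(scope="session")
def sim_cache_k2(sim_rho_grid):
    cfg = ScenarioConfig(theta_a=0.0, theta_b=0.0, rho_true=0.7, k_switch=2)
    return BoundaryCache(cfg, rho_grid=sim_rho_grid)
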