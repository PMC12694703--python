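"""Corrected critical values after a change of primary endpoint.

Reproduces the worked example: a five-stage trial monitored on a binary
day-15 response (endpoint A) stops at look 3; the primary endpoint has
meanwhile been changed to time to recovery (endpoint B).  The corrected
critical values for endpoint B control the type I error whatever the true
effect on endpoint A, using the estimated score-statistic correlation.
Two switch timings are shown: a post-hoc switch (decision at the last
planned look) and a switch at look 2 with per-look correlation estimates.
"""

import numpy as np

from gsswitch import (GroupSequentialDesign, LookStatistics, SpendingFunction,
                      SwitchSpec, TwoArmBinaryCounts, analyze_switch_trial,
                      binary_score_information, boundary_single_endpoint,
                      solve_switch_boundary)

spending = SpendingFunction(alpha=0.025)

# cumulative counts (control successes / n, treated successes / n) per look
counts = [(93, 184, 110, 184), (192, 369, 221, 369), (281, 553, 331, 553)]
stats_a = [binary_score_information(TwoArmBinaryCounts(*c), look=k + 1)
           for k, c in enumerate(counts)]
info_a = np.array([s.information for s in stats_a])
boundary_a = boundary_single_endpoint(GroupSequentialDesign(
    spending=spending, imax=114.6, info=info_a))

info_b = np.array([35.35, 70.53, 106.49, 139.91])
s_b = [1.60, 7.71, 23.13, 32.25]

print("endpoint A monitoring:")
for s, u in zip(stats_a, boundary_a.u):
    flag = "stop" if s.score >= u else "continue"
    print(f"  look {s.look}: S={s.score:5.1f}  u={u:5.1f}  -> {flag}")

print("\nswitch decided at the final planned look (k_switch = 5):")
spec5 = SwitchSpec(k_switch=5, boundary_a=boundary_a, info_b=info_b[:3],
                   imax_b=184.5, spending_b=spending, rho=0.715)
chain5 = solve_switch_boundary(spec5)
for r in chain5.records:
    print(f"  look {r.look}: u_B={r.u:5.1f}  u_B/sqrt(I)={r.z:.2f}  "
          f"worst-case theta_A={r.theta_star:+.4f}")
print(f"  observed S_3^B = {s_b[2]} vs u_3^B = {chain5.u[2]:.1f} -> "
      f"{'reject' if s_b[2] >= chain5.u[2] else 'retain'} H0(B)")

print("\nswitch at look 2 with per-look correlation estimates:")
from gsswitch.spending import BoundarySet
b1 = BoundarySet(info=info_a[:1], u=boundary_a.u[:1],
                 spent=boundary_a.spent[:1])
spec2 = SwitchSpec(k_switch=2, boundary_a=b1, info_b=info_b, imax_b=184.5,
                   spending_b=spending, rho=[0.721, 0.721, 0.705, 0.729])
chain2 = solve_switch_boundary(spec2)
for r in chain2.records:
    print(f"  look {r.look}: u_B={r.u:5.1f}  rho={r.rho:.3f}  "
          f"worst-case theta_A={r.theta_star:+.4f}")

stats_a_full = stats_a + [LookStatistics(4, 30.0, 91.0)]
stats_b_full = [LookStatistics(k + 1, s, i)
                for k, (s, i) in enumerate(zip(s_b, info_b))]
decision = analyze_switch_trial(stats_a_full, stats_b_full, spec2,
                                boundary=chain2)
print(f"  decision: stop at look {decision.stop_look} on "
      f"{decision.stopped_on}; H0(B) "
      f"{'rejected' if decision.reject_b else 'not rejected'}")
print("\nEarlier switching exposes endpoint B to more repeated testing, "
      "so its critical values are larger than under the late switch.")
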