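"""Design a five-look binary-endpoint trial with linear alpha spending.

Finds the maximum information giving 90% power to detect an increase in
response rate from 0.50 to 0.58 (one-sided alpha 0.025), converts it into
a total sample size with per-arm stage sizes, and prints the stopping
boundary on the planned information schedule.
"""

import numpy as np

from gsswitch import (GroupSequentialDesign, SpendingFunction,
                      binary_sample_size, boundary_single_endpoint,
                      design_imax)

alpha, power = 0.025, 0.9
p_control, p_treated = 0.50, 0.58
theta = np.log((p_treated / (1 - p_treated)) / (p_control / (1 - p_control)))

imax = design_imax(alpha, power, theta, n_looks=5)
total, stages = binary_sample_size(imax, p_control, p_treated)
print(f"design effect (log odds ratio): {theta:.4f}")
print(f"maximum information Imax:       {imax:.1f}")
print(f"total sample size:              {total} "
      f"(per-arm stage sizes {stages})")

info = imax * np.arange(1, 6) / 5
boundary = boundary_single_endpoint(GroupSequentialDesign(
    spending=SpendingFunction(alpha=alpha), imax=imax, info=info))
print("\nlook  t      I        u       u/sqrt(I)")
for k in range(5):
    print(f"{k + 1:>4}  {info[k] / imax:.2f}  {info[k]:7.2f}  "
          f"{boundary.u[k]:7.2f}  {boundary.z[k]:.3f}")
print("\nThe trial stops for efficacy at look k if the score statistic "
      "S_k reaches u_k; u/sqrt(I) is the usual z-scale critical value.")
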