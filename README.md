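# gsswitch

Group-sequential trial boundaries when the primary endpoint is changed
mid-trial on external grounds.

## The problem

In trials run under scientific uncertainty — emerging infectious diseases
are the motivating case — the community's view of the right primary
endpoint can change while a group-sequential trial is running.  If the new
endpoint (call it B) has been collected alongside the original one
(endpoint A), the trial can continue and test B instead.  But the interim
looks already taken were monitored on A: testing B as if nothing happened
inflates the one-sided type I error when the endpoints are correlated,
while re-using a conventional group-sequential boundary for B
over-corrects and loses power.

`gsswitch` constructs corrected critical values `u_k^B` for the new
endpoint.  Writing `S_k^X, I_k^X` for the efficient score statistic and
Fisher information of endpoint `X` at look `k` (so `S ~ N(theta I, I)`
with independent increments), the stacked statistics of both endpoints
are jointly normal with cross-covariance
`Cov(S_j^A, S_k^B) = rho sqrt(I_min^A I_min^B)`.  For a switch at look
`k_tilde`, H0(B) is rejected at look `k` on the event

    R_k^B = R_k^A  ∩ {S_k^B >= u_k^B}                         k <  k_tilde
          = C_k^A  ∩ {S_k^B >= u_k^B}                         k == k_tilde
          = C_kt^A ∩ {S_r^B < u_r^B, kt<=r<k} ∩ {S_k^B >= u_k^B}   k > k_tilde

(`R_k^A` / `C_k^A` = stop-and-reject / continue events of the original
alpha-spending boundary), and the corrected values solve the worst-case
spending condition

    sup_{theta_A}  sum_{r<=k} Pr_{H0(B)}( R_r^B )  =  alpha*(t_k^B),

which guarantees type I error control for the test of the new endpoint
*whatever the true treatment effect on the abandoned one*.  The supremum
is found numerically (including the `theta_A -> +-inf` limits) and each
`u_k^B` by root-finding on multivariate-normal rectangle probabilities.
The correlation `rho` is estimated from the trial: directly (pooled
within-arm Pearson) for normal endpoints, by a within-arm bootstrap of
`(S^A, S^B)` otherwise.

## Worked example

A five-stage trial (1:1 randomization, one-sided alpha 0.025, linear
spending `alpha*(t) = 0.025 t`) monitors a binary day-15 response with
90% power for an increase from 0.50 to 0.58 — maximum information 114.6,
total sample size 1844.  The trial crosses the endpoint-A boundary at
look 3; meanwhile the primary endpoint has been switched to time to
recovery.  `python examples/switch_boundary.py` prints:

```
endpoint A monitoring:
  look 1: S=  8.5  u= 12.3  -> continue
  look 2: S= 14.5  u= 16.8  -> continue
  look 3: S= 25.0  u= 19.9  -> stop

switch decided at the final planned look (k_switch = 5):
  look 1: u_B= 15.4  u_B/sqrt(I)=2.59  worst-case theta_A=+inf
  look 2: u_B= 18.9  u_B/sqrt(I)=2.26  worst-case theta_A=+0.2384
  look 3: u_B= 21.6  u_B/sqrt(I)=2.09  worst-case theta_A=+0.1822
  observed S_3^B = 23.13 vs u_3^B = 21.6 -> reject H0(B)

switch at look 2 with per-look correlation estimates:
  look 1: u_B= 15.4  rho=0.721  worst-case theta_A=+inf
  look 2: u_B= 19.9  rho=0.721  worst-case theta_A=+0.0769
  look 3: u_B= 24.6  rho=0.705  worst-case theta_A=+0.0086
  look 4: u_B= 27.8  rho=0.729  worst-case theta_A=-0.0174
  decision: stop at look 4 on B; H0(B) rejected
```

The corrected value at the stop look (21.6 on the score scale, 2.09 on
the z-scale) sits between the naive 1.96 and the look-3 group-sequential
value: it charges exactly the alpha consistent with the monitoring
actually performed.  Switching earlier (second block) exposes endpoint B
to repeated testing, so its critical values are larger, and the look-3
statistic 23.13 no longer crosses; the trial continues and stops at look
4.  Other examples: `examples/design_boundary.py` (boundary and sample
size from power), `examples/estimate_correlation.py` (bootstrap `rho`
from a synthetic binary + time-to-event trial),
`examples/operating_characteristics.py` (Monte-Carlo error rates of the
corrected, naive, and uncorrected group-sequential tests).

A thin CLI mirrors the library: `gsswitch design`, `gsswitch
switch-boundary`, `gsswitch analyze`, `gsswitch estimate-rho`, `gsswitch
simulate` (YAML/JSON configs; see `--help`).

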