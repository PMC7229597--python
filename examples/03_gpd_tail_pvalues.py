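"""How the generalized-Pareto tail approximation refines extreme p-values.

With B = 999 permutations the smallest empirical p-value is 1/1000.  The
GPD fitted to the largest null statistics extrapolates far below that;
here we compare it against a brute-force permutation run with B = 10^6.
"""

import numpy as np

import qpss
from qpss.permutation import _null_lr_stats

rng = np.random.default_rng(11)
n_g, n_plus = 200, 12
y = rng.standard_normal(n_g)
y[:n_plus] += 1.35  # carriers in the window sit visibly higher

obs = qpss.signed_lr(y, np.arange(n_g) < n_plus)[0]
null = qpss.permute_null(y, n_plus, B=999, seed=1, observed_stat=obs)
p_emp = qpss.empirical_p(null)
p_gpd, fit, method = qpss.gpd_tail_p(null)

big = np.concatenate(
    [_null_lr_stats(y, np.array([n_plus]), 200_000, rng)[0] for _ in range(5)]
)
p_ref = (1 + np.sum(big >= obs)) / (len(big) + 1)

print(f"observed |ln LR| = {obs:.2f}")
print(f"empirical p (B=999)         : {p_emp:.3e}  (floor 1/1000)")
print(f"GPD-accelerated p (B=999)   : {p_gpd:.3e}  via {method}, "
      f"shape={fit.shape:.3f}, {fit.n_exc} tail points")
print(f"brute-force p (B=10^6)      : {p_ref:.3e}")
# The GPD estimate from 999 permutations should agree with the million-
# permutation reference within a small factor, at ~1000x less work.
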