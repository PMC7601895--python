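"""Comparing affinity rankings from two energy sets.

Simulates the common situation where the same proteins are scored by two
methods (say, energies from experimental vs predicted structures) and
quantifies how well the rankings and values agree.
"""

import numpy as np

from npadsorb import kendall_tau, linear_fit, rank_by_energy

rng = np.random.default_rng(0)
ids = [f"protein-{i:02d}" for i in range(12)]
reference = {pid: float(e) for pid, e in zip(ids, rng.normal(-150, 40, 12))}
other = {pid: reference[pid] * rng.normal(1.0, 0.1) for pid in ids}

comparison = kendall_tau(rank_by_energy(reference), rank_by_energy(other))
fit = linear_fit([reference[i] for i in ids], [other[i] for i in ids])

print(f"Kendall tau = {comparison.tau:.2f}  (dK = {comparison.dK} of "
      f"{comparison.N * (comparison.N - 1) // 2} pairs discordant)")
print(f"linear fit:  slope = {fit.slope:.2f}, R^2 = {fit.r_squared:.2f}")
print(f"relative errors within +-20%: "
      f"{np.mean(np.abs(fit.relative_errors) < 0.2):.0%}")

# tau = 1 means identical ranking, 0 no relation, -1 reversal; the linear
# fit and relative errors say whether the energy *values* also agree.
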