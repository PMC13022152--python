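"""Diversity statistics and Tajima's D on neutral coalescent samples.

Under the neutral model, theta estimated from mutations (Watterson) and
from pairwise differences (pi) agree in expectation, so D centres near
zero; an excess of rare variants (as after a selective sweep) drives D
negative.
"""

import numpy as np

import sd1hap as s

matrix = s.simulate_neutral_sample(n=20, theta=5.0, locus_length=2000, seed=7)
stats = s.diversity_stats(matrix)
td = s.tajima_d(stats)

print(f"n={stats.n}  sites used={stats.L_used}")
print(f"S={stats.S}  eta={stats.eta}  k={stats.k:.3f}  pi={stats.pi:.5f}")
print(f"theta per sequence (from eta) = {stats.theta_per_seq:.3f}  (simulated theta = 5)")
print(f"Watterson theta per site     = {stats.theta_w_site:.6f}")
print(f"Tajima's D = {td.D:.3f} (two-sided p = {td.p_value:.3f}) — "
      "not significantly different from zero under neutrality")

# star-like variation: every polymorphism a singleton -> negative D
L, n = 30, 20
seqs = [["A"] * L for _ in range(n)]
for j in range(L):
    seqs[j % n][j] = "T"
star = s.SequenceMatrix.from_strings([f"s{i}" for i in range(n)], ["".join(x) for x in seqs])
star_d = s.tajima_d(s.diversity_stats(star))
print(f"singleton-only matrix: D = {star_d.D:.3f} < 0 (excess of rare variants)")
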