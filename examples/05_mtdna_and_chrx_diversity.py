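"""Mitochondrial nucleotide diversity and the autosome/chrX ratio.

Simulates mtDNA haplotypes along a star tree (closed-form expectation
E[pi] = 2m/L) and evaluates the autosome-to-X diversity ratio against the
neutral expectation 4/3 for equal male and female effective sizes.
"""

import numpy as np

from mouflon import simulate
from mouflon.diversity import autosome_x_ratio, mtdna_pi

m, L = 10, 2_000
aln, truth = simulate.simulate_mtdna(simulate.star_tree(6, m), length=L,
                                     seed=2)
est = mtdna_pi(aln)
print(f"star tree, {len(aln.ids)} haplotypes, ~{m} mutations per tip, "
      f"L = {L}")
print(f"pi = {est.value:.5f} (realized truth {truth['pi']:.5f}, "
      f"expectation 2m/L = {2 * m / L:.5f})")

# autosome vs chrX: X carries 3/4 of the autosomal effective size
rng = np.random.default_rng(0)
theta_a = 0.004
n = 200_000
est_a = rng.binomial(n, theta_a) / n
est_x = rng.binomial(n, 0.75 * theta_a) / n
ratio, expectation = autosome_x_ratio(est_a, est_x)
print(f"\nautosome/chrX diversity ratio = {ratio:.2f} "
      f"(neutral expectation {expectation:.2f})")
print("Ratios below 1.33 indicate reduced male effective size, e.g. from"
      " polygynous mating.")
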