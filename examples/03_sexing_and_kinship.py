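"""Genetic sexing from coverage (Rx) and kinship from pairwise mismatch.

Simulates per-chromosome coverage with an X-mappability deficit and
recovers each sample's sex with the Rx +- 1.96 SE rule; then plants
relative pairs of every degree in a population and classifies them from
pseudo-haploid mismatch rates.
"""

import itertools

from mouflon import simulate, variants
from mouflon.sample_qc import (
    assign_sex, classify_kinship, compute_rx, kmeans_thresholds,
    pairwise_mismatch, prune_relatives,
)

sexes = {f"s{i}": ("XX" if i % 2 == 0 else "XY") for i in range(8)}
profiles = simulate.simulate_coverage(sexes, depth=2.0, seed=5)
print("sample  Rx      call   truth")
rx_values = []
for prof in profiles:
    res = assign_sex(compute_rx(prof))
    rx_values.append(res.rx)
    print(f"{res.sample:>6}  {res.rx:.3f}  {res.assignment:>5}  "
          f"{sexes[res.sample]}")
means, cutoffs = kmeans_thresholds(rx_values, seed=0)
print(f"advisory k-means cluster means: {means[0]:.2f} / {means[1]:.2f} "
      f"(assignment always uses the 0.65/0.5 thresholds)")

tree = {"name": "r", "F": 0.0,
        "children": [{"name": "P1", "F": 0.05, "children": []}]}
relatives = [
    simulate.RelativeSpec("P1", d, f"P1_{11 + 2 * i}", f"P1_{12 + 2 * i}")
    for i, d in enumerate(("identical", "1st", "2nd", "3rd"))
]
cfg = simulate.SimConfig(tree=tree, samples_per_pop=10, n_sites=50_000,
                         seed=7, relatives=relatives)
freqs = simulate.simulate_frequencies(cfg)
gm, _ = simulate.simulate_genotypes(freqs, cfg)
ph = variants.pseudo_haploidize(gm, seed=8)

members = [s for s in gm.samples if s.startswith("P1_")]
mres = [pairwise_mismatch(ph, pair)
        for pair in itertools.combinations(members, 2)]
kres = classify_kinship(mres)

print("\nplanted pairs (theta = 1 - median-normalized mismatch):")
planted = {tuple(sorted((r.sample_a, r.sample_b))): r.degree
           for r in relatives}
for k in kres:
    key = tuple(sorted(k.pair))
    if key in planted:
        print(f"  {key[0]}-{key[1]}  theta={k.theta:.3f}  "
              f"called={k.degree:<9}  planted={planted[key]}")
excluded = prune_relatives(kres)
print(f"\ngreedy pruning would exclude {len(excluded)} samples: {excluded}")
print("Expected theta ladder: 0.5 (identical), 0.25, 0.125, 0.0625, ~0.")
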