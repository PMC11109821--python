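"""GERP-weighted relative mutation load on synthetic conserved regions.

Builds a conservation track, places derived alleles for two populations —
one uniformly, one tilted toward high-score regions — and shows that the
tilted population carries the higher relative mutation load (RML).
"""

import numpy as np

from mouflon import simulate
from mouflon.load import conserved_regions, rml

pops = {"uniform": ["u1", "u2", "u3"], "tilted": ["t1", "t2", "t3"]}
_, _, truth = simulate.simulate_load(pops, seed=21)
track, derived, _ = simulate.simulate_load(
    pops, weights={"uniform": None, "tilted": truth["region_scores"]}, seed=21
)
regions = conserved_regions(track, threshold=4.0)
print(f"{len(regions)} conserved regions (runs of bases with score > 4); "
      f"scores span {min(r.g for r in regions):.2f}-"
      f"{max(r.g for r in regions):.2f}")

print("\nsample  RML    derived alleles in regions")
for pop, members in pops.items():
    vals = []
    for s in members:
        res = rml(derived, regions, s)
        vals.append(res.rml)
        print(f"{s:>6}  {res.rml:.3f}  {res.n_derived}")
    print(f"  mean({pop}) = {np.mean(vals):.3f}")

print("\nRML is the derived-allele-weighted mean region score, so a genome"
      " whose derived variants concentrate in strongly conserved sequence"
      " scores higher - the signature of a heavier deleterious load.")
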