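"""Runs of homozygosity: calling planted tracts, F_ROH and dating.

Plants homozygous tracts of known length into one simulated genome, calls
them back with the sliding-window ROH caller, and converts tract lengths
into inbreeding ages with g = 100/(2 r L).
"""

from mouflon import simulate
from mouflon.roh import call_roh, classify_sizes, f_roh, inbreeding_time

cfg = simulate.SimConfig(
    tree={"name": "r", "F": 0.0,
          "children": [{"name": "P", "F": 0.05, "children": []}]},
    samples_per_pop=1, n_sites=12_000, n_chroms=1, seed=3,
)
freqs = simulate.simulate_frequencies(cfg)
gm, _ = simulate.simulate_genotypes(freqs, cfg)

planted = [simulate.ROHSpec("P_1", "chr1", s, l) for s, l in
           [(100_000, 600_000), (1_400_000, 1_500_000),
            (3_600_000, 2_500_000), (7_000_000, 4_000_000)]]
gm, _ = simulate.plant_roh(gm, planted, seed=4)

segments = call_roh(gm, "P_1")
print(f"planted {len(planted)} tracts, called {len(segments)} segments:")
for seg in segments:
    print(f"  {seg.chrom}:{seg.start}-{seg.end}  {seg.length_mb:.2f} Mb "
          f"({seg.n_snps} SNPs)")

genome_bp = int(gm.sites["pos"].max())
summary = classify_sizes(segments, sample="P_1", autosomal_genome_bp=genome_bp)
print(f"\nF_ROH = {summary.f_roh:.3f} "
      f"(fraction of the {genome_bp/1e6:.0f} Mb genome inside ROH)")
print("size classes:", summary.class_counts)

print("\ninbreeding ages from tract length (1.5 cM/Mb, 3 yr/generation):")
for seg in segments:
    t = inbreeding_time(seg.length_mb)
    print(f"  {seg.length_mb:.2f} Mb -> {t.generations_rounded} generations "
          f"(~{t.years:.0f} years ago)")
print("\nLonger tracts are broken up faster by recombination, so they"
      " indicate more recent common ancestors.")
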