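# Methods

This note documents the models, estimators, default parameters and design
choices behind the package, and what the synthetic-data experiments do and
do not demonstrate.

## Genotype substrate and filtering

All analyses operate on a `GenotypeMatrix`: sites × samples alt-allele
dosages (0/1/2, −1 missing) with 1-based coordinates, sorted by
(chromosome, position). VCF input is read with cyvcf2; multiallelic
records are carried through reading but dropped (never split) at the
filter stage.

Hard site filters follow common GATK-style short-variant practice:
QUAL ≥ 20, QD ≥ 2.0, SOR ≤ 3.0, FS ≤ 60.0, MQ ≥ 40.0, MQRankSum > −12.5,
ReadPosRankSum > −8.0. The depth window (default 4–16×) is interpreted as
bounds on the **per-site mean depth** (site DP divided by sample count),
inclusive at both ends — per-sample depth filtering is an equally
defensible reading, but per-site is what a cohort-level DP annotation
supports directly. Minor-allele frequency (default ≥ 0.05) is computed
over all non-missing genotypes including the outgroup; the
Hardy–Weinberg exact test (default p ≥ 0.001) is a plain two-sided exact
test on genotype counts pooled across non-outgroup samples, without the
mid-p adjustment. INFO fields absent from a record pass their test
vacuously unless listed in `FilterConfig.required_info`. Filtering is
idempotent.

A validation subset can be ascertained on outgroup heterozygous sites;
pseudo-haploidization replaces each diploid call by one uniformly drawn
allele (seeded, deterministic).

## f-statistics

f3(O; A, B) is the mean over usable sites of (o−a)(o−b); f4(A, B; C, D)
the mean of (a−b)(c−d). A site is usable iff every argument population
has at least one observed allele there (complete-case selection per
statistic; sites are never globally dropped for missingness). The
optional small-sample correction subtracts ĥ_O/n_O per site, with
ĥ_O = 2a(n−a)/(n(n−1)) the unbiased heterozygosity of the target; it is
**off by default** — the distance matrices use f3 only as a relative
distance, where the target term is a pair-independent constant — and it
refuses pseudo-haploid targets (n_O < 2).

Uncertainty comes from a weighted delete-one-block jackknife over
contiguous blocks, weighting blocks by their usable-site counts (the last
block of a chromosome is typically short). Default jackknife blocks are
5 Mb physical spans; the tree bootstrap instead resamples fixed 30,000-SNP
chunks with replacement (500 replicates in the pipeline default;
a final partial chunk is kept as its own chunk). With fewer than two
non-empty blocks the SE is reported as NaN with a warning rather than
fabricated.

Distances are D[p,q] = 1 − f3(outgroup; p, q), symmetric with zero
diagonal. The bootstrap exploits the fact that f3 is a ratio of sums:
per-chunk term sums and usable-site counts are precomputed once per pair,
so each replicate is a weighted ratio rather than a full recomputation.

## Structure summaries

Classical MDS double-centers B = −½ J D∘D J and eigendecomposes;
coordinates are the top-k eigenvectors scaled by √λ, axes ordered by
eigenvalue, and each axis's sign is fixed so its largest-magnitude
coordinate is positive (runs are bit-reproducible). If fewer than k
eigenvalues are positive, fewer axes are returned with a warning.

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion with the usual branch-length formulas. Ties in Q are broken
by the lexicographically smallest pair of subtree keys (the minimum leaf
label under each node), making the result invariant to input label
order. Negative branch lengths are clamped to zero with the deficit
moved to the sister branch — a display convention only; bipartition
comparison ignores branch lengths entirely. On additive matrices NJ is
exact, which the tests verify against an exhaustive
topology-enumeration + least-squares oracle for 4–6 taxa and against an
independent NJ implementation (dendropy).

Bootstrap support for an internal edge is the percentage of replicate
trees containing the same bipartition (canonicalized over the leaf set).
Outgroup rooting augments the distance matrix with one row at a constant
distance (default 1, comfortably above any ingroup 1−f3), reruns NJ and
roots on the outgroup's pendant edge at its midpoint, leaving the
outgroup sibling to the entire ingroup; a constant ≤ max(D)/2 triggers a
warning because the outgroup may then attach internally.

## Diversity

Individual heterozygosity is the count of heterozygous calls divided by
the callable-site denominator supplied by the caller. This genotype-based
estimator replaces genotype-likelihood machinery deliberately: on
accurately called genotypes it targets the same quantity, and it keeps
the package desk-scale; coverage-matched downsampling is out of scope, so
comparisons across samples assume comparable genotyping quality.

Within-population diversity is the mean of 1 − f3(outgroup; indᵢ, indⱼ)
over member pairs, each individual treated as its own population.

Mitochondrial π uses the average-pairwise-differences formula
π = [Σ_{i<j} π_ij / (n(n−1)/2)] / L. Site inclusion is decided once at
the cohort level: a column is included iff non-missing (not N/−) in at
least two individuals and carrying at most two distinct bases. π_ij
counts mismatches on included columns where both members are called;
pairs missing a member contribute zero there, and the single cohort-level
L normalizes every pair. The alternative per-pair normalization
(π_ij/L_ij averaged) is available behind `per_pair_length=True`; with no
missing data the two coincide.

The autosome/chrX ratio is reported next to its analytic expectation 4/3
(three X copies circulate per four autosomal copies when male and female
effective sizes are equal); values below 1.33 indicate reduced male Ne.

## Runs of homozygosity

The caller reproduces the SNP-window scheme of the classic PLINK
implementation with defaults: 50-SNP windows with at most 1 heterozygote
and 5 missing calls; a SNP is eligible when ≥ 5% of windows covering it
pass; maximal eligible runs are trimmed to their outermost homozygous
SNPs, split at inter-SNP gaps > 1 Mb, and kept when they have ≥ 30 SNPs,
≥ 500 kb, and ≤ 30 kb per SNP. The window-hit threshold, missing
allowance and gap limit are the cited tool's documented defaults; the
remaining values are the explicit study parameters. Segment bounds are
reported at the outermost homozygous SNPs, not extrapolated midpoints, so
breakpoint error is bounded by the local SNP spacing plus window effects
(≤ ~50 kb at 1 SNP/kb in the recovery tests).

F_ROH divides summed segment length by an autosomal genome size; the
package defaults to autosomes only (configurable), with overlapping
segments treated as a caller defect (error, not silent merging).
Inbreeding ages use g = 100/(2 r L) with defaults r = 1.5 cM/Mb and
3 years per generation; both raw and nearest-integer generations are
returned, and years are g × 3 unrounded. Size classes are half-open
[0.5,1), [1,2), [2,3), [3,5) Mb plus a ≥ 5 Mb overflow class.

## Sex determination

Rx is the unweighted mean over autosomes of depth(chrX)/depth(autosome),
with SE = sd/√n over those per-autosome ratios (per-autosome ratios,
rather than a single pooled ratio, are what make the SE meaningful).
Assignment is XX if Rx − 1.96·SE > 0.65 and XY if Rx + 1.96·SE < 0.5,
else unassigned. The thresholds are deliberately asymmetric around the
idealized 1/0.5 because incomplete X assemblies depress observed X
coverage; k-means clustering of the observed Rx values is provided to
let an operator check where the cohort's clusters actually sit, but
assignment always uses the configured thresholds. The k-means runs
Lloyd's algorithm with farthest-point seeding on the sorted values, so it
is deterministic and order-invariant.

## Kinship

P0 is the pseudo-haploid mismatch rate computed in 1 Mb windows (the
convention of mismatch-based kinship tools; the window size mainly
affects the SE, not the point estimate) and averaged over windows with at
least one jointly called site. Within a population, P0 is normalized by
the median over all pairs — a robust unrelated-pair baseline as long as
most pairs are unrelated — and θ = 1 − normalized P0 estimates the
kinship coefficient: 0.5 identical, 0.25 parent–offspring/full sibling,
0.125 second degree, 0.0625 third degree, ~0 unrelated. Degrees are
assigned by the midpoints (θ₁+θ₂)/2 of that ladder:
0.375, 0.1875, 0.09375, 0.03125. Third-degree detection extends the
classic second-degree ceiling of mismatch-based kinship; at 50,000 SNPs
the θ sampling noise (≈0.007 SD) is small against the 0.031 gap to the
unrelated class, which is why the recovery experiments classify ≥ 95% of
planted pairs correctly. Greedy pruning removes the sample in the most
related pairs, preferring low coverage then the lexicographically first
id, until no pair at or below the kept degree remains.

## Mutation load

Conserved regions are maximal runs of consecutive bases with conservation
score strictly greater than 4 (a base scoring exactly 4.0 is excluded);
the region score g_i defaults to the per-base mean (max and sum are
options). Ancestral states come from the outgroup's homozygous allele;
outgroup-heterozygous or missing sites are dropped and tallied. The
relative mutation load is RML = Σᵢ nᵢgᵢ / N with nᵢ the derived-allele
count in region i (1 per heterozygous, 2 per homozygous site). N counts
derived alleles **within conserved regions** by default, which makes RML
a weighted mean of region scores bounded by min(gᵢ) and max(gᵢ) — the
reading under which RML is interpretable as "how conserved is the
sequence my derived variants hit"; a genome-wide denominator is exposed
as `genome_wide_n=True` for sensitivity analysis.

## Synthetic data: what it emulates, what it does not

Frequencies drift along a user-supplied population tree under the
Balding–Nichols model: child ~ Beta(p(1−F)/F, (1−p)(1−F)/F) given parent
frequency p and branch drift F, i.e. mean p and variance F·p(1−p) — the
exact first two moments that f-statistics measure, which is why this
model (rather than a forward simulator) suffices for testing them.
Defaults mirror the study design at reduced scale: ten ingroup lineages
in two nested clades with F = 0.05 per branch, three samples per
population, 50,000 SNPs at 1 SNP/kb over four chromosomes, ancestral
frequencies uniform on [0.05, 0.95], and one outgroup at F = 0.6 —
distant enough that outgroup alleles approximate the ancestral state for
polarization.

Individuals are pairs of Bernoulli(p) haplotypes; relatives are built by
explicit gamete transmission through hidden intermediates, so a
degree-d pair has kinship coefficient 0.5^(d+1) exactly, and
parent–offspring pairs show zero opposite homozygotes. Sites are
unlinked: there is no recombination map or LD, so block-jackknife and
bootstrap behaviour under realistic linkage is *not* exercised — blocks
on simulated data are conservative (independent sites make any blocking
valid). Planted ROH duplicate a sampled haplotype within an interval,
giving truly homozygous tracts on an otherwise heterozygous background.

Coverage is Poisson per chromosome (26 autosomes of 50 Mb, one X).
Expected X depth is scaled by an X-mappability factor (default 0.74) and
halved for XY samples, so females sit at Rx ≈ 0.74 and males ≈ 0.37.
The mappability default is the empirically observed female cluster mean
in sheep data — the same assembly-incompleteness effect that motivates
the 0.65/0.5 assignment thresholds in the first place. With an ideal
assembly (mappability 1) male Rx sits exactly on the 0.5 threshold and
the 1.96-SE rule cannot call males reliably; the idealized setting is
kept available and tested, but the default reflects the data model the
thresholds were calibrated for. Poisson noise at whole-chromosome scale
is tiny compared to real mappability variation among autosomes, so the
simulated SEs are optimistic; the recovery experiment demonstrates the
decision rule, not realistic uncertainty.

The load generator writes conserved regions with constant per-base
scores (uniform on (4.5, 9)) separated by sub-threshold gaps and places a
fixed number of derived alleles per sample across regions with
probability ∝ weightᵢ × gᵢ. Weights are per-region vectors (a scalar
weight would cancel in the normalization); the acceptance experiment
gives one population weights ∝ gᵢ, tilting its placements toward
conserved sequence and raising its expected RML.

mtDNA haplotypes mutate along a tree under infinite sites (every
mutation hits a fresh position), so pairwise differences equal summed
branch mutation counts exactly and E[π] = 2m/L on a star tree with m
mutations per tip.

All generators are deterministic under their seed.

## Pipeline

`run_pipeline` executes filter → sexdet → kinship → f-stats → tree →
diversity → ROH → load, carrying state forward (the kinship exclusion
list propagates into the f-statistics grouping). Every stochastic stage
derives its seed from the single run seed, so identical configs produce
byte-identical outputs; the manifest records a config hash, per-stage
counts and completion status, and a failed stage writes a `FAILED`
marker naming itself while retaining earlier outputs. Bootstrap tree
support is computed on outgroup-rooted trees built from each replicate
matrix augmented with the outgroup row, so replicate and main leaf sets
match.

## Problem sizes and numerical conventions

Test and acceptance experiments use 50,000-SNP cohorts for kinship and f4
calibration, 12,000-SNP single-chromosome genomes for ROH recovery,
200-replicate f4 null panels, and 100-seed recovery loops — sizes chosen
so the full suite runs in well under ten minutes on one CPU while keeping
Monte-Carlo error far from every decision boundary. Numerical
conventions: coordinates 1-based inclusive internally, BED converted at
the boundary; missing dosage −1; jackknife SE NaN (flagged) under two
blocks; MDS sign fixed as above; NJ ties broken lexicographically;
half-open ROH size classes. Known limitations: no linkage in the
generator, no genotype-likelihood support, no indels or phasing, single
outgroup per configuration, and mtDNA alignment is consumed, not built.
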