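"""Synthetic genotype, coverage, conservation and mtDNA data with truth.

The generator emulates the statistical structure the analyses assume:

* ten ingroup lineages diverging on a known tree with per-branch drift
  (Balding-Nichols frequencies) plus one distant outgroup;
* planted relative pairs of degree 0-3 built by explicit gamete
  transmission through hidden intermediate individuals;
* planted homozygous tracts of controlled length;
* sex-dependent chrX coverage with an X-mappability deficit;
* conserved-region scores with per-population derived-allele burdens;
* mtDNA haplotype sets mutated along a tree under infinite sites.

Balding-Nichols drift is used instead of a forward Wright-Fisher model:
given parent frequency p and branch drift F, the child frequency is
Beta(p (1-F)/F, (1-p)(1-F)/F), which has mean p and variance F p (1-p) —
exactly the frequency covariance structure that f-statistics measure.
Every generator is deterministic under its seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mouflon.variants import GenotypeMatrix, MISSING
from mouflon.diversity import MtAlignment
from mouflon.sample_qc import CoverageProfile
from mouflon.load import GerpTrack, DerivedAlleles, conserved_regions

#: default ingroup topology: ten lineages in two major clades, nested
#: splits with per-branch drift F. Leaves are population labels.
DEFAULT_TREE: dict = {
    "name": "root",
    "F": 0.0,
    "children": [
        {
            "name": "cladeA", "F": 0.05,
            "children": [
                {"name": "A1", "F": 0.05, "children": [
                    {"name": "P1", "F": 0.05, "children": []},
                    {"name": "P2", "F": 0.05, "children": []},
                ]},
                {"name": "A2", "F": 0.05, "children": [
                    {"name": "P3", "F": 0.05, "children": []},
                    {"name": "A3", "F": 0.05, "children": [
                        {"name": "P4", "F": 0.05, "children": []},
                        {"name": "P5", "F": 0.05, "children": []},
                    ]},
                ]},
            ],
        },
        {
            "name": "cladeB", "F": 0.05,
            "children": [
                {"name": "B1", "F": 0.05, "children": [
                    {"name": "P6", "F": 0.05, "children": []},
                    {"name": "P7", "F": 0.05, "children": []},
                ]},
                {"name": "B2", "F": 0.05, "children": [
                    {"name": "P8", "F": 0.05, "children": []},
                    {"name": "B3", "F": 0.05, "children": [
                        {"name": "P9", "F": 0.05, "children": []},
                        {"name": "P10", "F": 0.05, "children": []},
                    ]},
                ]},
            ],
        },
    ],
}


@dataclass
class RelativeSpec:
    """A planted relative pair within one population."""

    pop: str
    degree: str  # identical / 1st / 2nd / 3rd
    sample_a: str
    sample_b: str


@dataclass
class ROHSpec:
    """A planted homozygous tract (1-based inclusive start)."""

    sample: str
    chrom: str
    start: int
    length_bp: int

    @property
    def end(self) -> int:
        return self.start + self.length_bp - 1


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic cohort.

    The default fixture mirrors a ten-lineage design at reduced scale:
    3 samples per population, 50,000 SNPs at 1 SNP/kb over 4
    chromosomes, per-branch drift F = 0.05, and a distant outgroup
    (drift 0.6 from the root).
    """

    tree: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_TREE))
    samples_per_pop: int = 3
    n_sites: int = 50_000
    freq_law: str = "uniform"  # uniform on [0.05, 0.95] or "beta"
    beta_params: tuple[float, float] = (0.8, 0.8)
    seed: int = 0
    n_chroms: int = 4
    snp_spacing_bp: int = 1_000
    outgroup_name: str = "Goat"
    outgroup_f: float = 0.6
    relatives: list[RelativeSpec] = field(default_factory=list)
    planted_roh: list[ROHSpec] = field(default_factory=list)
    sexes: dict[str, str] = field(default_factory=dict)

    def leaf_pops(self) -> list[str]:
        out: list[str] = []

        def walk(node: dict) -> None:
            if not node["children"]:
                out.append(node["name"])
            for c in node["children"]:
                walk(c)

        walk(self.tree)
        return out

    def chrom_layout(self) -> pd.DataFrame:
        """Site coordinates: n_sites split evenly over n_chroms."""
        per = self.n_sites // self.n_chroms
        sizes = [per] * self.n_chroms
        sizes[-1] += self.n_sites - per * self.n_chroms
        chroms, pos = [], []
        for i, sz in enumerate(sizes):
            chroms.append(np.repeat(f"chr{i + 1}", sz))
            pos.append(self.snp_spacing_bp * (np.arange(sz) + 1))
        return pd.DataFrame(
            {"chrom": np.concatenate(chroms), "pos": np.concatenate(pos)}
        )


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""

    tree_distance: dict[tuple[str, str], float]
    relatives: list[RelativeSpec]
    planted_roh: list[ROHSpec]
    sexes: dict[str, str]
    load_weights: dict[str, np.ndarray] | None = None


# ---------------------------------------------------------------------------
# Frequencies


def _bn_child(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Balding-Nichols draw of child frequencies given parent p and drift F."""
    if F == 0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    out = np.where(
        (p <= 0) | (p >= 1), p, rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
    )
    return out


def simulate_frequencies(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Per-population (and outgroup) alt-allele frequencies on the tree.

    Returns a dict mapping each leaf population — plus ``cfg.outgroup_name``
    and ``"__ancestral__"`` — to a frequency vector of length n_sites.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.freq_law == "uniform":
        anc = rng.uniform(0.05, 0.95, cfg.n_sites)
    elif cfg.freq_law == "beta":
        anc = rng.beta(*cfg.beta_params, cfg.n_sites)
    else:
        raise ValueError(f"unknown frequency law {cfg.freq_law!r}")

    freqs: dict[str, np.ndarray] = {"__ancestral__": anc}

    def walk(node: dict, parent_freq: np.ndarray) -> None:
        f = _bn_child(rng, parent_freq, float(node["F"]))
        if not node["children"]:
            freqs[node["name"]] = f
        for c in node["children"]:
            walk(c, f)

    walk(cfg.tree, anc)
    freqs[cfg.outgroup_name] = _bn_child(rng, anc, cfg.outgroup_f)
    return freqs


def tree_distances(cfg: SimConfig) -> dict[tuple[str, str], float]:
    """Pairwise drift distance (summed branch F along the path)."""
    paths: dict[str, list[tuple[str, float]]] = {}

    def walk(node: dict, acc: list[tuple[str, float]]) -> None:
        acc = acc + [(node["name"], float(node["F"]))]
        if not node["children"]:
            paths[node["name"]] = acc
        for c in node["children"]:
            walk(c, acc)

    walk(cfg.tree, [])
    out: dict[tuple[str, str], float] = {}
    pops = sorted(paths)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            pa, pb = paths[a], paths[b]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k][0] == pb[k][0]:
                k += 1
            out[(a, b)] = sum(f for _, f in pa[k:]) + sum(f for _, f in pb[k:])
    return out


# ---------------------------------------------------------------------------
# Genotypes and relatives


def _draw_haplotypes(rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    """Two haplotypes (2, n_sites) of Bernoulli(p) alleles."""
    return (rng.random((2, p.size)) < p).astype(np.int8)


def _gamete(rng: np.random.Generator, hap: np.ndarray) -> np.ndarray:
    """One gamete: per-site random choice between the two haplotypes."""
    pick = rng.integers(0, 2, hap.shape[1])
    return hap[pick, np.arange(hap.shape[1])]


def simulate_genotypes(
    freqs: Mapping[str, np.ndarray], cfg: SimConfig
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw diploid genotypes for every population plus planted relatives.

    Unrelated individuals are binomial(2, p_pop) per site (two Bernoulli
    haplotypes); planted pairs are built by gamete transmission through
    hidden intermediates, so degree-d pairs have kinship 0.5^(d+1)
    (identical pairs are genotype copies, kinship 0.5).  The outgroup is a
    single diploid individual from the high-drift outgroup branch.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    sites = cfg.chrom_layout()
    pops = cfg.leaf_pops()

    samples: list[str] = []
    haps: list[np.ndarray] = []
    for pop in pops:
        p = freqs[pop]
        for i in range(cfg.samples_per_pop):
            samples.append(f"{pop}_{i + 1}")
            haps.append(_draw_haplotypes(rng, p))

    for spec in cfg.relatives:
        if spec.pop not in pops:
            raise ValueError(f"relative spec references unknown population {spec.pop!r}")
        p = freqs[spec.pop]
        A = _draw_haplotypes(rng, p)
        if spec.degree == "identical":
            B = A.copy()
        elif spec.degree in ("1st", "2nd", "3rd"):
            links = {"1st": 1, "2nd": 2, "3rd": 3}[spec.degree]
            carrier = A
            for _ in range(links):
                other = _draw_haplotypes(rng, p)
                carrier = np.stack([_gamete(rng, carrier), _gamete(rng, other)])
            B = carrier
        else:
            raise ValueError(f"unknown degree {spec.degree!r}")
        samples.extend([spec.sample_a, spec.sample_b])
        haps.extend([A, B])

    samples.append(cfg.outgroup_name)
    haps.append(_draw_haplotypes(rng, freqs[cfg.outgroup_name]))

    dosages = np.stack([h.sum(axis=0) for h in haps], axis=1).astype(np.int8)
    site_df = sites.copy()
    site_df["ref"] = "A"
    site_df["alt"] = "G"
    gm = GenotypeMatrix(sites=site_df, samples=samples, dosages=dosages)

    sexes = dict(cfg.sexes)
    for i, s in enumerate(samples):
        sexes.setdefault(s, "XX" if i % 2 == 0 else "XY")
    truth = SimTruth(
        tree_distance=tree_distances(cfg),
        relatives=list(cfg.relatives),
        planted_roh=list(cfg.planted_roh),
        sexes=sexes,
    )
    return gm, truth


def plant_roh(
    gm: GenotypeMatrix, spec: Sequence[ROHSpec], seed: int = 0
) -> tuple[GenotypeMatrix, list[ROHSpec]]:
    """Force homozygosity inside the given intervals.

    Within each interval the sample's heterozygous calls are replaced by
    a duplicated, uniformly chosen haplotype (dosage 0 or 2); calls
    outside the intervals — and an empty spec — leave the matrix
    bit-identical.  Overlapping intervals for one sample raise.
    """
    by_sample: dict[str, list[ROHSpec]] = {}
    for s in spec:
        by_sample.setdefault(s.sample, []).append(s)
    for sample, specs in by_sample.items():
        specs = sorted(specs, key=lambda s: (s.chrom, s.start))
        for a, b in zip(specs[:-1], specs[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValueError(f"overlapping planted intervals for {sample}")

    rng = np.random.default_rng(seed)
    dosages = gm.dosages.copy()
    chrom = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    for s in spec:
        j = gm.sample_index(s.sample)
        m = (chrom == s.chrom) & (pos >= s.start) & (pos <= s.end)
        idx = np.flatnonzero(m)
        if idx.size == 0:
            raise ValueError(f"planted interval {s} covers no sites")
        d = dosages[idx, j]
        het = d == 1
        d[het] = rng.integers(0, 2, int(het.sum()), dtype=np.int8) * 2
        dosages[idx, j] = d
    out = GenotypeMatrix(
        sites=gm.sites.copy(), samples=list(gm.samples), dosages=dosages,
        ploidy=gm.ploidy,
    )
    return out, list(spec)


# ---------------------------------------------------------------------------
# Coverage


def simulate_coverage(
    sexes: Mapping[str, str],
    depth: float = 2.0,
    n_autosomes: int = 26,
    autosome_length: int = 50_000_000,
    x_length: int = 50_000_000,
    x_mappability: float = 0.74,
    seed: int = 0,
) -> list[CoverageProfile]:
    """Per-chromosome aligned-base counts ~ Poisson(depth x length).

    chrX expected depth is scaled by ``x_mappability`` (assembly
    incompleteness depresses X coverage even in XX individuals; the
    default matches an observed female Rx cluster mean of 0.74) and
    additionally halved for XY samples.  ``x_mappability=1`` gives the
    idealized Rx of 1 (XX) and 0.5 (XY).
    """
    rng = np.random.default_rng(seed)
    out = []
    for sample in sexes:
        sex = sexes[sample]
        chroms: dict[str, tuple[int, int]] = {}
        for i in range(n_autosomes):
            lam = depth * autosome_length
            chroms[f"chr{i + 1}"] = (autosome_length, int(rng.poisson(lam)))
        x_depth = depth * x_mappability * (0.5 if sex == "XY" else 1.0)
        chroms["chrX"] = (x_length, int(rng.poisson(x_depth * x_length)))
        out.append(CoverageProfile(sample=sample, chroms=chroms, chrx="chrX"))
    return out


# ---------------------------------------------------------------------------
# Conservation track and load placements


def simulate_load(
    populations: Mapping[str, Sequence[str]],
    weights: Mapping[str, np.ndarray | None] | None = None,
    n_regions: int = 200,
    n_alleles: int = 200,
    threshold: float = 4.0,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[GerpTrack, DerivedAlleles, dict]:
    """Conservation track plus per-population derived-allele placements.

    Builds ``n_regions`` conserved regions (constant per-base score drawn
    uniformly on (threshold + 0.5, threshold + 5)) separated by
    sub-threshold gaps, then places ``n_alleles`` derived alleles per
    sample across regions with probability proportional to
    ``weight_i * g_i`` (uniform weights by default).  Returns the track,
    a site-level :class:`DerivedAlleles` coding and the truth dict with
    the region scores and each population's weights.
    """
    rng = np.random.default_rng(seed)
    region_scores = rng.uniform(threshold + 0.5, threshold + 5.0, n_regions)
    region_len = rng.integers(20, 60, n_regions)
    gap_len = rng.integers(5, 20, n_regions)

    pos_list, score_list = [], []
    region_bounds = []
    cur = 1
    for g, rl, gl in zip(region_scores, region_len, gap_len):
        # sub-threshold gap before each region
        pos_list.append(np.arange(cur, cur + gl))
        score_list.append(rng.uniform(0.0, threshold - 0.5, gl))
        cur += gl
        pos_list.append(np.arange(cur, cur + rl))
        score_list.append(np.full(rl, g))
        region_bounds.append((cur, cur + int(rl) - 1))
        cur += rl
    pos = np.concatenate(pos_list)
    track = GerpTrack(
        chrom=np.repeat(chrom, pos.size), pos=pos, score=np.concatenate(score_list)
    )

    all_samples: list[str] = [s for pop in populations.values() for s in pop]
    placements: dict[str, dict[int, int]] = {s: {} for s in all_samples}
    used_weights: dict[str, np.ndarray] = {}
    for pop, members in populations.items():
        w = None if weights is None else weights.get(pop)
        w = np.ones(n_regions) if w is None else np.asarray(w, dtype=float)
        if w.size != n_regions:
            raise ValueError("weight vector length must equal n_regions")
        prob = w * region_scores
        prob = prob / prob.sum()
        used_weights[pop] = w
        for s in members:
            counts = rng.multinomial(n_alleles, prob)
            for ri in np.flatnonzero(counts):
                placements[s][ri] = placements[s].get(ri, 0) + int(counts[ri])

    # convert per-region counts to site-level derived dosages (1 or 2)
    site_pos: list[int] = []
    site_counts: dict[str, list[tuple[int, int]]] = {s: [] for s in all_samples}
    for s in all_samples:
        for ri, cnt in placements[s].items():
            lo, hi = region_bounds[ri]
            n_slots = hi - lo + 1
            n_hom = cnt // 2 if cnt <= 2 * n_slots else n_slots
            rem = cnt - 2 * n_hom
            chosen = rng.choice(n_slots, size=min(n_hom + rem, n_slots), replace=False)
            doses = [2] * n_hom + [1] * rem
            for off, dose in zip(chosen, doses):
                site_counts[s].append((lo + int(off), dose))
    all_pos = sorted({p for lst in site_counts.values() for p, _ in lst})
    pos_index = {p: i for i, p in enumerate(all_pos)}
    counts = np.zeros((len(all_pos), len(all_samples)), dtype=np.int8)
    for j, s in enumerate(all_samples):
        for p, dose in site_counts[s]:
            counts[pos_index[p], j] = dose
    derived = DerivedAlleles(
        sites=pd.DataFrame({"chrom": [chrom] * len(all_pos), "pos": all_pos}),
        samples=all_samples,
        counts=counts,
    )
    truth = {"region_scores": region_scores, "weights": used_weights,
             "region_bounds": region_bounds}
    return track, derived, truth


# ---------------------------------------------------------------------------
# mtDNA


def simulate_mtdna(
    tree: dict,
    length: int = 2_000,
    seed: int = 0,
    poisson: bool = True,
) -> tuple[MtAlignment, dict]:
    """Mutate haplotypes along a tree under infinite sites.

    ``tree`` is a nested dict with keys ``name``, ``mutations`` (expected
    count on the branch above the node; Poisson-drawn unless
    ``poisson=False``) and ``children``.  Each mutation hits a distinct
    alignment position and substitutes the base for every tip below its
    branch.  Returns the alignment and a truth dict with realized branch
    counts and exact pairwise difference counts.
    """
    rng = np.random.default_rng(seed)

    # realize mutation counts per branch
    def realize(node: dict) -> int:
        m = node.get("mutations", 0)
        node["_m"] = int(rng.poisson(m)) if poisson else int(m)
        return node["_m"] + sum(realize(c) for c in node["children"])

    tree = copy.deepcopy(tree)
    total = realize(tree)
    if total > length:
        raise ValueError(f"{total} mutations exceed sequence length {length}")
    positions = rng.choice(length, size=total, replace=False)

    bases = np.array(list("ACGT"))
    root_seq = rng.integers(0, 4, length)
    seqs: dict[str, np.ndarray] = {}
    cursor = [0]

    def walk(node: dict, seq: np.ndarray) -> None:
        seq = seq.copy()
        m = node["_m"]
        for _ in range(m):
            p = positions[cursor[0]]
            cursor[0] += 1
            seq[p] = (seq[p] + 1 + rng.integers(0, 3)) % 4
        if not node["children"]:
            seqs[node["name"]] = seq
        for c in node["children"]:
            walk(c, seq)

    walk(tree, root_seq)
    ids = sorted(seqs)
    aln = MtAlignment(ids=ids, seqs=["".join(bases[seqs[i]]) for i in ids])

    # exact pairwise differences from the realized sequences
    pair_diffs = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pair_diffs[(a, b)] = int(np.sum(seqs[a] != seqs[b]))
    n = len(ids)
    mean_pi = (
        sum(pair_diffs.values()) / (n * (n - 1) / 2) / length if n > 1 else 0.0
    )
    truth = {"pair_diffs": pair_diffs, "pi": mean_pi, "n_mutations": total}
    return aln, truth


def star_tree(n_tips: int, mutations_per_tip: float) -> dict:
    """A star topology with a common expected mutation count per tip."""
    return {
        "name": "root", "mutations": 0,
        "children": [
            {"name": f"t{i + 1}", "mutations": mutations_per_tip, "children": []}
            for i in range(n_tips)
        ],
    }
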