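"""Diversity estimators: heterozygosity, pairwise-f3 diversity, mtDNA pi.

Within-population diversity is summarized three ways, mirroring the
autosomal / chrX / mitochondrial compartments of a genome:

* per-individual heterozygosity — heterozygous genotypes per callable site;
* inter-individual diversity — the mean of 1 - f3(outgroup; ind_i, ind_j)
  over member pairs, which rises with within-population coalescence time;
* mitochondrial nucleotide diversity pi — average pairwise differences per
  included alignment site.

Under equal male and female effective sizes the autosome/chrX diversity
ratio is expected at 4/3 (three X chromosomes circulate for every four
autosomes), so deviations below 1.33 indicate reduced male Ne.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from mouflon.variants import GenotypeMatrix, MISSING
from mouflon.fstats import AlleleFreqTable, BlockScheme, f3

AUTOSOME_X_EXPECTATION = 4.0 / 3.0

_MISSING_BASES = {"N", "-"}


@dataclass
class DiversityEstimate:
    """A diversity value with its scope, compartment and support size."""

    scope: str  # sample id or population label
    compartment: str  # "autosomes" | "chrX" | "mtDNA"
    value: float
    n_sites: int = 0
    n_pairs: int = 0


@dataclass
class MtAlignment:
    """Equal-length mtDNA haplotype alignment over {A, C, G, T, N, -}."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ValueError("empty alignment")
        L = len(self.seqs[0])
        if L == 0 or any(len(s) != L for s in self.seqs):
            raise ValueError("sequences must share a positive common length")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @classmethod
    def from_fasta(cls, path: str) -> "MtAlignment":
        from Bio import SeqIO

        ids, seqs = [], []
        for rec in SeqIO.parse(path, "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        return cls(ids=ids, seqs=seqs)


def individual_heterozygosity(
    gm: GenotypeMatrix, sample: str, callable_sites: int
) -> DiversityEstimate:
    """Genome-wide heterozygosity: het genotypes over callable sites.

    ``callable_sites`` is the denominator of accessible positions (not
    just variant sites), so the value is a per-base rate comparable
    across samples genotyped on the same site set.
    """
    if callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    d = gm.sample_dosages(sample)
    n_het = int((d == 1).sum())
    return DiversityEstimate(
        scope=sample,
        compartment="autosomes",
        value=n_het / callable_sites,
        n_sites=callable_sites,
    )


def pairwise_f3_diversity(
    ft: AlleleFreqTable,
    members: Sequence[str],
    outgroup: str,
    blocks: BlockScheme,
    compartment: str = "autosomes",
    population: str = "",
) -> DiversityEstimate:
    """Within-population diversity as mean pairwise 1 - outgroup-f3.

    Each member must be present in the frequency table as its own
    population (single-individual populations).  Undefined pairs are
    skipped with a warning; zero usable pairs is an error.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("need at least 2 members")
    vals = []
    for a, b in itertools.combinations(sorted(members), 2):
        try:
            res = f3(ft, outgroup, a, b, blocks)
        except ValueError as exc:
            warnings.warn(f"skipping undefined pair ({a}, {b}): {exc}")
            continue
        vals.append(1.0 - res.estimate)
    if not vals:
        raise ValueError("no usable member pairs")
    return DiversityEstimate(
        scope=population or ",".join(sorted(members)),
        compartment=compartment,
        value=float(np.mean(vals)),
        n_pairs=len(vals),
    )


def mtdna_pi(aln: MtAlignment, per_pair_length: bool = False) -> DiversityEstimate:
    """Average pairwise nucleotide differences (pi) on an mtDNA alignment.

    A site is included iff it is non-missing (not N or -) in at least two
    individuals and carries at most two distinct bases among non-missing
    calls.  pi = [ sum_{i<j} pi_ij / (n(n-1)/2) ] / L with L the number of
    included sites; pairs missing a member at a site contribute 0 there.
    ``per_pair_length=True`` switches to averaging pi_ij / L_ij with L_ij
    the pair's jointly non-missing included sites.
    """
    n = len(aln.ids)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.frombuffer("".join(aln.seqs).encode(), dtype="S1").reshape(n, aln.length)
    valid = ~np.isin(arr, [b"N", b"-"])
    n_valid = valid.sum(axis=0)
    # distinct non-missing bases per column
    n_distinct = np.zeros(aln.length, dtype=int)
    for base in (b"A", b"C", b"G", b"T"):
        n_distinct += ((arr == base) & valid).any(axis=0)
    included = (n_valid >= 2) & (n_distinct <= 2) & (n_distinct >= 1)
    L = int(included.sum())
    if L == 0:
        raise ValueError("no included sites")

    sub = arr[:, included]
    sub_valid = valid[:, included]
    total = 0.0
    n_pairs = n * (n - 1) // 2
    for i, j in itertools.combinations(range(n), 2):
        both = sub_valid[i] & sub_valid[j]
        diffs = int(((sub[i] != sub[j]) & both).sum())
        if per_pair_length:
            L_ij = int(both.sum())
            total += diffs / L_ij if L_ij else 0.0
        else:
            total += diffs
    if per_pair_length:
        value = total / n_pairs
    else:
        value = (total / n_pairs) / L
    return DiversityEstimate(
        scope=",".join(aln.ids), compartment="mtDNA", value=value, n_sites=L,
        n_pairs=n_pairs,
    )


def autosome_x_ratio(div_aut: float, div_x: float) -> tuple[float, float]:
    """Autosome/chrX diversity ratio and its neutral expectation 4/3.

    Returns ``(div_aut / div_x, 4/3)``; the expectation assumes equal
    male and female effective population sizes.
    """
    if div_x <= 0:
        raise ValueError("chrX diversity must be positive")
    return div_aut / div_x, AUTOSOME_X_EXPECTATION
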