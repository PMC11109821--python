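"""GERP-weighted relative mutation load (RML).

Conserved regions are maximal runs of consecutive reference bases whose
conservation score (GERP rejected-substitution units) exceeds a threshold
(strictly > 4 by default).  Derived alleles are polarized against an
outgroup genome whose homozygous allele defines the ancestral state.  The
relative mutation load of genome x is then

    RML_x = sum_i n_i g_i / N_x

with n_i the derived-allele count of x inside conserved region i, g_i the
region's score (mean per-base score by default) and N_x the total derived
alleles of x in conserved regions — a derived-allele-weighted mean GERP
score, higher when a genome's derived variants sit in more constrained
sequence.  Heterozygous sites count one derived allele, homozygous two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from mouflon.variants import GenotypeMatrix, MISSING


@dataclass
class GerpTrack:
    """Per-base conservation scores: parallel chrom/pos/score arrays."""

    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    score: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.score = np.asarray(self.score, dtype=float)
        if not (len(self.chrom) == len(self.pos) == len(self.score)):
            raise ValueError("track arrays must have equal length")

    @classmethod
    def from_bed(cls, path: str) -> "GerpTrack":
        """Read a BED-like score track (chrom, start0, end, score).

        Intervals are expanded to per-base entries; BED half-open
        coordinates convert to 1-based inclusive here at the boundary.
        """
        df = pd.read_csv(
            path, sep="\t", names=["chrom", "start", "end", "score"], comment="#"
        )
        chroms, poss, scores = [], [], []
        for r in df.itertuples(index=False):
            n = int(r.end) - int(r.start)
            chroms.append(np.repeat(str(r.chrom), n))
            poss.append(np.arange(int(r.start) + 1, int(r.end) + 1))
            scores.append(np.full(n, float(r.score)))
        return cls(
            chrom=np.concatenate(chroms) if chroms else np.array([], dtype=str),
            pos=np.concatenate(poss) if poss else np.array([], dtype=np.int64),
            score=np.concatenate(scores) if scores else np.array([]),
        )


@dataclass
class ConservedRegion:
    """A maximal run of consecutive bases above the score threshold."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    g: float  # region score (mean per-base by default)
    n_bases: int


@dataclass
class DerivedAlleles:
    """Per-site derived-allele counts after outgroup polarization."""

    sites: pd.DataFrame  # chrom, pos
    samples: list[str]
    counts: np.ndarray  # (n_sites, n_samples), 0/1/2, MISSING for no call
    n_dropped_polymorphic: int = 0

    def sample_counts(self, sample: str) -> np.ndarray:
        return self.counts[:, self.samples.index(sample)]


@dataclass
class RMLResult:
    """Relative mutation load for one genome."""

    sample: str
    rml: float
    n_derived: int  # N: derived alleles entering the denominator
    k_used: int  # regions contributing at least one derived allele


def conserved_regions(
    track: GerpTrack,
    threshold: float = 4.0,
    aggregate: Literal["mean", "max", "sum"] = "mean",
) -> list[ConservedRegion]:
    """Maximal runs of consecutive positions with score > threshold.

    Positions must be sorted within chromosomes; a run breaks where the
    position increment is not 1 or the score drops to <= threshold
    (strict inequality keeps a base scoring exactly at the threshold out).
    """
    regions: list[ConservedRegion] = []
    if len(track.pos) == 0:
        return regions
    above = track.score > threshold
    same_chrom = np.concatenate([[False], track.chrom[1:] == track.chrom[:-1]])
    adjacent = np.concatenate([[False], np.diff(track.pos) == 1])
    # a new run starts wherever `above` holds but continuity fails
    run_start = above & ~(same_chrom & adjacent & np.concatenate([[False], above[:-1]]))
    run_ids = np.cumsum(run_start)
    agg_fn = {"mean": np.mean, "max": np.max, "sum": np.sum}[aggregate]
    for rid in np.unique(run_ids[above]):
        idx = np.flatnonzero(above & (run_ids == rid))
        regions.append(
            ConservedRegion(
                chrom=str(track.chrom[idx[0]]),
                start=int(track.pos[idx[0]]),
                end=int(track.pos[idx[-1]]),
                g=float(agg_fn(track.score[idx])),
                n_bases=len(idx),
            )
        )
    return regions


def polarize_derived(gm: GenotypeMatrix, outgroup_sample: str) -> DerivedAlleles:
    """Code genotypes as derived-allele counts using the outgroup allele.

    The ancestral allele is the outgroup's homozygous allele; sites where
    the outgroup is heterozygous (polymorphic) or missing are dropped and
    tallied.  Derived count per sample: dosage if the outgroup is
    homozygous reference, 2 - dosage if homozygous alternate; missing
    genotypes stay missing.
    """
    og = gm.sample_dosages(outgroup_sample)
    keep = (og == 0) | (og == 2)
    n_dropped = int(np.sum((og == 1)))
    sub = gm.subset_sites(keep)
    og_sub = sub.sample_dosages(outgroup_sample)
    counts = sub.dosages.astype(np.int8).copy()
    flip = og_sub == 2
    valid = counts != MISSING
    counts[flip] = np.where(valid[flip], 2 - counts[flip], MISSING)
    return DerivedAlleles(
        sites=sub.sites[["chrom", "pos"]].reset_index(drop=True),
        samples=list(sub.samples),
        counts=counts,
        n_dropped_polymorphic=n_dropped,
    )


def rml(
    derived: DerivedAlleles,
    regions: Sequence[ConservedRegion],
    sample: str,
    genome_wide_n: bool = False,
) -> RMLResult:
    """Relative mutation load of one genome over conserved regions.

    RML = sum_i n_i g_i / N.  By default N counts derived alleles inside
    conserved regions, making RML a weighted mean of region scores
    (bounded by their min and max); ``genome_wide_n=True`` instead divides
    by the genome-wide derived-allele total.  N == 0 raises.
    """
    c = derived.sample_counts(sample).astype(np.int64)
    c = np.where(c == MISSING, 0, c)
    chrom = derived.sites["chrom"].to_numpy()
    pos = derived.sites["pos"].to_numpy()

    weighted = 0.0
    n_in_regions = 0
    k_used = 0
    by_chrom: dict[str, np.ndarray] = {}
    for ch in np.unique(chrom):
        by_chrom[str(ch)] = np.flatnonzero(chrom == ch)
    for reg in regions:
        idx = by_chrom.get(reg.chrom)
        if idx is None:
            continue
        p = pos[idx]
        lo = np.searchsorted(p, reg.start, side="left")
        hi = np.searchsorted(p, reg.end, side="right")
        n_i = int(c[idx[lo:hi]].sum())
        if n_i > 0:
            weighted += n_i * reg.g
            n_in_regions += n_i
            k_used += 1
    n_total = int(c.sum())
    N = n_total if genome_wide_n else n_in_regions
    if N == 0:
        raise ValueError(f"no derived alleles for {sample} (N == 0); RML undefined")
    return RMLResult(sample=sample, rml=weighted / N, n_derived=N, k_used=k_used)


def regions_to_bed(regions: Sequence[ConservedRegion], path: str) -> None:
    """Write conserved regions as BED (0-based half-open) with scores."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.g:.6g}\n")
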