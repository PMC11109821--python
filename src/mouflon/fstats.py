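"""Outgroup-f3 and f4 statistics with block-jackknife standard errors.

f3(O; A, B) = E[(o - a)(o - b)] measures the shared drift of A and B
relative to the outgroup O: larger values mean a closer relationship, so
1 - f3 behaves as a genetic distance once frequencies are polarized by a
distant outgroup.  f4(A, B; C, D) = E[(a - b)(c - d)] is zero under any
tree in which {A,B} and {C,D} fall on opposite sides of an internal edge,
and deviates from zero under gene flow across that edge.

Standard errors come from a weighted delete-one-block jackknife over
contiguous genomic blocks (5 Mb physical spans by default), which absorbs
linkage between nearby sites; the chunked bootstrap used for tree support
resamples fixed-size SNP chunks (30,000 by default) with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mouflon.variants import MISSING, GenotypeMatrix
from mouflon.structure import DistanceMatrix


@dataclass
class AlleleFreqTable:
    """Per-population alt-allele frequencies and observed allele counts.

    ``freq[p, s]`` is defined (non-NaN) only where ``count[p, s] > 0``;
    a diploid genotype contributes 2 alleles, a pseudo-haploid call 1.
    """

    populations: list[str]
    freq: np.ndarray  # (n_pops, n_sites) float64, NaN where count == 0
    count: np.ndarray  # (n_pops, n_sites) int32 observed allele counts
    sites: pd.DataFrame  # chrom, pos per site (for block construction)

    def pop_index(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(
                f"population {pop!r} unknown; available: {self.populations}"
            ) from None


@dataclass
class BlockScheme:
    """A partition of the site list into contiguous blocks.

    ``block_id[s]`` assigns every site to one block; ids are consecutive
    integers starting at 0 and no block is empty.
    """

    block_id: np.ndarray
    n_blocks: int

    @classmethod
    def by_physical_span(cls, sites: pd.DataFrame, span_bp: int = 5_000_000) -> "BlockScheme":
        """Blocks of fixed physical span per chromosome (default 5 Mb)."""
        chrom = sites["chrom"].to_numpy()
        pos = sites["pos"].to_numpy()
        raw = np.zeros(len(sites), dtype=np.int64)
        offset = 0
        for c in pd.unique(chrom):
            m = chrom == c
            raw[m] = offset + (pos[m] - 1) // span_bp
            offset = raw[m].max() + 1 if m.any() else offset
        return cls._from_raw(raw)

    @classmethod
    def by_snp_count(cls, n_sites: int, chunk_size: int) -> "BlockScheme":
        """Blocks of a fixed SNP count; a final partial chunk is kept."""
        if chunk_size <= 0:
            raise ValueError("chunk_size must be positive")
        if chunk_size > n_sites:
            raise ValueError("chunk_size exceeds the number of sites")
        raw = np.arange(n_sites) // chunk_size
        return cls._from_raw(raw)

    @classmethod
    def _from_raw(cls, raw: np.ndarray) -> "BlockScheme":
        _, dense = np.unique(raw, return_inverse=True)
        return cls(block_id=dense.astype(np.int64), n_blocks=int(dense.max()) + 1)


@dataclass
class FStatResult:
    """An f3 or f4 estimate with its jackknife uncertainty."""

    kind: str  # "f3" | "f4"
    pops: tuple[str, ...]
    estimate: float
    se: float  # NaN when fewer than 2 non-empty blocks
    z: float
    n_blocks: int
    n_sites: int


def allele_frequencies(
    gm: GenotypeMatrix, grouping: Mapping[str, str]
) -> AlleleFreqTable:
    """Tally per-population alt-allele frequencies from a genotype matrix.

    ``grouping`` maps each included sample to a population label; a single
    individual may form its own population.  Pseudo-haploid calls
    contribute one allele each, diploid calls two.
    """
    pops: list[str] = []
    members: dict[str, list[int]] = {}
    for sample, pop in grouping.items():
        j = gm.sample_index(sample)
        members.setdefault(pop, []).append(j)
        if pop not in pops:
            pops.append(pop)
    for pop in pops:
        if not members[pop]:
            raise ValueError(f"population {pop!r} has no members")

    per_call = 1 if gm.ploidy == "pseudohaploid" else 2
    n_sites = gm.n_sites
    freq = np.full((len(pops), n_sites), np.nan)
    count = np.zeros((len(pops), n_sites), dtype=np.int32)
    for i, pop in enumerate(pops):
        d = gm.dosages[:, members[pop]]
        valid = d != MISSING
        alt = np.where(valid, d, 0).sum(axis=1)
        if gm.ploidy == "pseudohaploid":
            alt = alt // 2  # dosage 2 encodes a single alt allele
        cnt = per_call * valid.sum(axis=1)
        count[i] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[i] = np.where(cnt > 0, alt / np.maximum(cnt, 1), np.nan)
    return AlleleFreqTable(
        populations=pops, freq=freq, count=count, sites=gm.sites[["chrom", "pos"]].copy()
    )


# ---------------------------------------------------------------------------
# Jackknife machinery


def _weighted_jackknife(
    terms: np.ndarray, block_id: np.ndarray, n_blocks_total: int
) -> tuple[float, float, int]:
    """Weighted delete-one-block jackknife for a mean of per-site terms.

    Blocks are weighted by their usable site counts (the final chunk of a
    genome is typically short).  Returns (estimate, se, n_nonempty_blocks);
    se is NaN when fewer than two blocks contain usable sites.
    """
    n = terms.size
    est = float(terms.mean())
    sums = np.bincount(block_id, weights=terms, minlength=n_blocks_total)
    sizes = np.bincount(block_id, minlength=n_blocks_total).astype(float)
    nonempty = sizes > 0
    sums, sizes = sums[nonempty], sizes[nonempty]
    g = int(nonempty.sum())
    if g < 2:
        return est, float("nan"), g
    total = sums.sum()
    loo = (total - sums) / (n - sizes)  # delete-one-block means
    h = n / sizes
    theta_j = g * est - ((1.0 - sizes / n) * loo).sum()
    tau = h * est - (h - 1.0) * loo
    var = float(np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g)
    return est, float(np.sqrt(var)), g


def _fstat(
    kind: str,
    pops: tuple[str, ...],
    terms: np.ndarray,
    used: np.ndarray,
    blocks: BlockScheme,
) -> FStatResult:
    if not used.any():
        raise ValueError(f"no usable sites for {kind}{pops}")
    t = terms[used]
    bid = blocks.block_id[used]
    est, se, g = _weighted_jackknife(t, bid, blocks.n_blocks)
    if g < 2:
        warnings.warn(f"{kind}{pops}: fewer than 2 non-empty blocks; SE undefined")
    z = est / se if se and np.isfinite(se) and se > 0 else float("nan")
    return FStatResult(
        kind=kind, pops=pops, estimate=est, se=se, z=z, n_blocks=g, n_sites=int(used.sum())
    )


def f3(
    ft: AlleleFreqTable,
    target: str,
    a: str,
    b: str,
    blocks: BlockScheme,
    corrected: bool = False,
) -> FStatResult:
    """Outgroup-f3(target; A, B): mean of (o - a)(o - b) over usable sites.

    A site is used iff all three populations have observed alleles there
    (complete-case selection).  In corrected mode the target's sampling
    noise h_O / n_O is subtracted per site, with h_O the unbiased
    heterozygosity estimate 2 a_O (n_O - a_O) / (n_O (n_O - 1)); this
    requires n_O >= 2, so a pseudo-haploid target is rejected.
    """
    io, ia, ib = (ft.pop_index(p) for p in (target, a, b))
    o, fa, fb = ft.freq[io], ft.freq[ia], ft.freq[ib]
    used = (ft.count[io] > 0) & (ft.count[ia] > 0) & (ft.count[ib] > 0)
    terms = (o - fa) * (o - fb)
    if corrected:
        n_o = ft.count[io].astype(float)
        if np.any(used & (n_o < 2)):
            raise ValueError(
                "corrected f3 requires >= 2 observed alleles in the target "
                "(pseudo-haploid target not allowed)"
            )
        alt_o = np.round(o * n_o)
        with np.errstate(invalid="ignore", divide="ignore"):
            h_o = 2.0 * alt_o * (n_o - alt_o) / (n_o * (n_o - 1.0))
        terms = terms - h_o / n_o
    terms = np.where(used, terms, 0.0)
    return _fstat("f3", (target, a, b), terms, used, blocks)


def f4(
    ft: AlleleFreqTable,
    a: str,
    b: str,
    c: str,
    d: str,
    blocks: BlockScheme,
) -> FStatResult:
    """f4(A, B; C, D): mean of (a - b)(c - d) over complete-case sites."""
    idx = [ft.pop_index(p) for p in (a, b, c, d)]
    fa, fb, fc, fd = (ft.freq[i] for i in idx)
    used = np.all(ft.count[idx] > 0, axis=0)
    terms = np.where(used, (fa - fb) * (fc - fd), 0.0)
    return _fstat("f4", (a, b, c, d), terms, used, blocks)


def distance_matrix(
    ft: AlleleFreqTable,
    populations: Sequence[str],
    outgroup: str,
    blocks: BlockScheme,
) -> DistanceMatrix:
    """Pairwise 1 - outgroup-f3 distance matrix over ``populations``.

    D[p, q] = 1 - f3(outgroup; p, q) for p != q, symmetric with a zero
    diagonal.  Raises naming the pair if any f3 has no usable sites.
    """
    pops = list(populations)
    if len(pops) < 3:
        raise ValueError("need at least 3 populations for a distance matrix")
    n = len(pops)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                res = f3(ft, outgroup, pops[i], pops[j], blocks)
            except ValueError as exc:
                raise ValueError(
                    f"f3 undefined for pair ({pops[i]}, {pops[j]}): {exc}"
                ) from exc
            D[i, j] = D[j, i] = 1.0 - res.estimate
    return DistanceMatrix(labels=pops, matrix=D)


def bootstrap_distance_matrices(
    gm: GenotypeMatrix,
    grouping: Mapping[str, str],
    populations: Sequence[str],
    outgroup: str,
    chunk_size: int = 30_000,
    reps: int = 500,
    seed: int = 0,
    resample: bool = True,
) -> list[DistanceMatrix]:
    """Chunked-bootstrap replicates of the 1 - f3 distance matrix.

    The genotype data are divided into consecutive chunks of
    ``chunk_size`` SNPs (the final partial chunk is kept as its own
    chunk); each replicate draws chunks with replacement and recomputes
    every pairwise outgroup-f3 on the resampled concatenation.  With
    ``resample=False`` the identity draw is used, so a single replicate
    equals the point-estimate matrix.  Deterministic under ``seed``.
    """
    ft = allele_frequencies(gm, grouping)
    n_sites = ft.freq.shape[1]
    if chunk_size > n_sites:
        raise ValueError("chunk_size exceeds the number of sites")
    scheme = BlockScheme.by_snp_count(n_sites, chunk_size)
    n_chunks = scheme.n_blocks
    if n_chunks < 2:
        raise ValueError("need at least 2 chunks to bootstrap")

    pops = list(populations)
    io = ft.pop_index(outgroup)
    pairs = [(i, j) for i in range(len(pops)) for j in range(i + 1, len(pops))]
    # Per-chunk sums of the per-site f3 terms and usable-site counts per
    # pair; a replicate's f3 is then a ratio of resampled chunk sums.
    chunk_sums = np.zeros((len(pairs), n_chunks))
    chunk_counts = np.zeros((len(pairs), n_chunks))
    o = ft.freq[io]
    for k, (i, j) in enumerate(pairs):
        pi, pj = ft.pop_index(pops[i]), ft.pop_index(pops[j])
        used = (ft.count[io] > 0) & (ft.count[pi] > 0) & (ft.count[pj] > 0)
        terms = np.where(used, (o - ft.freq[pi]) * (o - ft.freq[pj]), 0.0)
        chunk_sums[k] = np.bincount(scheme.block_id, weights=terms, minlength=n_chunks)
        chunk_counts[k] = np.bincount(
            scheme.block_id, weights=used.astype(float), minlength=n_chunks
        )

    rng = np.random.default_rng(seed)
    out: list[DistanceMatrix] = []
    n = len(pops)
    for _ in range(reps):
        if resample:
            draw = rng.integers(0, n_chunks, size=n_chunks)
        else:
            draw = np.arange(n_chunks)
        mult = np.bincount(draw, minlength=n_chunks).astype(float)
        sums = chunk_sums @ mult
        counts = chunk_counts @ mult
        if np.any(counts == 0):
            raise ValueError("bootstrap replicate with zero usable sites for a pair")
        vals = 1.0 - sums / counts
        D = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            D[i, j] = D[j, i] = vals[k]
        out.append(DistanceMatrix(labels=pops, matrix=D))
    return out


def fstat_table(results: Sequence[FStatResult]) -> pd.DataFrame:
    """Tabulate f-statistic results, one row per statistic."""
    return pd.DataFrame(
        {
            "kind": [r.kind for r in results],
            "pops": [":".join(r.pops) for r in results],
            "estimate": [r.estimate for r in results],
            "se": [r.se for r in results],
            "z": [r.z for r in results],
            "n_blocks": [r.n_blocks for r in results],
            "n_sites": [r.n_sites for r in results],
        }
    )
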