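"""Runs of homozygosity: sliding-window calling, F_ROH, inbreeding dating.

The caller reproduces the classic SNP-window scheme: a window of
``window_snp`` consecutive SNPs passes if it contains at most
``window_het`` heterozygous and ``window_missing`` missing calls; a SNP is
ROH-eligible when the fraction of passing windows covering it reaches
``window_hit_threshold``; maximal eligible runs are trimmed to their
outermost homozygous SNPs, split at large gaps, and kept if they satisfy
the SNP-count, length and density minima.  Defaults correspond to a
minimum ROH length of 0.5 Mb.

The age of the inbreeding event producing ROH of length L (in Mb) is
estimated as g = 100 / (2 r L) generations, with r the recombination rate
in cM/Mb: longer tracts are broken up faster by recombination, so they
reflect more recent common ancestors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mouflon.variants import GenotypeMatrix, MISSING

#: size classes in Mb, half-open [low, high)
SIZE_CLASSES = ((0.5, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 5.0))


@dataclass
class ROHParams:
    """Sliding-window ROH calling parameters (lengths in kb)."""

    window_snp: int = 50
    window_het: int = 1
    min_snp: int = 30
    min_kb: float = 500.0
    density_kb_per_snp: float = 30.0
    window_missing: int = 5
    window_hit_threshold: float = 0.05
    max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("window_snp", "window_het", "min_snp", "min_kb",
                     "density_kb_per_snp", "window_hit_threshold", "max_gap_kb"):
            if getattr(self, name) <= 0 and name not in ("window_het",):
                raise ValueError(f"{name} must be positive")
        if self.window_het < 0 or self.window_missing < 0:
            raise ValueError("window allowances must be non-negative")


@dataclass
class ROHSegment:
    """One called homozygous tract (1-based inclusive coordinates)."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass
class ROHSummary:
    """Per-sample aggregation of called segments."""

    sample: str
    n_segments: int
    total_length_bp: int
    f_roh: float
    class_counts: dict[str, int]
    mean_length_mb: float


def call_roh(
    gm: GenotypeMatrix, sample: str, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Call ROH segments for one sample with the sliding-window scheme."""
    params = params or ROHParams()
    d_all = gm.sample_dosages(sample)
    chroms = gm.sites["chrom"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy()
    segments: list[ROHSegment] = []
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        segments.extend(
            _call_chrom(sample, str(chrom), pos_all[m], d_all[m], params)
        )
    return segments


def _call_chrom(
    sample: str, chrom: str, pos: np.ndarray, d: np.ndarray, p: ROHParams
) -> list[ROHSegment]:
    n = len(pos)
    ws = p.window_snp
    if n < ws:
        warnings.warn(f"{chrom}: fewer than {ws} SNPs; no calls")
        return []
    het = (d == 1).astype(np.int32)
    mis = (d == MISSING).astype(np.int32)
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(mis)])
    n_win = n - ws + 1
    win_het = ch[ws:] - ch[:-ws]
    win_mis = cm[ws:] - cm[:-ws]
    win_pass = ((win_het <= p.window_het) & (win_mis <= p.window_missing)).astype(
        np.int32
    )
    # hit rate per SNP: passing windows covering it / windows covering it
    cp = np.concatenate([[0], np.cumsum(win_pass)])
    i = np.arange(n)
    w_lo = np.maximum(0, i - ws + 1)
    w_hi = np.minimum(i, n_win - 1)
    covering = (w_hi - w_lo + 1).astype(float)
    hits = cp[w_hi + 1] - cp[w_lo]
    eligible = hits / covering >= p.window_hit_threshold

    hom = (d == 0) | (d == 2)
    segments: list[ROHSegment] = []
    for lo, hi in _true_runs(eligible):
        # trim to outermost homozygous SNPs
        idx = np.arange(lo, hi + 1)
        hom_idx = idx[hom[idx]]
        if hom_idx.size == 0:
            continue
        lo_t, hi_t = int(hom_idx[0]), int(hom_idx[-1])
        # split at physical gaps larger than max_gap_kb
        run_pos = pos[lo_t : hi_t + 1]
        gaps = np.diff(run_pos)
        breaks = np.flatnonzero(gaps > p.max_gap_kb * 1000.0)
        starts = np.concatenate([[lo_t], lo_t + breaks + 1])
        ends = np.concatenate([lo_t + breaks, [hi_t]])
        for s_i, e_i in zip(starts, ends):
            # re-trim each piece to homozygous endpoints
            piece = np.arange(s_i, e_i + 1)
            piece_hom = piece[hom[piece]]
            if piece_hom.size == 0:
                continue
            s_t, e_t = int(piece_hom[0]), int(piece_hom[-1])
            n_snps = e_t - s_t + 1
            length = int(pos[e_t] - pos[s_t] + 1)
            if n_snps < p.min_snp:
                continue
            if length < p.min_kb * 1000.0:
                continue
            if length / n_snps > p.density_kb_per_snp * 1000.0:
                continue
            segments.append(
                ROHSegment(
                    sample=sample, chrom=chrom, start=int(pos[s_t]),
                    end=int(pos[e_t]), n_snps=n_snps,
                )
            )
    return segments


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(a), int(b) - 1) for a, b in zip(edges[::2], edges[1::2])]


def f_roh(segments: Sequence[ROHSegment], autosomal_genome_bp: int) -> float:
    """F_ROH: summed segment length over the autosomal genome size.

    Segments must be disjoint within each (sample, chromosome);
    overlapping segments indicate a caller defect and raise.
    """
    if autosomal_genome_bp <= 0:
        raise ValueError("autosomal_genome_bp must be positive")
    by_key: dict[tuple[str, str], list[ROHSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample, seg.chrom), []).append(seg)
    total = 0
    for key, segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs[:-1], segs[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping segments on {key}")
        total += sum(s.length_bp for s in segs)
    return total / autosomal_genome_bp


@dataclass
class InbreedingTime:
    """Generations (raw and rounded) and years since the common ancestor."""

    generations: float
    generations_rounded: int
    years: float


def inbreeding_time(
    length_mb: float, r_cm_per_mb: float = 1.5, gen_years: float = 3.0
) -> InbreedingTime:
    """Date the inbreeding event for ROH of a given length.

    g = 100 / (2 r L) generations for tract length L in Mb and
    recombination rate r in cM/Mb; years = g * generation time.
    """
    if length_mb <= 0 or r_cm_per_mb <= 0 or gen_years <= 0:
        raise ValueError("length, recombination rate and generation time must be positive")
    g = 100.0 / (2.0 * r_cm_per_mb * length_mb)
    return InbreedingTime(
        generations=g, generations_rounded=int(round(g)), years=g * gen_years
    )


def classify_sizes(
    segments: Sequence[ROHSegment],
    sample: str = "",
    autosomal_genome_bp: int | None = None,
) -> ROHSummary:
    """Bin segments into the size classes 0.5-1, 1-2, 2-3, 3-5 and >=5 Mb.

    Classes are half-open [low, high) Mb; segments of at least 5 Mb fall
    in the overflow class.  F_ROH is filled in when a genome size is
    given, otherwise NaN.
    """
    counts = {f"{lo:g}-{hi:g}Mb": 0 for lo, hi in SIZE_CLASSES}
    counts[">=5Mb"] = 0
    lengths = []
    for seg in segments:
        mb = seg.length_mb
        lengths.append(mb)
        placed = False
        for lo, hi in SIZE_CLASSES:
            if lo <= mb < hi:
                counts[f"{lo:g}-{hi:g}Mb"] += 1
                placed = True
                break
        if not placed and mb >= 5.0:
            counts[">=5Mb"] += 1
    total_bp = int(sum(s.length_bp for s in segments))
    froh = (
        f_roh(segments, autosomal_genome_bp)
        if autosomal_genome_bp
        else float("nan")
    )
    return ROHSummary(
        sample=sample or (segments[0].sample if segments else ""),
        n_segments=len(segments),
        total_length_bp=total_bp,
        f_roh=froh,
        class_counts=counts,
        mean_length_mb=float(np.mean(lengths)) if lengths else 0.0,
    )


def segments_table(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    """Per-segment table (sample, chrom, start, end, n_snps, kb)."""
    return pd.DataFrame(
        {
            "sample": [s.sample for s in segments],
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "kb": [s.length_bp / 1000.0 for s in segments],
        }
    )
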