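"""Sample-level QC: coverage-based genetic sexing and mismatch kinship.

Genetic sex is inferred from Rx, the ratio of chrX coverage to mean
autosomal coverage: roughly 1 for XX and 0.5 for XY with a complete
assembly, lower in practice.  A sample is called XX when
Rx - 1.96 SE > 0.65 and XY when Rx + 1.96 SE < 0.5, with the SE taken
over per-autosome ratios; anything between stays unassigned.  k-means on
the observed Rx values is provided as an advisory check of where the two
clusters sit — assignment always uses the configured thresholds.

Kinship is classified from pseudo-haploid pairwise mismatch rates (P0):
P0 is normalized by the population median (an unrelated-pair baseline),
theta = 1 - normalized P0 estimates the kinship coefficient, and pairs
are binned against midpoints of the expected ladder
identical 0.5 / 1st 0.25 / 2nd 0.125 / 3rd 0.0625 / unrelated 0.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mouflon.variants import GenotypeMatrix, MISSING

DEGREES = ("identical", "1st", "2nd", "3rd", "unrelated")


@dataclass
class CoverageProfile:
    """Per-chromosome coverage for one sample.

    ``chroms`` maps chromosome id -> (length_bp, aligned_bases); depth is
    aligned bases per base of chromosome length.
    """

    sample: str
    chroms: dict[str, tuple[int, int]]
    chrx: str = "chrX"

    def __post_init__(self) -> None:
        if self.chrx not in self.chroms:
            raise ValueError(f"chrX id {self.chrx!r} absent from profile")
        if len(self.chroms) < 3:
            raise ValueError("need chrX plus at least 2 autosomes")
        for c, (length, _) in self.chroms.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {c}")

    def depth(self, chrom: str) -> float:
        length, aligned = self.chroms[chrom]
        return aligned / length

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chroms if c != self.chrx]


@dataclass
class RxResult:
    """Rx value with uncertainty and (optionally) a sex call."""

    sample: str
    rx: float
    se: float
    assignment: str = "unassigned"  # XX / XY / unassigned
    n_autosomes: int = 0


@dataclass
class MismatchResult:
    """Pairwise pseudo-haploid mismatch for one sample pair."""

    pair: tuple[str, str]
    p0: float
    window_p0: np.ndarray
    n_windows: int
    n_sites: int


@dataclass
class KinshipResult:
    """Classified kinship for one pair."""

    pair: tuple[str, str]
    p0: float
    normalized_p0: float
    theta: float
    degree: str
    n_windows: int


@dataclass
class KinshipConfig:
    """Expected kinship-coefficient ladder and derived midpoints."""

    window_bp: int = 1_000_000
    expected_theta: tuple[float, ...] = (0.5, 0.25, 0.125, 0.0625, 0.0)

    def __post_init__(self) -> None:
        t = self.expected_theta
        if any(a <= b for a, b in zip(t[:-1], t[1:])):
            raise ValueError("expected theta ladder must be strictly decreasing")

    @property
    def thresholds(self) -> tuple[float, ...]:
        """Midpoints (theta_1 + theta_2)/2 between adjacent ladder rungs."""
        t = self.expected_theta
        return tuple((a + b) / 2.0 for a, b in zip(t[:-1], t[1:]))


# ---------------------------------------------------------------------------
# Sex determination


def compute_rx(profile: CoverageProfile) -> RxResult:
    """Rx = mean over autosomes i of depth(chrX)/depth(autosome_i).

    The SE is sd(ratios)/sqrt(n autosomes).  Autosomes with zero depth
    are dropped with a warning; no usable autosomes is an error.
    """
    dx = profile.depth(profile.chrx)
    ratios = []
    for c in profile.autosomes:
        da = profile.depth(c)
        if da == 0:
            warnings.warn(f"autosome {c} has zero depth; dropped")
            continue
        ratios.append(dx / da)
    if not ratios:
        raise ValueError("no autosome with non-zero depth")
    arr = np.asarray(ratios)
    rx = float(arr.mean())
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return RxResult(sample=profile.sample, rx=rx, se=se, n_autosomes=arr.size)


def assign_sex(
    rx_result: RxResult, xx_threshold: float = 0.65, xy_threshold: float = 0.5
) -> RxResult:
    """Apply the 1.96-SE assignment rule to an Rx estimate.

    XX when rx - 1.96 se > xx_threshold; XY when rx + 1.96 se <
    xy_threshold; otherwise unassigned.
    """
    r = rx_result
    if r.rx - 1.96 * r.se > xx_threshold:
        call = "XX"
    elif r.rx + 1.96 * r.se < xy_threshold:
        call = "XY"
    else:
        call = "unassigned"
    return RxResult(
        sample=r.sample, rx=r.rx, se=r.se, assignment=call, n_autosomes=r.n_autosomes
    )


def kmeans_thresholds(
    rx_values: Sequence[float], k: int = 2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Advisory k-means clustering of Rx values.

    Lloyd's algorithm with farthest-point seeding on the sorted values
    (hence invariant to input order and deterministic under ``seed``).
    Returns (sorted cluster means, suggested cutoffs) where the cutoffs
    are midpoints between adjacent cluster means — for operator review
    only; assignment always uses the configured thresholds.
    """
    vals = np.sort(np.asarray(rx_values, dtype=float))
    if vals.size < 2 * k:
        raise ValueError("need at least 2k values")
    if np.allclose(vals, vals[0]):
        raise ValueError("degenerate input: all values equal (single cluster)")
    rng = np.random.default_rng(seed)
    centers = [vals[rng.integers(vals.size)]]
    while len(centers) < k:
        dists = np.min(np.abs(vals[:, None] - np.asarray(centers)[None, :]), axis=1)
        centers.append(vals[int(np.argmax(dists))])
    centers = np.sort(np.asarray(centers, dtype=float))
    for _ in range(200):
        assign = np.argmin(np.abs(vals[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [vals[assign == j].mean() if (assign == j).any() else centers[j]
             for j in range(k)]
        )
        if np.allclose(new, centers):
            break
        centers = np.sort(new)
    cutoffs = (centers[:-1] + centers[1:]) / 2.0
    return centers, cutoffs


# ---------------------------------------------------------------------------
# Kinship


_window_cache: dict[tuple[int, int], tuple[np.ndarray, int]] = {}


def _window_key(gm: GenotypeMatrix, window_bp: int) -> tuple[np.ndarray, int]:
    """Dense (chrom, window) ids per site, memoized per site table."""
    cache_id = (id(gm.sites), window_bp)
    hit = _window_cache.get(cache_id)
    if hit is not None and hit[0].size == len(gm.sites):
        return hit
    chrom_codes = pd.factorize(gm.sites["chrom"].to_numpy())[0]
    win = (gm.sites["pos"].to_numpy() - 1) // window_bp
    raw = chrom_codes.astype(np.int64) * (int(win.max()) + 1 if win.size else 1) + win
    _, key = np.unique(raw, return_inverse=True)
    key = key.astype(np.int64)
    n_win = int(key.max()) + 1 if key.size else 0
    if len(_window_cache) > 32:
        _window_cache.clear()
    _window_cache[cache_id] = (key, n_win)
    return key, n_win


def pairwise_mismatch(
    ph_gm: GenotypeMatrix,
    pair: tuple[str, str],
    window_bp: int = 1_000_000,
) -> MismatchResult:
    """Windowed pseudo-haploid mismatch rate P0 for one sample pair.

    P0(window) = mismatching / jointly non-missing sites; the genome-wide
    value is the unweighted mean over windows with at least one usable
    site.  Raises when no window is usable.
    """
    if ph_gm.ploidy != "pseudohaploid":
        raise ValueError("pairwise mismatch requires pseudo-haploid genotypes")
    a = ph_gm.sample_dosages(pair[0])
    b = ph_gm.sample_dosages(pair[1])
    both = (a != MISSING) & (b != MISSING)
    mismatch = both & (a != b)

    key, n_win_total = _window_key(ph_gm, window_bp)
    used = np.bincount(key, weights=both.astype(float), minlength=n_win_total)
    mis = np.bincount(key, weights=mismatch.astype(float), minlength=n_win_total)
    ok = used > 0
    if not ok.any():
        raise ValueError(f"no usable windows for pair {pair}")
    window_p0 = mis[ok] / used[ok]
    return MismatchResult(
        pair=pair,
        p0=float(window_p0.mean()),
        window_p0=window_p0,
        n_windows=int(ok.sum()),
        n_sites=int(both.sum()),
    )


def classify_kinship(
    results: Sequence[MismatchResult], cfg: KinshipConfig | None = None
) -> list[KinshipResult]:
    """Classify all pairs of one population from their P0 values.

    P0 is normalized by the median over all supplied pairs (assumed to be
    dominated by unrelated pairs), theta = 1 - normalized P0, and the
    degree is read off the midpoint thresholds of the expected ladder.
    """
    cfg = cfg or KinshipConfig()
    if not results:
        raise ValueError("no pairs supplied")
    med = float(np.median([r.p0 for r in results]))
    if med == 0:
        raise ValueError("median P0 is zero (population of clones?)")
    out = []
    thr = cfg.thresholds
    for r in results:
        norm = r.p0 / med
        theta = 1.0 - norm
        degree = DEGREES[-1]
        for name, t in zip(DEGREES[:-1], thr):
            if theta >= t:
                degree = name
                break
        out.append(
            KinshipResult(
                pair=r.pair, p0=r.p0, normalized_p0=norm, theta=theta,
                degree=degree, n_windows=r.n_windows,
            )
        )
    return out


def prune_relatives(
    kinship: Sequence[KinshipResult],
    max_degree_kept: str = "3rd",
    coverage: Mapping[str, float] | None = None,
) -> list[str]:
    """Greedy exclusion list removing relatedness up to a given degree.

    Repeatedly removes the sample participating in the most remaining
    related pairs (degree at or closer than ``max_degree_kept``); ties
    remove the lower-coverage sample first, then the lexicographically
    first id.  Returns the samples to exclude.
    """
    if max_degree_kept not in DEGREES[:-1]:
        raise ValueError(f"max_degree_kept must be one of {DEGREES[:-1]}")
    cutoff = DEGREES.index(max_degree_kept)
    related = [
        set(k.pair) for k in kinship if DEGREES.index(k.degree) <= cutoff
    ]
    excluded: list[str] = []
    while related:
        counts: dict[str, int] = {}
        for pair in related:
            for s in pair:
                counts[s] = counts.get(s, 0) + 1
        max_n = max(counts.values())
        cands = sorted(s for s, c in counts.items() if c == max_n)
        if coverage:
            cands.sort(key=lambda s: (coverage.get(s, float("inf")), s))
        victim = cands[0]
        excluded.append(victim)
        related = [p for p in related if victim not in p]
    return sorted(excluded)


def read_coverage_tsv(path: str, chrx: str = "chrX") -> list[CoverageProfile]:
    """Read a coverage TSV (sample, chrom, length, aligned_bases)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for sample, grp in df.groupby("sample", sort=True):
        chroms = {
            str(r.chrom): (int(r.length), int(r.aligned_bases))
            for r in grp.itertuples(index=False)
        }
        out.append(CoverageProfile(sample=str(sample), chroms=chroms, chrx=chrx))
    return out
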