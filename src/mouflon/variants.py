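"""Genotype I/O, site filtering, ascertainment and pseudo-haploidization.

The central container is :class:`GenotypeMatrix`: a sites x samples matrix
of diploid alt-allele dosages (0/1/2, ``MISSING`` = -1) with per-site
coordinates, alleles and INFO annotations held in a pandas DataFrame.
Coordinates are 1-based inclusive (VCF convention) throughout; BED-style
interchange converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

#: INFO annotations consumed by the hard site filters.
INFO_FIELDS = ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "DP")

_SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid (or pseudo-haploid) alt-allele dosages.

    Attributes
    ----------
    sites:
        DataFrame with at least ``chrom, pos, ref, alt`` plus optional
        ``qual``, INFO columns and a boolean ``biallelic`` flag.  Rows are
        sorted by (chrom, pos) with no duplicate coordinates.
    samples:
        Ordered sample identifiers, one per dosage column.
    dosages:
        ``(n_sites, n_samples)`` int8 array; values 0/1/2 (0/2 only for
        pseudo-haploid data) and -1 for missing calls.
    ploidy:
        ``"diploid"`` or ``"pseudohaploid"``.
    """

    sites: pd.DataFrame
    samples: list[str]
    dosages: np.ndarray
    ploidy: str = "diploid"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        dup = self.sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos) coordinates in site table")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(
                f"sample {sample!r} not found; available: {', '.join(self.samples)}"
            ) from None

    def sample_dosages(self, sample: str) -> np.ndarray:
        return self.dosages[:, self.sample_index(sample)]

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            dosages=self.dosages[idx],
            ploidy=self.ploidy,
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in keep]
        return GenotypeMatrix(
            sites=self.sites.copy(),
            samples=list(keep),
            dosages=self.dosages[:, idx],
            ploidy=self.ploidy,
        )


@dataclass
class SampleInfo:
    """Per-sample metadata: lineage, outgroup flag, coverage, sex."""

    id: str
    lineage: str
    outgroup: bool = False
    coverage: float = float("nan")
    sex: str = "unknown"  # unknown / XX / XY


@dataclass
class FilterConfig:
    """Hard-filter thresholds for site-level quality control.

    Defaults follow common GATK-style hard filtering for short variants:
    QUAL >= 20, QD >= 2.0, SOR <= 3.0, FS <= 60.0, MQ >= 40.0,
    MQRankSum > -12.5, ReadPosRankSum > -8.0, per-site mean depth within
    [4, 16] inclusive, minor-allele frequency >= 0.05, and a two-sided
    Hardy-Weinberg exact-test p >= 0.001.

    ``required_info`` lists INFO fields whose absence fails a site; absent
    fields not listed there pass their test vacuously.
    """

    min_qual: float = 20.0
    min_qd: float = 2.0
    max_sor: float = 3.0
    max_fs: float = 60.0
    min_mq: float = 40.0
    min_mqranksum: float = -12.5
    min_readposranksum: float = -8.0
    min_depth: float = 4.0
    max_depth: float = 16.0
    min_maf: float = 0.05
    min_hwe_p: float = 0.001
    required_info: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.min_depth < self.max_depth:
            raise ValueError("min_depth must be < max_depth")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(
    path: str,
    sample_subset: Sequence[str] | None = None,
    sort_sites: bool = True,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` of alt-allele dosages.

    Multiallelic records are retained with ``biallelic=False`` so the
    filter stage can drop them explicitly; their dosage counts any
    non-reference allele.  Missing genotypes become ``MISSING``.  Sites
    arriving out of order are re-sorted deterministically by (chrom, pos)
    when ``sort_sites`` is true, otherwise an error is raised.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    available = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in available]
        if missing:
            raise KeyError(
                f"samples {missing} absent from VCF; available: {available}"
            )
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    rows = []
    dosage_rows = []
    for var in vcf:
        alts = [a for a in (var.ALT or []) if a is not None]
        # gts012: 0/1/2 = dosage of non-ref, 3 = missing
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        row = {
            "chrom": var.CHROM,
            "pos": var.POS,
            "ref": var.REF,
            "alt": ",".join(alts) if alts else ".",
            "qual": var.QUAL if var.QUAL is not None else np.nan,
            "biallelic": len(alts) == 1,
        }
        for name in INFO_FIELDS:
            val = var.INFO.get(name)
            row[name] = float(val) if val is not None else np.nan
        rows.append(row)
        dosage_rows.append(gt)
    vcf.close()

    sites = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "qual", "biallelic", *INFO_FIELDS],
    )
    dosages = (
        np.vstack(dosage_rows)
        if dosage_rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(sites))):
        if not sort_sites:
            raise ValueError("VCF records out of coordinate order")
        sites = sites.iloc[order].reset_index(drop=True)
        dosages = dosages[order]
    return GenotypeMatrix(sites=sites, samples=samples, dosages=dosages)


def write_vcf(gm: GenotypeMatrix, path: str, contigs: Mapping[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 preserving coordinates, alleles, INFO and GTs."""
    sites = gm.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mouflon\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in pd.unique(sites["chrom"]):
                fh.write(f"##contig=<ID={name}>\n")
        for name in INFO_FIELDS:
            typ = "Integer" if name == "DP" else "Float"
            fh.write(
                f'##INFO=<ID={name},Number=1,Type={typ},Description="{name}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        has_info = [f for f in INFO_FIELDS if f in sites.columns]
        qual = sites["qual"] if "qual" in sites.columns else None
        for i in range(gm.n_sites):
            row = sites.iloc[i]
            parts = []
            for name in has_info:
                val = row[name]
                if pd.notna(val):
                    if name == "DP":
                        parts.append(f"{name}={int(val)}")
                    else:
                        parts.append(f"{name}={val:g}")
            info = ";".join(parts) if parts else "."
            q = "." if qual is None or pd.isna(qual.iloc[i]) else f"{qual.iloc[i]:g}"
            gts = "\t".join(gt_map[int(d)] for d in gm.dosages[i])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{q}\tPASS\t{info}\tGT\t{gts}\n"
            )


def write_genotype_tsv(gm: GenotypeMatrix, path: str) -> None:
    """Dump coordinates plus dosage columns as a plain TSV (missing = -1)."""
    out = gm.sites[["chrom", "pos", "ref", "alt"]].copy()
    for j, s in enumerate(gm.samples):
        out[s] = gm.dosages[:, j]
    out.to_csv(path, sep="\t", index=False)


def write_eigenstrat(gm: GenotypeMatrix, prefix: str) -> None:
    """Optional EIGENSTRAT-style export: .geno/.snp/.ind triple.

    geno codes count REFERENCE alleles (2 - dosage), 9 = missing, matching
    the convention of that format family.
    """
    with open(prefix + ".geno", "w") as fh:
        for i in range(gm.n_sites):
            codes = [
                "9" if d == MISSING else str(2 - int(d)) for d in gm.dosages[i]
            ]
            fh.write("".join(codes) + "\n")
    with open(prefix + ".snp", "w") as fh:
        for i, row in enumerate(gm.sites.itertuples(index=False)):
            fh.write(
                f"snp{i}\t{row.chrom}\t0.0\t{row.pos}\t{row.ref}\t{row.alt}\n"
            )
    with open(prefix + ".ind", "w") as fh:
        for s in gm.samples:
            fh.write(f"{s}\tU\tpop\n")


def read_sample_metadata(path: str) -> list[SampleInfo]:
    """Read a metadata TSV with columns id, lineage, outgroup, coverage, sex."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    infos = []
    for row in df.itertuples(index=False):
        infos.append(
            SampleInfo(
                id=row.id,
                lineage=getattr(row, "lineage", ""),
                outgroup=bool(getattr(row, "outgroup", False)),
                coverage=float(getattr(row, "coverage", np.nan)),
                sex=str(getattr(row, "sex", "unknown")),
            )
        )
    return infos


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Two-sided exact Hardy-Weinberg test on diploid genotype counts.

    Enumerates the conditional distribution of heterozygote counts given
    the observed allele counts and sums the probabilities of all outcomes
    no more likely than the observed one (plain exact test, no mid-p).
    """
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    # feasible het counts share the parity of the minor-allele count
    het_values = np.arange(n_minor % 2, n_minor + 1, 2)
    # unnormalized log-probabilities of each het count
    from scipy.special import gammaln

    hom_minor = (n_minor - het_values) // 2
    hom_major = n - het_values - hom_minor
    logp = (
        het_values * np.log(2.0)
        - gammaln(het_values + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.flatnonzero(het_values == n_het)
    if obs.size == 0:  # inconsistent counts
        raise ValueError("observed heterozygote count infeasible for allele counts")
    p_obs = p[obs[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Filtering and transforms


def _maf(dosages: np.ndarray) -> np.ndarray:
    """Per-site minor-allele frequency over non-missing genotypes."""
    valid = dosages != MISSING
    alt = np.where(valid, dosages, 0).sum(axis=1)
    n_alleles = 2 * valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return np.minimum(p, 1.0 - p)


def apply_site_filters(
    gm: GenotypeMatrix,
    cfg: FilterConfig,
    outgroup: str | None = None,
) -> GenotypeMatrix:
    """Apply hard site filters, returning the retained biallelic SNPs.

    Retained sites are biallelic SNPs passing every threshold test, with
    cohort minor-allele frequency >= ``cfg.min_maf`` (computed over all
    samples' non-missing genotypes) and a two-sided Hardy-Weinberg exact
    p >= ``cfg.min_hwe_p`` pooled across non-outgroup samples.
    Multiallelic records are dropped, never split.  An empty result is a
    warning, not an error.
    """
    sites = gm.sites
    n = gm.n_sites
    keep = np.ones(n, dtype=bool)

    if "biallelic" in sites.columns:
        keep &= sites["biallelic"].to_numpy(dtype=bool)
    keep &= (sites["ref"].str.len() == 1).to_numpy()
    keep &= (sites["alt"].str.len() == 1).to_numpy()
    keep &= (sites["alt"] != ".").to_numpy()

    def _test(col: str, fn) -> None:
        nonlocal keep
        if col == "QUAL":
            vals = (
                sites["qual"].to_numpy(dtype=float)
                if "qual" in sites.columns
                else np.full(n, np.nan)
            )
        else:
            vals = (
                sites[col].to_numpy(dtype=float)
                if col in sites.columns
                else np.full(n, np.nan)
            )
        ok = fn(vals)
        absent = np.isnan(vals)
        if col in cfg.required_info:
            ok = ok & ~absent
        else:
            ok = ok | absent
        keep &= ok

    _test("QUAL", lambda v: v >= cfg.min_qual)
    _test("QD", lambda v: v >= cfg.min_qd)
    _test("SOR", lambda v: v <= cfg.max_sor)
    _test("FS", lambda v: v <= cfg.max_fs)
    _test("MQ", lambda v: v >= cfg.min_mq)
    _test("MQRankSum", lambda v: v > cfg.min_mqranksum)
    _test("ReadPosRankSum", lambda v: v > cfg.min_readposranksum)
    # per-site mean depth within [min_depth, max_depth], inclusive
    _test(
        "DP",
        lambda v: (v / max(gm.n_samples, 1) >= cfg.min_depth)
        & (v / max(gm.n_samples, 1) <= cfg.max_depth),
    )

    keep &= _maf(gm.dosages) >= cfg.min_maf

    if cfg.min_hwe_p > 0:
        if outgroup is not None:
            cohort = [s for s in gm.samples if s != outgroup]
        else:
            cohort = list(gm.samples)
        idx = [gm.samples.index(s) for s in cohort]
        d = gm.dosages[:, idx]
        for i in np.flatnonzero(keep):
            di = d[i]
            di = di[di != MISSING]
            n_het = int((di == 1).sum())
            n_alt = int((di == 2).sum())
            n_ref = int((di == 0).sum())
            if n_alt + n_ref + n_het == 0:
                continue
            if hwe_exact_test(n_het, n_alt, n_ref) < cfg.min_hwe_p:
                keep[i] = False

    if not keep.any():
        warnings.warn("all sites removed by filters; returning empty matrix")
    return gm.subset_sites(keep)


def ascertain_outgroup_het(gm: GenotypeMatrix, outgroup_sample: str) -> GenotypeMatrix:
    """Keep only sites heterozygous in the outgroup sample.

    Ascertaining on outgroup heterozygotes yields a site set whose allele
    frequencies are unbiased with respect to ingroup drift, a standard
    validation set for f3-based affinities.
    """
    d = gm.sample_dosages(outgroup_sample)
    if np.all(d == MISSING):
        raise ValueError(f"outgroup sample {outgroup_sample!r} has no called genotypes")
    mask = d == 1
    if not mask.any():
        warnings.warn("no heterozygous outgroup sites; returning empty matrix")
    return gm.subset_sites(mask)


def pseudo_haploidize(gm: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Replace each diploid call by one uniformly sampled allele.

    Heterozygotes map to dosage 0 or 2 with probability 1/2 each;
    homozygotes are invariant; missing stays missing.  Deterministic under
    ``seed``.
    """
    if gm.ploidy != "diploid":
        raise ValueError("input must be diploid")
    rng = np.random.default_rng(seed)
    out = gm.dosages.copy()
    het = out == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8) * 2
    return GenotypeMatrix(
        sites=gm.sites.copy(),
        samples=list(gm.samples),
        dosages=out,
        ploidy="pseudohaploid",
    )
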