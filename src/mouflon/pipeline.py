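"""End-to-end orchestration: fixture generation and the staged pipeline.

``make_fixture`` writes a complete synthetic input set (VCF, coverage
TSV, conservation BED, mtDNA FASTA, metadata TSV, truth JSON) from a
:class:`~mouflon.simulate.SimConfig`.  ``run_pipeline`` consumes those
inputs (or real ones with the same schemas) and executes

    filter -> sexdet -> kinship -> fstats -> tree -> diversity -> roh -> load

writing per-stage TSVs, Newick trees and a manifest carrying the config
hash, seed and per-stage counts.  Re-running with an identical config
reproduces every output bit-exactly: all stochastic stages are seeded
from the single root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mouflon import variants, fstats, structure, diversity, roh as roh_mod
from mouflon import sample_qc, load as load_mod, simulate
from mouflon.variants import FilterConfig
from mouflon.roh import ROHParams
from mouflon.sample_qc import KinshipConfig

ALL_STAGES = (
    "filter", "sexdet", "kinship", "fstats", "tree", "diversity", "roh", "load",
)


@dataclass
class RunConfig:
    """Input paths, stage toggles and parameters for one pipeline run."""

    vcf: str
    metadata: str
    coverage: str | None = None
    gerp_bed: str | None = None
    mtdna_fasta: str | None = None
    outdir: str = "out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    roh_params: ROHParams = field(default_factory=ROHParams)
    kinship_config: KinshipConfig = field(default_factory=KinshipConfig)
    xx_threshold: float = 0.65
    xy_threshold: float = 0.5
    bootstrap_reps: int = 100
    bootstrap_chunk: int = 30_000
    jackknife_span_bp: int = 5_000_000
    outgroup_distance: float = 1.0
    autosomal_genome_bp: int | None = None
    prune_max_degree: str = "3rd"

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


class StageFailure(RuntimeError):
    """A pipeline stage failed; the stage name is in ``stage``."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages and return the manifest dict."""
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
        "status": "running",
    }
    state: dict = {}

    def out(name: str) -> str:
        return os.path.join(cfg.outdir, name)

    stage_fns = {
        "filter": _stage_filter,
        "sexdet": _stage_sexdet,
        "kinship": _stage_kinship,
        "fstats": _stage_fstats,
        "tree": _stage_tree,
        "diversity": _stage_diversity,
        "roh": _stage_roh,
        "load": _stage_load,
    }
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        try:
            info = stage_fns[stage](cfg, state, out)
        except Exception as exc:
            manifest["status"] = f"FAILED at {stage}"
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            with open(out("manifest.json"), "w") as fh:
                json.dump(_as_jsonable(manifest), fh, indent=2, sort_keys=True)
            with open(out("FAILED"), "w") as fh:
                fh.write(f"{stage}: {exc}\n")
            raise StageFailure(stage, exc) from exc
        manifest["stages"][stage] = {"status": "complete", **info}
    manifest["status"] = "complete"
    with open(out("manifest.json"), "w") as fh:
        json.dump(_as_jsonable(manifest), fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Stages


def _load_metadata(cfg: RunConfig, state: dict) -> None:
    if "meta" not in state:
        meta = variants.read_sample_metadata(cfg.metadata)
        state["meta"] = meta
        outgroups = [m.id for m in meta if m.outgroup]
        if len(outgroups) != 1:
            raise ValueError(
                f"exactly one outgroup sample required, found {outgroups}"
            )
        state["outgroup"] = outgroups[0]
        state["lineage"] = {m.id: m.lineage for m in meta if not m.outgroup}
        state["coverage_nominal"] = {m.id: m.coverage for m in meta}


def _stage_filter(cfg: RunConfig, state: dict, out) -> dict:
    _load_metadata(cfg, state)
    gm = variants.read_vcf(cfg.vcf)
    n_raw = gm.n_sites
    gm = variants.apply_site_filters(gm, cfg.filter_config, outgroup=state["outgroup"])
    state["gm"] = gm
    variants.write_genotype_tsv(gm, out("genotypes_filtered.tsv"))
    return {"n_sites_raw": n_raw, "n_sites_filtered": gm.n_sites,
            "n_samples": gm.n_samples}


def _stage_sexdet(cfg: RunConfig, state: dict, out) -> dict:
    _load_metadata(cfg, state)
    if cfg.coverage is None:
        raise ValueError("sexdet stage requires a coverage TSV")
    profiles = sample_qc.read_coverage_tsv(cfg.coverage)
    rows = []
    calls = {}
    for prof in profiles:
        res = sample_qc.assign_sex(
            sample_qc.compute_rx(prof), cfg.xx_threshold, cfg.xy_threshold
        )
        calls[res.sample] = res.assignment
        rows.append(
            {"sample": res.sample, "rx": res.rx, "se": res.se,
             "assignment": res.assignment, "n_autosomes": res.n_autosomes}
        )
    state["sex_calls"] = calls
    pd.DataFrame(rows).to_csv(out("sex.tsv"), sep="\t", index=False)
    return {"n_samples": len(rows),
            "n_assigned": sum(1 for v in calls.values() if v != "unassigned")}


def _stage_kinship(cfg: RunConfig, state: dict, out) -> dict:
    _load_metadata(cfg, state)
    gm = state["gm"]
    ph = variants.pseudo_haploidize(gm, seed=cfg.seed + 11)
    rows = []
    excluded: list[str] = []
    for lineage in sorted(set(state["lineage"].values())):
        members = sorted(
            s for s, l in state["lineage"].items() if l == lineage and s in gm.samples
        )
        if len(members) < 2:
            continue
        mres = [
            sample_qc.pairwise_mismatch(ph, (a, b), cfg.kinship_config.window_bp)
            for i, a in enumerate(members)
            for b in members[i + 1:]
        ]
        kres = sample_qc.classify_kinship(mres, cfg.kinship_config)
        excluded.extend(
            sample_qc.prune_relatives(
                kres, cfg.prune_max_degree, state["coverage_nominal"]
            )
        )
        for k in kres:
            rows.append(
                {"lineage": lineage, "a": k.pair[0], "b": k.pair[1], "p0": k.p0,
                 "normalized_p0": k.normalized_p0, "theta": k.theta,
                 "degree": k.degree, "n_windows": k.n_windows}
            )
    state["excluded"] = sorted(set(excluded))
    pd.DataFrame(rows).to_csv(out("kinship.tsv"), sep="\t", index=False)
    with open(out("excluded_samples.txt"), "w") as fh:
        fh.write("\n".join(state["excluded"]) + ("\n" if state["excluded"] else ""))
    return {"n_pairs": len(rows), "n_excluded": len(state["excluded"])}


def _grouping(cfg: RunConfig, state: dict) -> dict[str, str]:
    excluded = set(state.get("excluded", []))
    grouping = {
        s: l for s, l in state["lineage"].items()
        if s not in excluded and s in state["gm"].samples
    }
    grouping[state["outgroup"]] = state["outgroup"]
    return grouping


def _stage_fstats(cfg: RunConfig, state: dict, out) -> dict:
    gm = state["gm"]
    grouping = _grouping(cfg, state)
    ft = fstats.allele_frequencies(gm, grouping)
    blocks = fstats.BlockScheme.by_physical_span(ft.sites, cfg.jackknife_span_bp)
    pops = sorted(set(grouping.values()) - {state["outgroup"]})
    results = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            results.append(fstats.f3(ft, state["outgroup"], a, b, blocks))
    fstats.fstat_table(results).to_csv(out("f3.tsv"), sep="\t", index=False)
    D = fstats.distance_matrix(ft, pops, state["outgroup"], blocks)
    D.to_frame().to_csv(out("distance_matrix.tsv"), sep="\t")
    state["ft"], state["blocks"], state["D"], state["pops"] = ft, blocks, D, pops
    return {"n_pops": len(pops), "n_f3": len(results), "n_sites": gm.n_sites}


def _stage_tree(cfg: RunConfig, state: dict, out) -> dict:
    D = state["D"]
    gm = state["gm"]
    mds = structure.classical_mds(D, k=min(2, D.n - 1))
    structure.write_mds_tsv(mds, out("mds.tsv"))
    reps = fstats.bootstrap_distance_matrices(
        gm, _grouping(cfg, state), state["pops"], state["outgroup"],
        chunk_size=min(cfg.bootstrap_chunk, max(2, gm.n_sites // 2)),
        reps=cfg.bootstrap_reps, seed=cfg.seed + 23,
    )
    og = state["outgroup"]
    main_rooted = structure.root_with_outgroup(D, og, cfg.outgroup_distance)
    rep_rooted = [
        structure.root_with_outgroup(r, og, cfg.outgroup_distance) for r in reps
    ]
    supported = structure.bootstrap_support(main_rooted, rep_rooted)
    with open(out("tree_rooted.nwk"), "w") as fh:
        fh.write(supported.newick(with_support=True) + "\n")
    unrooted = structure.nj_tree(D)
    with open(out("tree_unrooted.nwk"), "w") as fh:
        fh.write(unrooted.newick() + "\n")
    state["tree"] = supported
    return {"n_bootstrap": len(reps)}


def _stage_diversity(cfg: RunConfig, state: dict, out) -> dict:
    gm = state["gm"]
    excluded = set(state.get("excluded", []))
    # each individual as its own population for pairwise-f3 diversity
    samples = [
        s for s in gm.samples
        if s != state["outgroup"] and s not in excluded
    ]
    grouping = {s: s for s in samples}
    grouping[state["outgroup"]] = state["outgroup"]
    ft = fstats.allele_frequencies(gm, grouping)
    blocks = fstats.BlockScheme.by_physical_span(ft.sites, cfg.jackknife_span_bp)
    rows = []
    for lineage in sorted(set(state["lineage"].values())):
        members = [s for s in samples if state["lineage"].get(s) == lineage]
        if len(members) >= 2:
            est = diversity.pairwise_f3_diversity(
                ft, members, state["outgroup"], blocks, population=lineage
            )
            rows.append(
                {"scope": lineage, "compartment": "autosomes",
                 "metric": "pairwise_1mf3", "value": est.value,
                 "n": est.n_pairs}
            )
    for s in samples:
        est = diversity.individual_heterozygosity(gm, s, gm.n_sites)
        rows.append(
            {"scope": s, "compartment": "autosomes", "metric": "heterozygosity",
             "value": est.value, "n": est.n_sites}
        )
    if cfg.mtdna_fasta:
        aln = diversity.MtAlignment.from_fasta(cfg.mtdna_fasta)
        by_lineage: dict[str, list[int]] = {}
        for i, sid in enumerate(aln.ids):
            lin = state["lineage"].get(sid)
            if lin is not None:
                by_lineage.setdefault(lin, []).append(i)
        for lineage, idx in sorted(by_lineage.items()):
            if len(idx) < 2:
                continue
            sub = diversity.MtAlignment(
                ids=[aln.ids[i] for i in idx], seqs=[aln.seqs[i] for i in idx]
            )
            est = diversity.mtdna_pi(sub)
            rows.append(
                {"scope": lineage, "compartment": "mtDNA", "metric": "pi",
                 "value": est.value, "n": est.n_sites}
            )
    pd.DataFrame(rows).to_csv(out("diversity.tsv"), sep="\t", index=False)
    return {"n_estimates": len(rows)}


def _stage_roh(cfg: RunConfig, state: dict, out) -> dict:
    gm = state["gm"]
    genome_bp = cfg.autosomal_genome_bp
    if genome_bp is None:
        genome_bp = int(
            gm.sites.groupby("chrom", observed=True)["pos"].max().sum()
        )
    all_segments = []
    summaries = []
    for s in gm.samples:
        if s == state["outgroup"]:
            continue
        segs = roh_mod.call_roh(gm, s, cfg.roh_params)
        all_segments.extend(segs)
        summ = roh_mod.classify_sizes(segs, sample=s, autosomal_genome_bp=genome_bp)
        row = {"sample": s, "n_segments": summ.n_segments,
               "total_length_bp": summ.total_length_bp, "f_roh": summ.f_roh,
               "mean_length_mb": summ.mean_length_mb}
        row.update(summ.class_counts)
        if summ.mean_length_mb > 0:
            t = roh_mod.inbreeding_time(summ.mean_length_mb)
            row["inbreeding_generations"] = t.generations_rounded
            row["inbreeding_years"] = t.years
        summaries.append(row)
    roh_mod.segments_table(all_segments).to_csv(
        out("roh_segments.tsv"), sep="\t", index=False
    )
    pd.DataFrame(summaries).to_csv(out("roh_summary.tsv"), sep="\t", index=False)
    return {"n_segments": len(all_segments), "genome_bp": genome_bp}


def _stage_load(cfg: RunConfig, state: dict, out) -> dict:
    if cfg.gerp_bed is None:
        raise ValueError("load stage requires a conservation-score BED")
    gm = state["gm"]
    track = load_mod.GerpTrack.from_bed(cfg.gerp_bed)
    regions = load_mod.conserved_regions(track)
    load_mod.regions_to_bed(regions, out("conserved_regions.bed"))
    derived = load_mod.polarize_derived(gm, state["outgroup"])
    rows = []
    for s in gm.samples:
        if s == state["outgroup"]:
            continue
        try:
            res = load_mod.rml(derived, regions, s)
        except ValueError:
            continue
        rows.append(
            {"sample": s, "rml": res.rml, "n_derived": res.n_derived,
             "k_used": res.k_used}
        )
    pd.DataFrame(rows).to_csv(out("rml.tsv"), sep="\t", index=False)
    return {"n_regions": len(regions), "n_samples": len(rows)}


# ---------------------------------------------------------------------------
# Fixture generation


def make_fixture(
    cfg: simulate.SimConfig,
    outdir: str,
    force: bool = False,
    coverage_depth: float = 2.0,
    x_mappability: float = 0.74,
) -> dict:
    """Write a full synthetic input set plus its truth JSON.

    Returns a dict of the written paths.  Refuses to write into an
    existing non-empty directory unless ``force`` is set.
    """
    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    os.makedirs(outdir, exist_ok=True)

    freqs = simulate.simulate_frequencies(cfg)
    gm, truth = simulate.simulate_genotypes(freqs, cfg)
    if cfg.planted_roh:
        gm, _ = simulate.plant_roh(gm, cfg.planted_roh, seed=cfg.seed + 7)

    # INFO annotations that pass the default hard filters
    sites = gm.sites
    sites["qual"] = 50.0
    sites["biallelic"] = True
    sites["QD"] = 20.0
    sites["SOR"] = 1.0
    sites["FS"] = 10.0
    sites["MQ"] = 60.0
    sites["MQRankSum"] = 0.0
    sites["ReadPosRankSum"] = 0.0
    sites["DP"] = 10 * gm.n_samples

    paths = {}
    contigs = {
        str(c): int(sites.loc[sites["chrom"] == c, "pos"].max()) + cfg.snp_spacing_bp
        for c in pd.unique(sites["chrom"])
    }
    paths["vcf"] = os.path.join(outdir, "genotypes.vcf")
    variants.write_vcf(gm, paths["vcf"], contigs=contigs)

    meta = pd.DataFrame(
        {
            "id": gm.samples,
            "lineage": [
                s.rsplit("_", 1)[0] if s != cfg.outgroup_name else cfg.outgroup_name
                for s in gm.samples
            ],
            "outgroup": [s == cfg.outgroup_name for s in gm.samples],
            "coverage": coverage_depth,
            "sex": [truth.sexes[s] for s in gm.samples],
        }
    )
    paths["metadata"] = os.path.join(outdir, "metadata.tsv")
    meta.to_csv(paths["metadata"], sep="\t", index=False)

    profiles = simulate.simulate_coverage(
        truth.sexes, depth=coverage_depth, x_mappability=x_mappability,
        seed=cfg.seed + 13,
    )
    cov_rows = [
        {"sample": p.sample, "chrom": c, "length": length, "aligned_bases": aligned}
        for p in profiles
        for c, (length, aligned) in p.chroms.items()
    ]
    paths["coverage"] = os.path.join(outdir, "coverage.tsv")
    pd.DataFrame(cov_rows).to_csv(paths["coverage"], sep="\t", index=False)

    # conservation track: regions of ~50 bp around a subset of SNPs on chr1
    rng = np.random.default_rng(cfg.seed + 17)
    chr1 = sites[sites["chrom"] == "chr1"]
    n_reg = min(200, len(chr1) // 10)
    chosen = np.sort(
        rng.choice(chr1["pos"].to_numpy(), size=n_reg, replace=False)
    )
    paths["gerp_bed"] = os.path.join(outdir, "gerp.bed")
    with open(paths["gerp_bed"], "w") as fh:
        for p in chosen:
            score = rng.uniform(4.5, 9.0)
            fh.write(f"chr1\t{p - 26}\t{p + 25}\t{score:.3f}\n")

    mt_tree = {
        "name": "root", "mutations": 0,
        "children": [
            {
                "name": pop, "mutations": 10,
                "children": [
                    {"name": f"{pop}_{i + 1}", "mutations": 3, "children": []}
                    for i in range(cfg.samples_per_pop)
                ],
            }
            for pop in cfg.leaf_pops()
        ],
    }
    aln, mt_truth = simulate.simulate_mtdna(mt_tree, length=2000, seed=cfg.seed + 19)
    paths["mtdna_fasta"] = os.path.join(outdir, "mtdna.fasta")
    with open(paths["mtdna_fasta"], "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")

    truth_json = {
        "tree_distance": {f"{a}|{b}": v for (a, b), v in truth.tree_distance.items()},
        "relatives": [dataclasses.asdict(r) for r in truth.relatives],
        "planted_roh": [dataclasses.asdict(r) for r in truth.planted_roh],
        "sexes": truth.sexes,
        "mtdna_pi_by_pair": {
            f"{a}|{b}": v for (a, b), v in mt_truth["pair_diffs"].items()
        },
        "seed": cfg.seed,
    }
    paths["truth"] = os.path.join(outdir, "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(_as_jsonable(truth_json), fh, indent=2, sort_keys=True)
    return paths
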