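"""End-to-end run: synthetic fixture -> staged pipeline -> report bundle.

Writes a complete input set (VCF, metadata, coverage, conservation BED,
mtDNA FASTA, truth JSON) and runs filter -> sexing -> kinship ->
f-statistics -> tree -> diversity -> ROH -> load, printing the manifest.
"""

import json
import tempfile
from pathlib import Path

from mouflon import pipeline, simulate

with tempfile.TemporaryDirectory() as td:
    cfg = simulate.SimConfig(
        n_sites=10_000, samples_per_pop=2, seed=42,
        relatives=[simulate.RelativeSpec("P1", "identical", "P1_3", "P1_4")],
        planted_roh=[simulate.ROHSpec("P2_1", "chr1", 200_000, 800_000)],
    )
    paths = pipeline.make_fixture(cfg, str(Path(td) / "fixture"))
    print("fixture files:", ", ".join(Path(p).name for p in paths.values()))

    run_cfg = pipeline.RunConfig(
        vcf=paths["vcf"], metadata=paths["metadata"],
        coverage=paths["coverage"], gerp_bed=paths["gerp_bed"],
        mtdna_fasta=paths["mtdna_fasta"],
        outdir=str(Path(td) / "out"), seed=1, bootstrap_reps=25,
    )
    manifest = pipeline.run_pipeline(run_cfg)
    print(f"\npipeline status: {manifest['status']} "
          f"(config hash {manifest['config_hash']})")
    for stage, info in manifest["stages"].items():
        detail = {k: v for k, v in info.items() if k != "status"}
        print(f"  {stage:<9} {detail}")

    excluded = (Path(td) / "out" / "excluded_samples.txt").read_text().split()
    print(f"\nkinship pruning excluded {excluded} "
          "(one of the planted identical twins)")
    print("Outputs are plain TSV/Newick/JSON; re-running the same config"
          " reproduces them byte-for-byte.")
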