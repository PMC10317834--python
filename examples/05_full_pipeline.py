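"""End-to-end pipeline run, from in-memory objects to a manifest.

Runs every stage (filter, TMM, DE for two contrasts, PCA exports, locus
analytics, network, enrichment) and prints the manifest's per-stage counts.
The same run is available from the shell:

    mirlink run-all --mrna-counts ... --mirna-counts ... --metadata ... \
        --annotation ... --database ... --locus "chr14:100,825,000-101,070,000" \
        --contrasts "UvsM=M-CLL-NS+M-CLL-S/U-CLL-S" --outdir out/
"""

import json

from mirlink.pipeline import Contrast, PipelineConfig, run_pipeline
from mirlink.synthetic import SyntheticConfig, generate_dataset

ds = generate_dataset(SyntheticConfig(n_mrna=3000, n_mirna=300, cluster_size=53,
                                      n_true_pairs=60, de_fraction=0.06,
                                      db_decoy_count=3000, seed=2))

cfg = PipelineConfig(
    mrna_counts=ds.mrna_counts,
    mirna_counts=ds.mirna_counts,
    metadata=ds.metadata,
    annotation=ds.annotation,
    databases=(ds.database,),
    locus=ds.locus,
    outdir="scratch/example_pipeline",
    contrasts=(
        Contrast("UvsM", reference=("M-CLL-NS", "M-CLL-S"), treatment=("U-CLL-S",)),
        Contrast("SvsNS", reference=("M-CLL-NS",), treatment=("M-CLL-S",)),
    ),
    top_n=200,
    resample_B=5000,
    seed=123,
)

manifest = run_pipeline(cfg)
print(json.dumps(manifest.stage_counts, indent=2, default=str))
print(f"\n{len(manifest.files)} output files written to {cfg.outdir} "
      "(checksums in manifest.json; reruns with the same seed are bitwise identical)")
# Typical reading: the first contrast shows a few hundred DEGs while the
# within-M contrast shows none; the locus stage reports the planted gradient;
# the enrichment block compares the observed database-supported interaction
# count against its resampling null.
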