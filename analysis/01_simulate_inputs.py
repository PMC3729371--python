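#!/usr/bin/env python
"""Generate the simulated input bundle for the downstream analyses.

Emits, under scratch/simulated/ (large, regenerable files stay out of the
results tree):

* a 2,000-gene annotation with 10.8% of loci carrying one planted
  alternative-splicing event and per-region intron-length targets of
  520/264/268 bp (GFF3);
* a genome-scale gene-family cluster set (32,275 focal loci) with planted
  secondary intron losses (14%, of which 3% full loss), fragmentary decoys,
  832 expanded families (184 beyond twice the largest counterpart), 48%
  focal-only loci and the orphan classes, plus per-species annotations and
  hit/EST flag tables;
* a two-species GO annotation pair with five terms planted at 4x relative
  frequency (GAF);
* subcellular predictor calls with planted localizations (TSV).

Run me first; the other numbered scripts read this bundle.
"""

import json
from pathlib import Path

from structome.synthetic_data import (
    ClusterConfig,
    GenomeConfig,
    GoaPairConfig,
    PredictorConfig,
    generate_cluster_set,
    generate_genome,
    generate_goa_pair,
    generate_predictor_calls,
)

SEED = 498
ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    genome_cfg = GenomeConfig(seed=SEED, n_genes=2000, genome_size=29_760_000)
    ann, truth = generate_genome(genome_cfg, out_gff=OUT / "genome.gff3")
    (OUT / "genome_truth.json").write_text(
        json.dumps({"as_events": truth.as_events, "n_genes": genome_cfg.n_genes})
    )
    print(f"genome: {len(ann)} genes, {len(truth.as_loci)} planted AS loci")

    fam_cfg = ClusterConfig(
        seed=SEED + 2, n_focal_genes=32275, n_expansions=832, n_strong_expansions=184
    )
    clusters, _, _, _, fam_truth = generate_cluster_set(fam_cfg, out_dir=OUT / "families")
    print(
        f"families: {len(clusters)} clusters, "
        f"{sum(1 for k in fam_truth.loss_class.values() if k != 'none')} planted loss/decoy genes"
    )

    goa_cfg = GoaPairConfig(seed=SEED + 3, n_null_terms=200, n_planted_terms=5, fold=4.0)
    focal, other, planted = generate_goa_pair(goa_cfg, out_dir=OUT / "goa")
    (OUT / "goa" / "planted_terms.json").write_text(json.dumps(planted))
    print(f"goa: {len(focal)}/{len(other)} annotations, planted terms {planted}")

    pred_cfg = PredictorConfig(seed=SEED + 4, n_proteins=200)
    calls, tools, complete, loc_truth = generate_predictor_calls(pred_cfg)
    with open(OUT / "predictor_calls.tsv", "w") as fh:
        fh.write("tool\tprotein\tcompartment\tscore\n")
        for c in calls:
            fh.write(f"{c.tool}\t{c.protein}\t{c.compartment}\t{c.score}\n")
    with open(OUT / "predictor_truth.tsv", "w") as fh:
        fh.write("protein\tterm\tcomplete\n")
        for p, term in sorted(loc_truth.items()):
            fh.write(f"{p}\t{term}\t{int(complete[p])}\n")
    print(f"predictors: {len(calls)} calls over {pred_cfg.n_proteins} proteins")
    print(f"bundle written to {OUT}")


if __name__ == "__main__":
    main()
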