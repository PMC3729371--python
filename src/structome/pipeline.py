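"""Single entry point wiring the analysis stages.

Stages run in dependency order (io -> stats/splice -> families ->
functional); each writes TSV tables into the output directory and
contributes headline numbers to a versioned JSON summary that also echoes
every threshold for provenance.  All randomness flows from the single
config seed, so a rerun with the same config reproduces the summary
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as sio
from .family_evolution import classify_orphans, family_profile, infer_intron_loss
from .functional_annotation import goa_summary, term_enrichment
from .models import GenomeAnnotation
from .splice_events import genome_as_summary
from .structure_stats import (
    genome_structure_summary,
    intron_length_profile,
    proximal_utr5_intron_distances,
    utr5_intron_count_frequencies,
)

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1
ALL_STAGES = ("stats", "splice", "families", "functional")


@dataclass
class RunConfig:
    out_dir: Path
    gff: Optional[Path] = None
    clusters: Optional[Path] = None
    species_gffs: dict[str, Path] = field(default_factory=dict)
    focal_species: str = ""
    hits: Optional[Path] = None
    est: Optional[Path] = None
    gaf_focal: Optional[Path] = None
    gaf_other: Optional[Path] = None
    stages: tuple[str, ...] = ALL_STAGES
    genome_size: Optional[int] = None
    scope: str = "all_transcripts"
    intron_length_threshold: int = 500
    atg_distance_threshold: int = 65
    length_ratio_threshold: float = 0.5
    majority_fraction: float = 0.5
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"


_REQUIRED = {
    "stats": ("gff",),
    "splice": ("gff",),
    "families": ("clusters",),
    "functional": ("gaf_focal", "gaf_other"),
}


def _preflight(cfg: RunConfig) -> None:
    missing = []
    for stage in cfg.stages:
        if stage not in ALL_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        for attr in _REQUIRED[stage]:
            p = getattr(cfg, attr)
            if p is None:
                missing.append(f"{stage}: --{attr}")
            elif not Path(p).exists():
                missing.append(f"{stage}: {p}")
    for sp, p in cfg.species_gffs.items():
        if not Path(p).exists():
            missing.append(f"families: {sp} -> {p}")
    if missing:
        raise FileNotFoundError(
            "missing required inputs:\n  " + "\n  ".join(missing)
        )


def _read_flag_table(path: Path, column: str) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t")
    return {str(r["gene_id"]): bool(int(r[column])) for _, r in df.iterrows()}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the selected stages; returns the JSON-ready summary dict."""
    logging.basicConfig(level=cfg.log_level, format="%(asctime)s %(levelname)s %(message)s")
    _preflight(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "thresholds": {
            "intron_length_threshold": cfg.intron_length_threshold,
            "atg_distance_threshold": cfg.atg_distance_threshold,
            "length_ratio_threshold": cfg.length_ratio_threshold,
            "majority_fraction": cfg.majority_fraction,
            "alpha": cfg.alpha,
            "scope": cfg.scope,
        },
        "stages": {},
    }

    annotation: Optional[GenomeAnnotation] = None
    if any(s in cfg.stages for s in ("stats", "splice")):
        annotation = sio.read_gff3(cfg.gff, genome_size=cfg.genome_size)

    if "stats" in cfg.stages:
        stats = genome_structure_summary(annotation, scope=cfg.scope)
        pd.DataFrame(stats.to_rows()).to_csv(out / "structure_stats.tsv", sep="\t", index=False)
        profile = intron_length_profile(annotation, threshold=cfg.intron_length_threshold)
        pd.DataFrame(
            {
                "region": list(profile.means),
                "n": [len(profile.lengths[r]) for r in profile.means],
                "mean": [profile.means[r] for r in profile.means],
                "median": [profile.medians[r] for r in profile.means],
                f"frac_gt_{cfg.intron_length_threshold}": [
                    profile.frac_gt_threshold[r] for r in profile.means
                ],
            }
        ).to_csv(out / "intron_length_profile.tsv", sep="\t", index=False)
        freqs = utr5_intron_count_frequencies(annotation)
        pd.DataFrame(
            {"n_utr5_introns": list(freqs.frequencies),
             "fraction": list(freqs.frequencies.values())}
        ).to_csv(out / "utr5_intron_frequencies.tsv", sep="\t", index=False)
        pos = proximal_utr5_intron_distances(annotation, cfg.atg_distance_threshold)
        pd.DataFrame(
            {"transcript": pos.transcript_ids,
             "distance_to_atg": pos.distance_to_atg,
             "distance_to_tss": pos.distance_to_tss}
        ).to_csv(out / "utr5_intron_positions.tsv", sep="\t", index=False)
        summary["stages"]["stats"] = {
            "n_genes": stats.counts["genes"],
            "n_transcripts": stats.counts["transcripts"],
            "multi_exon_utr5_fraction": stats.fractions["multi_exon_utr5"],
            "utr5_intron_mean": profile.means["UTR5"],
            "cds_intron_mean": profile.means["CDS"],
            "utr3_intron_mean": profile.means["UTR3"],
            "frac_atg_below_threshold": pos.frac_atg_below_threshold,
            "gene_density_kb_per_gene": stats.gene_density_kb,
        }

    if "splice" in cfg.stages:
        table = genome_as_summary(annotation)
        table.to_csv(out / "splice_summary.tsv", sep="\t")
        summary["stages"]["splice"] = {
            "as_fraction": float(table.loc["as_fraction", "n_loci"]),
            "loci_total": int(table.loc["loci_total", "n_loci"]),
            "loci_AS": int(table.loc["loci_AS", "n_loci"]),
        }

    if "families" in cfg.stages:
        clusters = sio.read_clusters(cfg.clusters)
        fam = family_profile(clusters, cfg.focal_species)
        pd.DataFrame(
            [
                {"cluster_id": p.cluster_id, "focal_only": p.focal_only,
                 "expansion": p.expansion, "strong_expansion": p.strong_expansion,
                 **{f"n_{sp}": n for sp, n in p.counts.items()}}
                for p in fam.profiles
            ]
        ).to_csv(out / "family_profiles.tsv", sep="\t", index=False)
        summary["stages"]["families"] = {
            "focal_only_locus_fraction": fam.focal_only_locus_fraction,
            "expansion_count": fam.expansion_count,
            "strong_expansion_count": fam.strong_expansion_count,
        }
        if cfg.hits and cfg.est:
            orphans = classify_orphans(
                clusters, cfg.focal_species,
                _read_flag_table(Path(cfg.hits), "has_hit"),
                _read_flag_table(Path(cfg.est), "est_supported"),
            )
            pd.DataFrame([{"gene_id": o.gene_id, "class": o.klass} for o in orphans]).to_csv(
                out / "orphan_calls.tsv", sep="\t", index=False
            )
            n = len(orphans)
            summary["stages"]["families"]["orphan_no_homolog_fraction"] = (
                sum(1 for o in orphans if o.klass == "orphan_no_homolog") / n if n else None
            )
            summary["stages"]["families"]["orphan_with_est_fraction"] = (
                sum(1 for o in orphans if o.klass == "orphan_with_est") / n if n else None
            )
        if cfg.species_gffs:
            anns = {
                sp: sio.read_gff3(p, species_label=sp)
                for sp, p in cfg.species_gffs.items()
            }
            loss = infer_intron_loss(
                clusters, anns, cfg.focal_species,
                length_ratio_threshold=cfg.length_ratio_threshold,
            )
            pd.DataFrame(
                [
                    {"gene_id": c.gene_id, "cluster_id": c.cluster_id,
                     "focal_introns": c.focal_introns,
                     "median_other_introns": c.median_other_introns,
                     "excluded_fragmentary": c.excluded_fragmentary, "call": c.call}
                    for c in loss.calls
                ]
            ).to_csv(out / "intron_loss_calls.tsv", sep="\t", index=False)
            summary["stages"]["families"]["intron_loss_fraction"] = loss.reduced_fraction
            summary["stages"]["families"]["full_loss_fraction"] = loss.full_loss_fraction

    if "functional" in cfg.stages:
        goa_f = sio.read_gaf(cfg.gaf_focal).annotations
        goa_o = sio.read_gaf(cfg.gaf_other).annotations
        focal_genes = {a.gene_id for a in goa_f}
        summ = goa_summary(goa_f, total_gene_count=len(focal_genes))
        results = term_enrichment(goa_f, goa_o, alpha=cfg.alpha)
        pd.DataFrame(
            [
                {"term": r.term, "aspect": r.aspect, "a": r.a, "A": r.A,
                 "b": r.b, "B": r.B, "odds_ratio": r.odds_ratio,
                 "p_greater": r.p_greater, "p_less": r.p_less, "p": r.p, "q": r.q}
                for r in results
            ]
        ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        summary["stages"]["functional"] = {
            "total_terms": summ.total_terms,
            "genes_with_terms": summ.genes_with_terms,
            "n_terms_tested": len(results),
            "n_significant": sum(1 for r in results if r.q < cfg.alpha),
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
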