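"""Seeded generators for every input the pipeline consumes, with planted
ground truth.

The genome generator emulates the structural features the comparative
analyses measure: shifted-Poisson exon counts, lognormal intron lengths that
are longer in 5'-UTRs than in CDS and 3'-UTRs (default targets 520/264/268
bp), configurable UTR presence probabilities, and an exactly planted
fraction of loci carrying one alternative-splicing event of a requested
type.  The cluster generator plants secondary intron losses, fragmentary
decoys and family expansions; the GOA generator plants enriched terms at a
chosen fold; the predictor generator plants true localizations; the CDS
generator emits codon sequences with a tunable synonymous-usage bias.

Planted quantities that downstream tests assert exactly are constructed
(counts), not sampled; sampled quantities converge to their targets with
CLT tolerances.  All randomness flows from a single integer seed and files
are emitted deterministically (integer coordinates only), so identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .models import (
    Cluster,
    Gene,
    GenomeAnnotation,
    GoAnnotation,
    Interval,
    Transcript,
    cds_from_span,
    derive_transcript_regions,
)
from .splice_events import EVENT_TYPES

# ---------------------------------------------------------------------------
# genome generation


@dataclass
class GenomeConfig:
    seed: int = 0
    n_genes: int = 2000
    species_label: str = "synthetic"
    genome_size: Optional[int] = None
    exon_mean: float = 5.0  # shifted Poisson: 1 + Poisson(exon_mean - 1)
    p_utr5: float = 0.474
    p_utr3: float = 0.496
    # P(k 5'-UTR introns | transcript has a 5'-UTR); multi-exon fraction 0.392
    utr5_intron_probs: tuple[float, ...] = (0.608, 0.33, 0.062)
    utr3_intron_probs: tuple[float, ...] = (0.927, 0.073)
    intron_mean_utr5: float = 520.0
    intron_mean_cds: float = 264.0
    intron_mean_utr3: float = 268.0
    intron_sigma: float = 0.75
    min_intron: int = 20
    utr5_exon_mean: float = 211.0
    utr3_exon_mean: float = 338.0
    utr_exon_sigma: float = 0.6
    min_utr_exon: int = 12
    cds_mean: float = 1062.0
    cds_sigma: float = 0.7
    min_cds: int = 90
    as_fraction: float = 0.108
    # genes-granularity mix; paired categories planted once per pair
    as_event_mix: dict = field(
        default_factory=lambda: {
            "alt_acceptor": 1657,
            "alt_donor": 1433,
            "alternate_exon": 908,
            "ends_in_intron": 836,
            "retained_intron": 2082,
            "skipped_exon": 575,
            "starts_in_intron": 1033,
        }
    )
    p_event_in_cds: float = 0.5
    p_est: float = 0.83
    genes_per_scaffold: int = 200
    gap_min: int = 200
    gap_max: int = 2000


@dataclass
class GenomeTruth:
    exon_counts: dict[str, int] = field(default_factory=dict)
    intron_lengths: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    as_events: dict[str, str] = field(default_factory=dict)  # gene -> event type
    as_loci: list[str] = field(default_factory=list)


def _lognormal(rng: np.random.Generator, target_mean: float, sigma: float) -> float:
    mu = math.log(target_mean) - sigma * sigma / 2.0
    return float(rng.lognormal(mu, sigma))


def _intron_len(rng, cfg: GenomeConfig, region: str) -> int:
    target = {
        "UTR5": cfg.intron_mean_utr5,
        "CDS": cfg.intron_mean_cds,
        "UTR3": cfg.intron_mean_utr3,
    }[region]
    return max(cfg.min_intron, int(round(_lognormal(rng, target, cfg.intron_sigma))))


def _utr_seg_len(rng, cfg: GenomeConfig, which: str) -> int:
    target = cfg.utr5_exon_mean if which == "UTR5" else cfg.utr3_exon_mean
    return max(cfg.min_utr_exon, int(round(_lognormal(rng, target, cfg.utr_exon_sigma))))


@dataclass
class _Layout:
    """Spliced-coordinate transcript layout before genomic realization."""

    utr5_segs: list[int]
    cds_len: int
    cds_junctions: list[int]  # offsets within the CDS, ascending
    utr3_segs: list[int]
    intron_lens: list[int]  # transcript order, one per junction

    @property
    def utr5_len(self) -> int:
        return sum(self.utr5_segs)

    def exon_lengths(self) -> list[int]:
        """Exon segment lengths in transcript order."""
        bounds = [0]
        off = 0
        for seg in self.utr5_segs[:-1] if self.utr5_segs else []:
            off += seg
            bounds.append(off)
        u5 = self.utr5_len
        for j in self.cds_junctions:
            bounds.append(u5 + j)
        off = u5 + self.cds_len
        for seg in (self.utr3_segs[:-1] if self.utr3_segs else []):
            off += seg
            bounds.append(off)
        total = u5 + self.cds_len + sum(self.utr3_segs)
        bounds.append(total)
        return [b - a for a, b in zip(bounds, bounds[1:])]


def _build_layout(
    rng,
    cfg: GenomeConfig,
    min_k5: int = 0,
    min_kcds: int = 0,
    min_k3: int = 0,
    force_utr5: bool = False,
    force_utr3: bool = False,
) -> _Layout:
    has5 = force_utr5 or min_k5 > 0 or rng.random() < cfg.p_utr5
    has3 = force_utr3 or min_k3 > 0 or rng.random() < cfg.p_utr3
    n_exons = 1 + int(rng.poisson(max(0.0, cfg.exon_mean - 1.0)))
    k_total = n_exons - 1
    k5 = 0
    if has5:
        probs = np.asarray(cfg.utr5_intron_probs)
        k5 = int(rng.choice(len(probs), p=probs / probs.sum()))
    k3 = 0
    if has3:
        probs = np.asarray(cfg.utr3_intron_probs)
        k3 = int(rng.choice(len(probs), p=probs / probs.sum()))
    # UTR junctions come out of the total budget so the realized exon count
    # keeps the shifted-Poisson target; forced minima may exceed it
    k5 = max(min_k5, min(k5, k_total))
    k3 = max(min_k3, min(k3, k_total - k5))
    kcds = max(min_kcds, k_total - k5 - k3)

    cds_len = max(cfg.min_cds, 3 * int(round(_lognormal(rng, cfg.cds_mean, cfg.cds_sigma) / 3)))
    if kcds > 0:
        cuts = rng.choice(np.arange(30, cds_len - 30), size=min(kcds, cds_len - 60), replace=False)
        cds_junctions = sorted(int(c) for c in cuts)
    else:
        cds_junctions = []
    utr5_segs = [_utr_seg_len(rng, cfg, "UTR5") for _ in range(k5 + 1)] if has5 else []
    utr3_segs = [_utr_seg_len(rng, cfg, "UTR3") for _ in range(k3 + 1)] if has3 else []

    intron_lens = (
        [_intron_len(rng, cfg, "UTR5") for _ in range(len(utr5_segs) - 1 if utr5_segs else 0)]
        + [_intron_len(rng, cfg, "CDS") for _ in cds_junctions]
        + [_intron_len(rng, cfg, "UTR3") for _ in range(len(utr3_segs) - 1 if utr3_segs else 0)]
    )
    return _Layout(utr5_segs, cds_len, cds_junctions, utr3_segs, intron_lens)


def _realize(
    layout: _Layout, tid: str, scaffold: str, strand: str, origin: int
) -> Transcript:
    """Place a spliced layout on the genome at ``origin`` (leftmost base)."""
    exon_lens = layout.exon_lengths()
    introns = layout.intron_lens
    assert len(introns) == len(exon_lens) - 1
    if strand == "-":
        exon_lens = exon_lens[::-1]
        introns = introns[::-1]
    exons: list[Interval] = []
    pos = origin
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < len(introns):
            pos += introns[i]
    # CDS occupies spliced interval [utr5_len, utr5_len + cds_len)
    c0 = layout.utr5_len
    c1 = c0 + layout.cds_len
    t = Transcript(id=tid, scaffold=scaffold, strand=strand, exons=exons)
    cds: list[Interval] = []
    tx_exons = exons if strand == "+" else exons[::-1]
    off = 0
    for s, e in tx_exons:
        a, b = off, off + (e - s)
        lo, hi = max(a, c0), min(b, c1)
        if lo < hi:
            if strand == "+":
                cds.append((s + (lo - a), s + (hi - a)))
            else:
                cds.append((e - (hi - a), e - (lo - a)))
        off = b
    t.cds = sorted(cds)
    return derive_transcript_regions(t)


# --- alternative-splicing edits (genomic coordinates, strand aware) --------


class UnsuitableLocus(ValueError):
    """The base isoform lacks the structure the requested edit needs."""


def _reclip_cds(t: Transcript, exons: list[Interval]) -> list[Interval]:
    if not t.cds:
        return []
    lo = min(s for s, _ in t.cds)
    hi = max(e for _, e in t.cds)
    return cds_from_span(exons, lo, hi)


def _introns_in_region(t: Transcript, region: Optional[str]) -> list[int]:
    """Genomic indices of introns (by gap order) in the given region class."""
    gaps = t.intron_intervals()
    out = []
    for idx, gap in enumerate(gaps):
        rec = next(i for i in t.introns if i.interval == gap)
        if region is None or rec.region == region:
            out.append(idx)
    return out


def apply_as_edit(
    base: Transcript,
    event_type: str,
    rng: np.random.Generator,
    region: Optional[str] = None,
    alt_id: Optional[str] = None,
    min_intron: int = 20,
) -> Transcript:
    """Derive a second isoform from ``base`` exhibiting ``event_type``.

    ``region`` restricts the edit to introns/exons of that class (UTR5, CDS,
    UTR3).  Raises :class:`UnsuitableLocus` when the base structure cannot
    host the event.
    """
    if event_type == "spliced_intron":
        event_type = "retained_intron"
    if event_type == "retained_exon":
        event_type = "skipped_exon"
    exons = list(base.exons)
    gaps = base.intron_intervals()
    strand = base.strand
    tid = alt_id or f"{base.id}x"

    def finish(new_exons: list[Interval]) -> Transcript:
        t = Transcript(
            id=tid, scaffold=base.scaffold, strand=strand,
            exons=new_exons, cds=_reclip_cds(base, new_exons),
        )
        return derive_transcript_regions(t)

    if event_type == "retained_intron":
        cands = _introns_in_region(base, region)
        if not cands:
            raise UnsuitableLocus("no intron available for retention")
        j = int(rng.choice(cands))
        merged = exons[: j] + [(exons[j][0], exons[j + 1][1])] + exons[j + 2 :]
        return finish(merged)

    if event_type in ("alt_acceptor", "alt_donor"):
        cands = [
            j for j in _introns_in_region(base, region)
            if gaps[j][1] - gaps[j][0] >= min_intron + 12
        ]
        if not cands:
            raise UnsuitableLocus("no intron long enough for an alt splice site")
        j = int(rng.choice(cands))
        s, e = gaps[j]
        delta = min(30, (e - s) - min_intron - 1)
        # donor = transcript-5' end of the intron; move the *other* end to
        # produce the requested event
        shift_right_end = (event_type == "alt_acceptor") == (strand == "+")
        new_exons = list(exons)
        if shift_right_end:
            new_exons[j + 1] = (e - delta, exons[j + 1][1])  # acceptor/donor moves left
        else:
            new_exons[j] = (exons[j][0], s + delta)
        return finish(new_exons)

    if event_type == "skipped_exon":
        cands = []
        for k in range(1, len(exons) - 1):
            if region is not None:
                rec_l = next(i for i in base.introns if i.interval == gaps[k - 1])
                rec_r = next(i for i in base.introns if i.interval == gaps[k])
                if not (rec_l.region == region and rec_r.region == region):
                    continue
            cands.append(k)
        if not cands:
            raise UnsuitableLocus("no internal exon with same-region flanks to skip")
        k = int(rng.choice(cands))
        return finish(exons[:k] + exons[k + 1 :])

    if event_type == "alternate_exon":
        # shift an internal exon rightwards inside its downstream intron
        cands = []
        for k in range(1, len(exons) - 1):
            es, ee = exons[k]
            room = gaps[k][1] - gaps[k][0]
            need = (ee - es) + 2 * min_intron + 4
            if room < need:
                continue
            if region is not None:
                rec_l = next(i for i in base.introns if i.interval == gaps[k - 1])
                rec_r = next(i for i in base.introns if i.interval == gaps[k])
                if not (rec_l.region == region and rec_r.region == region):
                    continue
            cands.append(k)
        if not cands:
            raise UnsuitableLocus("no internal exon with room for an alternate exon")
        k = int(rng.choice(cands))
        es, ee = exons[k]
        d = (ee - es) + min_intron + 2
        new_exons = list(exons)
        new_exons[k] = (es + d, ee + d)
        return finish(new_exons)

    if event_type in ("starts_in_intron", "ends_in_intron"):
        # the terminus lands in a UTR-side intron so the CDS is untouched
        at_tx5 = event_type == "starts_in_intron"
        want_region = region or ("UTR5" if at_tx5 else "UTR3")
        cands = [
            j for j in _introns_in_region(base, want_region)
            if gaps[j][1] - gaps[j][0] >= 4
        ]
        if not cands:
            raise UnsuitableLocus(f"no {want_region} intron to truncate into")
        at_genomic_left = at_tx5 == (strand == "+")
        j = int(rng.choice(cands))
        s, e = gaps[j]
        mid = (s + e) // 2
        if at_genomic_left:
            new_exons = [(mid, exons[j + 1][1])] + exons[j + 2 :]
        else:
            new_exons = exons[:j] + [(exons[j][0], mid)]
        return finish(new_exons)

    raise ValueError(f"unknown AS event type {event_type!r}")


_AS_REQUIREMENTS = {
    # (min UTR5 introns, min CDS introns, min UTR3 introns) by (event, region)
    ("retained_intron", "UTR5"): (1, 0, 0),
    ("retained_intron", "CDS"): (0, 1, 0),
    ("alt_acceptor", "UTR5"): (1, 0, 0),
    ("alt_acceptor", "CDS"): (0, 1, 0),
    ("alt_donor", "UTR5"): (1, 0, 0),
    ("alt_donor", "CDS"): (0, 1, 0),
    ("skipped_exon", "UTR5"): (2, 0, 0),
    ("skipped_exon", "CDS"): (0, 2, 0),
    ("alternate_exon", "UTR5"): (2, 0, 0),
    ("alternate_exon", "CDS"): (0, 2, 0),
    ("starts_in_intron", "UTR5"): (1, 0, 0),
    ("ends_in_intron", "UTR3"): (0, 0, 1),
}


def generate_as_locus(
    event_type: str,
    seed: int = 0,
    region: Optional[str] = None,
    strand: Optional[str] = None,
    cfg: Optional[GenomeConfig] = None,
    locus_id: str = "as_locus",
    origin: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> Gene:
    """Construct a two-isoform locus exhibiting exactly ``event_type``."""
    canonical = {"spliced_intron": "retained_intron", "retained_exon": "skipped_exon"}
    key_event = canonical.get(event_type, event_type)
    if key_event not in EVENT_TYPES:
        raise ValueError(f"unknown AS event type {event_type!r}")
    cfg = cfg or GenomeConfig()
    rng = rng if rng is not None else np.random.default_rng(seed)
    if region is None:
        if key_event == "starts_in_intron":
            region = "UTR5"
        elif key_event == "ends_in_intron":
            region = "UTR3"
        else:
            region = "CDS" if rng.random() < cfg.p_event_in_cds else "UTR5"
    k5, kcds, k3 = _AS_REQUIREMENTS[(key_event, region)]
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    for _ in range(20):
        layout = _build_layout(rng, cfg, min_k5=k5, min_kcds=kcds, min_k3=k3)
        if key_event == "alternate_exon":
            # widen introns so the largest internal exon fits inside one
            lens = layout.exon_lengths()
            if len(lens) > 2:
                need = max(lens[1:-1]) + 2 * cfg.min_intron + 10
                layout.intron_lens = [max(l, need) for l in layout.intron_lens]
        t1 = _realize(layout, f"{locus_id}.1", "scaffold_sim", strand, origin)
        try:
            t2 = apply_as_edit(t1, event_type, rng, region=region,
                               alt_id=f"{locus_id}.2", min_intron=cfg.min_intron)
        except UnsuitableLocus:
            continue
        return Gene(locus_id, "scaffold_sim", strand, [t1, t2])
    raise UnsuitableLocus(
        f"could not build a locus for {event_type} in {region} after 20 tries"
    )


def generate_genome(
    cfg: GenomeConfig, out_gff: Optional[Path] = None
) -> tuple[GenomeAnnotation, GenomeTruth]:
    """Generate a structurally valid annotation with planted truth.

    Exactly ``round(as_fraction * n_genes)`` loci carry one planted AS event
    (types drawn from ``as_event_mix``); all remaining loci are
    single-isoform.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.as_fraction > 0 and not cfg.p_utr5:
        raise ValueError("AS events in UTRs require a nonzero UTR probability")
    n_as = int(round(cfg.as_fraction * cfg.n_genes))
    as_ids = set(rng.choice(cfg.n_genes, size=n_as, replace=False).tolist())
    mix_types = list(cfg.as_event_mix)
    mix_p = np.asarray([cfg.as_event_mix[t] for t in mix_types], dtype=float)
    mix_p /= mix_p.sum()

    truth = GenomeTruth()
    genes: list[Gene] = []
    cursor = 1000
    scaffold_idx = 0
    for gi in range(cfg.n_genes):
        if gi % cfg.genes_per_scaffold == 0 and gi > 0:
            scaffold_idx += 1
            cursor = 1000
        scaffold = f"scaffold_{scaffold_idx + 1}"
        gid = f"g{gi + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if gi in as_ids:
            etype = str(rng.choice(mix_types, p=mix_p))
            gene = generate_as_locus(
                etype, region=None, strand=strand, cfg=cfg,
                locus_id=gid, origin=cursor, rng=rng,
            )
            for t in gene.transcripts:
                t.scaffold = scaffold
            gene.scaffold = scaffold
            truth.as_events[gid] = etype
            truth.as_loci.append(gid)
            ref = gene.transcripts[0]
        else:
            layout = _build_layout(rng, cfg)
            ref = _realize(layout, f"{gid}.1", scaffold, strand, cursor)
            gene = Gene(gid, scaffold, strand, [ref])
        for t in gene.transcripts:
            t.est_supported = bool(rng.random() < cfg.p_est)
        truth.exon_counts[gid] = len(ref.exons)
        truth.intron_lengths[gid] = {"UTR5": [], "CDS": [], "UTR3": []}
        for i in ref.introns:
            truth.intron_lengths[gid][i.region].append(i.length)
        genes.append(gene)
        cursor = gene.span[1] + int(rng.integers(cfg.gap_min, cfg.gap_max + 1))

    ann = GenomeAnnotation(cfg.species_label, genes, genome_size=cfg.genome_size)
    if out_gff is not None:
        from .io import write_gff3

        write_gff3(ann, out_gff)
    return ann, truth


def random_isoform_pair(
    rng: np.random.Generator,
    cfg: Optional[GenomeConfig] = None,
    max_edits: int = 2,
) -> tuple[Transcript, Transcript]:
    """A random two-isoform locus: a base transcript plus 1..``max_edits``
    stacked random edits.  Used to stress the event classifier against an
    independent re-implementation."""
    cfg = cfg or GenomeConfig()
    while True:
        strand = "+" if rng.random() < 0.5 else "-"
        layout = _build_layout(rng, cfg, min_kcds=1)
        t1 = _realize(layout, "iso.1", "scaffold_sim", strand, 0)
        t2 = t1
        n_edits = int(rng.integers(1, max_edits + 1))
        applied = 0
        for _ in range(n_edits):
            etype = str(rng.choice(EVENT_TYPES))
            try:
                t2 = apply_as_edit(t2, etype, rng, alt_id="iso.2",
                                   min_intron=cfg.min_intron)
                applied += 1
            except UnsuitableLocus:
                continue
        if applied:
            return t1, t2


# ---------------------------------------------------------------------------
# cluster sets with planted intron loss and expansions


@dataclass
class ClusterConfig:
    seed: int = 0
    focal_species: str = "Ppa"
    other_species: tuple[str, ...] = ("Ath", "Osa", "Cre")
    n_focal_genes: int = 2000
    focal_only_fraction: float = 0.48  # of focal loci in focal-only clusters
    loss_fraction: float = 0.14  # of all focal genes: reduced (incl. full)
    full_loss_fraction: float = 0.03  # of all focal genes: zero introns
    fragmentary_rate: float = 0.03  # decoys excluded by the length filter
    n_expansions: int = 20  # clusters with focal count > max other
    n_strong_expansions: int = 5  # subset with focal count > 2 x max other
    orphan_no_homolog_fraction: float = 0.222  # of all focal loci
    orphan_with_est_fraction: float = 0.129
    length_ratio_threshold: float = 0.5
    base_transcript_length: int = 1500


@dataclass
class ClusterTruth:
    loss_class: dict[str, str] = field(default_factory=dict)
    orphan_class: dict[str, str] = field(default_factory=dict)
    expansion_clusters: set[str] = field(default_factory=set)
    strong_expansion_clusters: set[str] = field(default_factory=set)
    n_focal_genes: int = 0


def _uniform_gene(
    gid: str, scaffold: str, n_exons: int, total_len: int, origin: int
) -> Gene:
    """Single-transcript gene with ``n_exons`` exons summing to ``total_len``."""
    base = total_len // n_exons
    lens = [base] * n_exons
    lens[-1] += total_len - base * n_exons
    exons = []
    pos = origin
    for el in lens:
        exons.append((pos, pos + el))
        pos += el + 100
    t = Transcript(id=f"{gid}.1", scaffold=scaffold, strand="+", exons=exons)
    t.cds = list(exons)
    derive_transcript_regions(t)
    return Gene(gid, scaffold, "+", [t])


def generate_cluster_set(
    cfg: ClusterConfig, out_dir: Optional[Path] = None
) -> tuple[
    list[Cluster], dict[str, GenomeAnnotation], dict[str, bool], dict[str, bool], ClusterTruth
]:
    """Build clusters + per-species annotations with planted intron losses.

    Shared clusters hold one focal gene plus several non-focal members whose
    intron-count median is at least 2.  Loss, full-loss, and fragmentary
    counts are planted exactly (rounded from the configured fractions of all
    focal genes); expansions are planted as dedicated clusters.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = ClusterTruth(n_focal_genes=cfg.n_focal_genes)
    n = cfg.n_focal_genes
    n_focal_only = int(round(cfg.focal_only_fraction * n))
    n_full = int(round(cfg.full_loss_fraction * n))
    n_reduced = int(round(cfg.loss_fraction * n)) - n_full
    n_frag = int(round(cfg.fragmentary_rate * n))
    n_exp_members = cfg.n_expansions * 3 + cfg.n_strong_expansions * 2
    n_shared = n - n_focal_only
    if n_full + n_reduced + n_frag + n_exp_members > n_shared:
        raise ValueError("planted fractions exceed the shared-cluster budget")

    focal_genes: list[Gene] = []
    other_genes: dict[str, list[Gene]] = {sp: [] for sp in cfg.other_species}
    clusters: list[Cluster] = []
    has_hit: dict[str, bool] = {}
    est: dict[str, bool] = {}
    origin = {sp: 1000 for sp in (cfg.focal_species, *cfg.other_species)}
    counters = {sp: 0 for sp in cfg.other_species}
    L = cfg.base_transcript_length

    def new_other(sp: str, n_exons: int) -> str:
        counters[sp] += 1
        gid = f"{sp}g{counters[sp]:05d}"
        g = _uniform_gene(gid, f"{sp}_scaf", n_exons, L, origin[sp])
        origin[sp] = g.span[1] + 500
        other_genes[sp].append(g)
        return gid

    def new_focal(gid: str, n_exons: int, total_len: int) -> None:
        g = _uniform_gene(gid, "Ppa_scaf", n_exons, total_len, origin[cfg.focal_species])
        origin[cfg.focal_species] = g.span[1] + 500
        focal_genes.append(g)

    gi = 0
    cid = 0

    def next_gid() -> str:
        nonlocal gi
        gi += 1
        return f"{cfg.focal_species}g{gi:05d}"

    def shared_cluster(
        focal_ids: Sequence[str],
        other_exon_counts: Sequence[int],
        other_species: Optional[Sequence[str]] = None,
    ) -> Cluster:
        nonlocal cid
        cid += 1
        members = [(cfg.focal_species, g) for g in focal_ids]
        for i, ec in enumerate(other_exon_counts):
            if other_species is not None:
                sp = other_species[i]
            else:
                sp = cfg.other_species[i % len(cfg.other_species)]
            members.append((sp, new_other(sp, ec)))
        c = Cluster(f"C{cid:05d}", members)
        clusters.append(c)
        return c

    # planted loss genes: non-focal exon counts {5,7,9} -> median introns 6
    other_counts = [5, 7, 9]
    for _ in range(n_full):
        gid = next_gid()
        new_focal(gid, 1, L)
        shared_cluster([gid], other_counts)
        truth.loss_class[gid] = "full_loss"
    for _ in range(n_reduced):
        gid = next_gid()
        k = int(rng.integers(1, 6))  # 1..5 introns, all < median 6
        new_focal(gid, k + 1, L)
        shared_cluster([gid], other_counts)
        truth.loss_class[gid] = "reduced_introns"
    for _ in range(n_frag):
        gid = next_gid()
        new_focal(gid, 1, int(L * cfg.length_ratio_threshold * 0.5))
        shared_cluster([gid], other_counts)
        truth.loss_class[gid] = "fragmentary"
    # planted expansions: max other-species count is 2, so focal 3 is an
    # expansion (3 > 2 but not > 4) and focal 5 a strong one (5 > 4)
    for i in range(cfg.n_expansions):
        strong = i < cfg.n_strong_expansions
        focal_n = 5 if strong else 3
        ids = [next_gid() for _ in range(focal_n)]
        for g in ids:
            new_focal(g, 7, L)
            truth.loss_class[g] = "none"
        sp0 = cfg.other_species[0]
        c = shared_cluster(ids, [7, 7], other_species=[sp0, sp0])
        truth.expansion_clusters.add(c.id)
        if strong:
            truth.strong_expansion_clusters.add(c.id)
    # ordinary shared genes: intron count equals the cluster median
    while gi < n_shared:
        gid = next_gid()
        new_focal(gid, 7, L)
        shared_cluster([gid], other_counts)
        truth.loss_class[gid] = "none"
    # focal-only loci with orphan classes
    n_orphan = int(round(cfg.orphan_no_homolog_fraction * n))
    n_orphan_est = int(round(cfg.orphan_with_est_fraction * n))
    if n_orphan + n_orphan_est > n_focal_only:
        raise ValueError("orphan fractions exceed the focal-only budget")
    for i in range(n_focal_only):
        gid = next_gid()
        new_focal(gid, int(rng.integers(1, 4)), 450)
        cid += 1
        clusters.append(Cluster(f"C{cid:05d}", [(cfg.focal_species, gid)]))
        truth.loss_class[gid] = "none"
        if i < n_orphan:
            truth.orphan_class[gid] = "orphan_no_homolog"
            has_hit[gid], est[gid] = False, False
        elif i < n_orphan + n_orphan_est:
            truth.orphan_class[gid] = "orphan_with_est"
            has_hit[gid], est[gid] = False, True
        else:
            truth.orphan_class[gid] = "focal_only_with_homolog"
            has_hit[gid], est[gid] = True, bool(rng.random() < 0.5)
    for g in focal_genes:
        if g.id not in truth.orphan_class:
            truth.orphan_class[g.id] = "has_plant_family"
            has_hit.setdefault(g.id, True)
            est.setdefault(g.id, True)

    annotations = {cfg.focal_species: GenomeAnnotation(cfg.focal_species, focal_genes)}
    for sp, gs in other_genes.items():
        annotations[sp] = GenomeAnnotation(sp, gs)

    if out_dir is not None:
        from .io import write_clusters, write_gff3

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_clusters(clusters, out_dir / "clusters.txt")
        for sp, ann in annotations.items():
            write_gff3(ann, out_dir / f"{sp}.gff3")
        with open(out_dir / "hits.tsv", "w") as fh:
            fh.write("gene_id\thas_hit\n")
            for g, h in sorted(has_hit.items()):
                fh.write(f"{g}\t{int(h)}\n")
        with open(out_dir / "est.tsv", "w") as fh:
            fh.write("gene_id\test_supported\n")
            for g, e in sorted(est.items()):
                fh.write(f"{g}\t{int(e)}\n")
    return clusters, annotations, has_hit, est, truth


# ---------------------------------------------------------------------------
# GOA pairs with planted enrichment


@dataclass
class GoaPairConfig:
    seed: int = 0
    n_genes_focal: int = 2000
    n_genes_other: int = 2000
    n_null_terms: int = 200
    n_planted_terms: int = 5
    fold: float = 4.0
    base_freq_range: tuple[float, float] = (0.02, 0.08)
    aspect: str = "BP"
    evidence_code: str = "IEA"


def generate_goa_pair(
    cfg: GoaPairConfig, out_dir: Optional[Path] = None
) -> tuple[list[GoAnnotation], list[GoAnnotation], list[str]]:
    """Two GAF-ready annotation sets; planted terms are ``fold`` times more
    frequent in the focal set.  Returns (focal, other, planted term ids)."""
    rng = np.random.default_rng(cfg.seed)
    n_terms = cfg.n_null_terms + cfg.n_planted_terms
    terms = [f"GO:{7000000 + i}" for i in range(n_terms)]
    planted = terms[: cfg.n_planted_terms]
    base = rng.uniform(*cfg.base_freq_range, size=n_terms)
    freq_other = base
    freq_focal = base.copy()
    freq_focal[: cfg.n_planted_terms] = np.minimum(
        0.9, base[: cfg.n_planted_terms] * cfg.fold
    )

    def sample(n_genes: int, prefix: str, freqs: np.ndarray) -> list[GoAnnotation]:
        hits = rng.random((n_genes, n_terms)) < freqs[None, :]
        out = []
        for gi, ti in zip(*np.nonzero(hits)):
            out.append(
                GoAnnotation(
                    f"{prefix}{gi + 1:05d}", terms[ti], cfg.aspect, cfg.evidence_code
                )
            )
        return out

    focal = sample(cfg.n_genes_focal, "F", freq_focal)
    other = sample(cfg.n_genes_other, "O", freq_other)
    if out_dir is not None:
        from .io import write_gaf

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gaf(focal, out_dir / "focal.gaf")
        write_gaf(other, out_dir / "other.gaf")
    return focal, other, planted


# ---------------------------------------------------------------------------
# subcellular predictor calls


DEFAULT_COMPARTMENT_GO = {
    "chloroplast": "GO:0009507",
    "mitochondrion": "GO:0005739",
    "secretory": "GO:0005576",
    "nucleus": "GO:0005634",
    "cytosol": "GO:0005829",
}

DEFAULT_TOOLS = (
    ("TAPScan", False),
    ("MultiLoc", False),
    ("WolfPSORT", False),
    ("TargetP", True),
    ("ChloroP", True),
    ("SignalP", True),
    ("HMMTOP", False),
    ("MEMSAT3", False),
)


@dataclass
class PredictorConfig:
    seed: int = 0
    n_proteins: int = 200
    accuracy: float = 1.0
    incomplete_fraction: float = 0.2
    tools: tuple[tuple[str, bool], ...] = DEFAULT_TOOLS  # (name, n_terminal_only)
    weights: Optional[dict[str, float]] = None


def generate_predictor_calls(cfg: PredictorConfig):
    """Predictor call table with planted true localizations.

    Returns (calls, tool_configs, complete_flags, truth) where truth maps
    protein id -> true GO CC term.
    """
    from .functional_annotation import PredictorCall, ToolConfig

    rng = np.random.default_rng(cfg.seed)
    compartments = sorted(DEFAULT_COMPARTMENT_GO)
    tools = {
        name: ToolConfig(
            name=name,
            weight=(cfg.weights or {}).get(name, 1.0),
            n_terminal_only=nterm,
            compartment_map=dict(DEFAULT_COMPARTMENT_GO),
        )
        for name, nterm in cfg.tools
    }
    calls: list[PredictorCall] = []
    complete: dict[str, bool] = {}
    truth: dict[str, str] = {}
    for pi in range(cfg.n_proteins):
        pid = f"P{pi + 1:05d}"
        true_c = compartments[int(rng.integers(len(compartments)))]
        truth[pid] = DEFAULT_COMPARTMENT_GO[true_c]
        complete[pid] = bool(rng.random() >= cfg.incomplete_fraction)
        for name in tools:
            if rng.random() < cfg.accuracy:
                called = true_c
            else:
                wrong = [c for c in compartments if c != true_c]
                called = wrong[int(rng.integers(len(wrong)))]
            calls.append(PredictorCall(name, pid, called, round(float(rng.random()), 6)))
    return calls, tools, complete, truth


# ---------------------------------------------------------------------------
# codon sequences with tunable synonymous bias


@dataclass
class CdsBiasConfig:
    seed: int = 0
    n_codons: int = 300
    bias: float = 0.0  # 0 = uniform synonymous usage, 1 = one codon per aa


def generate_biased_cds(cfg: CdsBiasConfig) -> str:
    """Codon sequence whose synonymous usage interpolates between uniform
    (bias 0, Nc near 61) and maximally biased (bias 1, Nc 20)."""
    from .codon_usage import _FAMILIES

    rng = np.random.default_rng(cfg.seed)
    aas = sorted(_FAMILIES)
    codons = []
    for _ in range(cfg.n_codons):
        aa = aas[int(rng.integers(len(aas)))]
        fam = sorted(_FAMILIES[aa])
        k = len(fam)
        w = np.full(k, (1.0 - cfg.bias) / k)
        w[0] += cfg.bias
        codons.append(fam[int(rng.choice(k, p=w / w.sum()))])
    return "".join(codons)
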