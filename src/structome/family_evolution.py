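"""Gene-family analyses: representative isoforms, size profiles, orphan
classes and cluster-based inference of secondary intron loss.

The intron-loss rule compares a focal gene's intron count with the
interpolated median intron count of the non-focal members of its family;
strictly fewer introns is a reduced-intron call, zero introns against a
median of at least one is additionally a full loss (putative retrocopy).
Focal models shorter than a configurable fraction (default 0.5) of the
median non-focal transcript length are flagged fragmentary and excluded
from calling, since truncated predictions mimic intron loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import Cluster, GenomeAnnotation, Transcript
from .structure_stats import representative_transcript


def pairwise_uncorrected_distance(aligned_a: str, aligned_b: str) -> Optional[float]:
    """Uncorrected p-distance between two aligned sequences.

    Mismatches over compared positions; any position where either sequence
    has a gap is excluded.  Returns ``None`` when no positions are compared.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    compared = mismatches = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in "-." or y in "-.":
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        return None
    return mismatches / compared


@dataclass
class RepresentativeChoice:
    locus_id: str
    transcript_id: str
    tier: str  # "min_distance" | "best_hit_coverage" | "longest_transcript"
    value: float


def select_representative(
    cluster: Cluster,
    focal_species: str,
    isoform_to_locus: Mapping[str, str],
    distances: Optional[Mapping[tuple[str, str], float]] = None,
    hit_coverage: Optional[Mapping[str, float]] = None,
    transcript_lengths: Optional[Mapping[str, int]] = None,
) -> list[RepresentativeChoice]:
    """Pick one representative isoform per focal locus in a cluster.

    Tier 1 (clusters with at least one non-focal member): the isoform with
    the minimum pairwise distance to any non-focal member.  Tier 2
    (focal-only clusters with homology hits): the isoform covering its best
    hit most completely.  Tier 3: the longest transcript.  All ties break to
    the lexicographically smallest transcript id.
    """
    focal_isoforms = cluster.members_of(focal_species)
    others = [(sp, g) for sp, g in cluster.members if sp != focal_species]
    by_locus: dict[str, list[str]] = {}
    for iso in focal_isoforms:
        locus = isoform_to_locus.get(iso, iso)
        by_locus.setdefault(locus, []).append(iso)

    choices = []
    for locus, isoforms in sorted(by_locus.items()):
        if others:
            if distances is None:
                raise ValueError("tier-1 selection needs a distance matrix")
            scored = []
            for iso in isoforms:
                ds = []
                for _, og in others:
                    d = distances.get((iso, og), distances.get((og, iso)))
                    if d is not None:
                        ds.append(d)
                if not ds:
                    raise KeyError(
                        f"isoform {iso} absent from the distance matrix"
                    )
                scored.append((min(ds), iso))
            best = min(scored, key=lambda x: (x[0], x[1]))
            choices.append(RepresentativeChoice(locus, best[1], "min_distance", best[0]))
        elif hit_coverage and any(iso in hit_coverage for iso in isoforms):
            scored = [(hit_coverage.get(iso, 0.0), iso) for iso in isoforms]
            # highest coverage wins; ties to the smallest transcript id
            top = max(s for s, _ in scored)
            best_iso = min(iso for s, iso in scored if s == top)
            choices.append(
                RepresentativeChoice(locus, best_iso, "best_hit_coverage", top)
            )
        else:
            if transcript_lengths is None:
                raise ValueError("tier-3 selection needs transcript lengths")
            top = max(transcript_lengths.get(iso, 0) for iso in isoforms)
            best_iso = min(
                iso for iso in isoforms if transcript_lengths.get(iso, 0) == top
            )
            choices.append(
                RepresentativeChoice(locus, best_iso, "longest_transcript", float(top))
            )
    return choices


@dataclass
class FamilyProfile:
    cluster_id: str
    counts: dict[str, int]  # species -> member count
    focal_only: bool
    shared_with: set[str]
    expansion: bool  # focal count > max other (shared clusters only)
    strong_expansion: bool  # focal count > 2 x max other


@dataclass
class FamilySummary:
    profiles: list[FamilyProfile]
    focal_only_cluster_count: int
    shared_cluster_count: int
    focal_only_locus_fraction: float
    n_focal_loci: int
    expansion_count: int
    strong_expansion_count: int
    size_distributions: pd.DataFrame  # shared clusters only (Figure-7 analog)


def family_profile(clusters: Sequence[Cluster], focal_species: str) -> FamilySummary:
    """Per-cluster per-species counts, focal-only and expansion flags.

    Size-frequency distributions are restricted to clusters containing the
    focal species plus at least one other (the conserved-cluster view).
    Expansion: focal count strictly greater than the largest non-focal count;
    strong expansion: strictly greater than twice the largest.
    """
    if not clusters:
        raise ValueError("no clusters")
    profiles = []
    n_focal_loci = 0
    n_focal_only_loci = 0
    dist_rows = []
    for c in clusters:
        counts = c.counts_by_species()
        focal_n = counts.get(focal_species, 0)
        others = {sp: n for sp, n in counts.items() if sp != focal_species}
        focal_only = focal_n > 0 and not others
        shared = focal_n > 0 and bool(others)
        max_other = max(others.values()) if others else 0
        profiles.append(
            FamilyProfile(
                cluster_id=c.id,
                counts=counts,
                focal_only=focal_only,
                shared_with=set(others),
                expansion=shared and focal_n > max_other,
                strong_expansion=shared and focal_n > 2 * max_other,
            )
        )
        n_focal_loci += focal_n
        if focal_only:
            n_focal_only_loci += focal_n
        if shared:
            dist_rows.append({"cluster_id": c.id, **counts})
    size_dist = pd.DataFrame(dist_rows).set_index("cluster_id") if dist_rows else pd.DataFrame()
    return FamilySummary(
        profiles=profiles,
        focal_only_cluster_count=sum(1 for p in profiles if p.focal_only),
        shared_cluster_count=sum(1 for p in profiles if p.shared_with),
        focal_only_locus_fraction=(n_focal_only_loci / n_focal_loci) if n_focal_loci else float("nan"),
        n_focal_loci=n_focal_loci,
        expansion_count=sum(1 for p in profiles if p.expansion),
        strong_expansion_count=sum(1 for p in profiles if p.strong_expansion),
        size_distributions=size_dist,
    )


@dataclass(frozen=True)
class OrphanCall:
    gene_id: str
    klass: str  # has_plant_family | focal_only_with_homolog | orphan_no_homolog | orphan_with_est


def classify_orphans(
    clusters: Sequence[Cluster],
    focal_species: str,
    has_hit: Mapping[str, bool],
    est_supported: Mapping[str, bool],
) -> list[OrphanCall]:
    """Classify focal loci: family membership beats hits; among focal-only
    loci, homology hits beat transcript evidence; orphans split on EST."""
    calls: dict[str, str] = {}
    for c in clusters:
        multi_species = len(c.species() - {focal_species}) > 0
        for gid in c.members_of(focal_species):
            if multi_species:
                calls[gid] = "has_plant_family"
            elif calls.get(gid) != "has_plant_family":
                if has_hit.get(gid, False):
                    calls[gid] = "focal_only_with_homolog"
                elif est_supported.get(gid, False):
                    calls[gid] = "orphan_with_est"
                else:
                    calls[gid] = "orphan_no_homolog"
    return [OrphanCall(g, k) for g, k in sorted(calls.items())]


@dataclass
class IntronLossCall:
    gene_id: str
    cluster_id: str
    focal_introns: int
    median_other_introns: float
    excluded_fragmentary: bool
    call: str  # "none" | "reduced_introns" | "full_loss"


_SEVERITY = {"none": 0, "reduced_introns": 1, "full_loss": 2}


@dataclass
class IntronLossSummary:
    calls: list[IntronLossCall]  # per (locus, cluster)
    per_locus: dict[str, str]  # most severe call per locus
    n_focal_genes: int
    n_reduced: int  # loci called reduced_introns or full_loss
    n_full_loss: int
    n_excluded: int
    reduced_fraction: float
    full_loss_fraction: float


def infer_intron_loss(
    clusters: Sequence[Cluster],
    annotations_by_species: Mapping[str, GenomeAnnotation],
    focal_species: str,
    length_ratio_threshold: float = 0.5,
) -> IntronLossSummary:
    """Infer secondary intron loss from cross-species family clusters.

    For each cluster with at least one non-focal member, ``m`` is the
    interpolated median intron count of the non-focal representative models.
    A focal gene whose representative transcript is shorter than
    ``length_ratio_threshold`` times the median non-focal transcript length
    is flagged fragmentary and receives no call.  Otherwise strictly fewer
    introns than ``m`` is ``reduced_introns``; zero introns with ``m >= 1``
    is ``full_loss``.  Genome fractions use all focal genes as denominator.
    """
    rep_cache: dict[str, Transcript] = {}
    gene_maps = {sp: ann.gene_by_id() for sp, ann in annotations_by_species.items()}

    def rep(sp: str, gid: str) -> Transcript:
        key = f"{sp}|{gid}"
        if key not in rep_cache:
            gmap = gene_maps.get(sp)
            if gmap is None or gid not in gmap:
                raise KeyError(f"cluster member {sp}|{gid} not found in annotations")
            rep_cache[key] = representative_transcript(gmap[gid])
        return rep_cache[key]

    calls: list[IntronLossCall] = []
    per_locus: dict[str, str] = {}
    excluded_loci: set[str] = set()
    for c in clusters:
        focal = c.members_of(focal_species)
        others = [(sp, g) for sp, g in c.members if sp != focal_species]
        if not focal or not others:
            continue
        other_introns = [len(rep(sp, g).exons) - 1 for sp, g in others]
        other_lengths = [rep(sp, g).spliced_length for sp, g in others]
        m = float(np.median(other_introns))
        med_len = float(np.median(other_lengths))
        for gid in focal:
            t = rep(focal_species, gid)
            n_introns = len(t.exons) - 1
            fragmentary = t.spliced_length < length_ratio_threshold * med_len
            if fragmentary:
                call = "none"
                excluded_loci.add(gid)
            elif n_introns == 0 and m >= 1:
                call = "full_loss"
            elif n_introns < m:
                call = "reduced_introns"
            else:
                call = "none"
            calls.append(
                IntronLossCall(gid, c.id, n_introns, m, fragmentary, call)
            )
            if not fragmentary:
                prev = per_locus.get(gid, "none")
                if _SEVERITY[call] > _SEVERITY[prev]:
                    per_locus[gid] = call
                else:
                    per_locus.setdefault(gid, prev)

    focal_ann = annotations_by_species.get(focal_species)
    if focal_ann is not None:
        n_focal = len(focal_ann.genes)
    else:
        n_focal = len({g for c in clusters for g in c.members_of(focal_species)})
    n_reduced = sum(1 for v in per_locus.values() if v in ("reduced_introns", "full_loss"))
    n_full = sum(1 for v in per_locus.values() if v == "full_loss")
    return IntronLossSummary(
        calls=calls,
        per_locus=per_locus,
        n_focal_genes=n_focal,
        n_reduced=n_reduced,
        n_full_loss=n_full,
        n_excluded=len(excluded_loci - set(per_locus)),
        reduced_fraction=n_reduced / n_focal if n_focal else float("nan"),
        full_loss_fraction=n_full / n_focal if n_focal else float("nan"),
    )
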