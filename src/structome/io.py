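"""Readers and writers for the formats the pipeline touches.

GFF3 parsing is delegated to :mod:`gffutils` (in-memory database); OBO
parsing to :mod:`obonet`.  The OrthoMCL-style cluster format and GAF 2.x are
simple line formats read directly.  External files use 1-based inclusive
coordinates (GFF3 standard); everything in memory is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import gffutils
import networkx as nx
import obonet

from .models import (
    Cluster,
    Gene,
    GenomeAnnotation,
    GoAnnotation,
    StructureError,
    Transcript,
    derive_all,
)

log = logging.getLogger(__name__)

_ASPECT_FROM_GAF = {"P": "BP", "F": "MF", "C": "CC"}
_ASPECT_TO_GAF = {v: k for k, v in _ASPECT_FROM_GAF.items()}


@dataclass
class Gff3Dialect:
    """Which feature types map onto the gene/transcript/exon/CDS hierarchy."""

    gene_types: tuple[str, ...] = ("gene",)
    transcript_types: tuple[str, ...] = ("mRNA", "transcript")
    exon_types: tuple[str, ...] = ("exon",)
    cds_types: tuple[str, ...] = ("CDS",)
    synthesize_orphan_genes: bool = False


class ClusterParseError(ValueError):
    pass


def read_gff3(
    path: Union[str, Path],
    dialect: Optional[Gff3Dialect] = None,
    species_label: str = "",
    genome_size: Optional[int] = None,
    derive: bool = True,
) -> GenomeAnnotation:
    """Read a GFF3 file into a :class:`GenomeAnnotation`.

    Features of types not named in the dialect are ignored.  UTR features in
    the input are ignored and re-derived from exon/CDS geometry.  An mRNA
    without a gene parent is an error unless the dialect enables synthesizing
    a single-transcript gene for it.
    """
    dialect = dialect or Gff3Dialect()
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )
    genes: list[Gene] = []
    claimed: set[str] = set()

    def build_transcript(feat) -> Transcript:
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(feat, featuretype=dialect.exon_types)
        )
        cds = sorted(
            (f.start - 1, f.end)
            for f in db.children(feat, featuretype=dialect.cds_types)
        )
        if not exons:
            # exon-less transcript: treat CDS intervals as exons
            exons = list(cds)
        return Transcript(
            id=feat.id, scaffold=feat.seqid, strand=feat.strand, exons=exons, cds=cds
        )

    for gfeat in db.features_of_type(dialect.gene_types, order_by="start"):
        transcripts = []
        for mfeat in db.children(gfeat, featuretype=dialect.transcript_types, level=1):
            claimed.add(mfeat.id)
            transcripts.append(build_transcript(mfeat))
        if transcripts:
            strands = {t.strand for t in transcripts}
            scaffolds = {t.scaffold for t in transcripts}
            if len(strands) > 1 or len(scaffolds) > 1:
                raise StructureError(
                    f"gene {gfeat.id} mixes scaffolds or strands across transcripts"
                )
            genes.append(
                Gene(gfeat.id, gfeat.seqid, gfeat.strand, sorted(transcripts, key=lambda t: t.id))
            )
    for mfeat in db.features_of_type(dialect.transcript_types, order_by="start"):
        if mfeat.id in claimed:
            continue
        parents = list(db.parents(mfeat, featuretype=dialect.gene_types))
        if parents:
            continue
        if not dialect.synthesize_orphan_genes:
            raise StructureError(f"transcript {mfeat.id} has no gene parent")
        t = build_transcript(mfeat)
        genes.append(Gene(f"{mfeat.id}.gene", mfeat.seqid, mfeat.strand, [t]))

    ann = GenomeAnnotation(
        species_label=species_label or Path(path).stem,
        genes=genes,
        genome_size=genome_size,
    )
    return derive_all(ann) if derive else ann


def write_gff3(annotation: GenomeAnnotation, path: Union[str, Path]) -> None:
    """Write gene/mRNA/exon/CDS features (derived UTRs are not emitted)."""
    lines = ["##gff-version 3"]
    for g in annotation.genes:
        gs, ge = g.span
        lines.append(
            "\t".join(
                [g.scaffold, "structome", "gene", str(gs + 1), str(ge), ".",
                 g.strand, ".", f"ID={g.id}"]
            )
        )
        for t in g.transcripts:
            ts, te = t.span
            lines.append(
                "\t".join(
                    [t.scaffold, "structome", "mRNA", str(ts + 1), str(te), ".",
                     t.strand, ".", f"ID={t.id};Parent={g.id}"]
                )
            )
            for i, (s, e) in enumerate(t.exons, 1):
                lines.append(
                    "\t".join(
                        [t.scaffold, "structome", "exon", str(s + 1), str(e), ".",
                         t.strand, ".", f"ID={t.id}.exon{i};Parent={t.id}"]
                    )
                )
            for i, (s, e) in enumerate(sorted(t.cds), 1):
                lines.append(
                    "\t".join(
                        [t.scaffold, "structome", "CDS", str(s + 1), str(e), ".",
                         t.strand, "0", f"ID={t.id}.cds{i};Parent={t.id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_clusters(path: Union[str, Path]) -> list[Cluster]:
    """Read an OrthoMCL-style groups file: ``clusterID: sp|gene sp|gene ...``.

    Duplicate (species, gene) pairs within a line are collapsed with a
    warning.  A member token without the ``|`` separator is a parse error
    reporting the line number.
    """
    clusters: list[Cluster] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            cid = tokens[0].rstrip(":")
            members: list[tuple[str, str]] = []
            seen: set[tuple[str, str]] = set()
            for tok in tokens[1:]:
                if "|" not in tok:
                    raise ClusterParseError(
                        f"{path} line {lineno}: member token {tok!r} lacks the "
                        "'species|gene' separator"
                    )
                sp, gid = tok.split("|", 1)
                if (sp, gid) in seen:
                    log.warning(
                        "cluster %s line %d: duplicate member %s|%s collapsed",
                        cid, lineno, sp, gid,
                    )
                    continue
                seen.add((sp, gid))
                members.append((sp, gid))
            clusters.append(Cluster(cid, members))
    return clusters


def write_clusters(clusters: Iterable[Cluster], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            toks = " ".join(f"{sp}|{g}" for sp, g in c.members)
            fh.write(f"{c.id}: {toks}\n")


@dataclass
class GafResult:
    """Parsed GAF annotations plus row-level errors (parse continues)."""

    annotations: list[GoAnnotation] = field(default_factory=list)
    errors: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.annotations)

    def __len__(self):
        return len(self.annotations)


def read_gaf(path: Union[str, Path]) -> GafResult:
    """Read a GAF 2.x file.

    Comment lines (``!``) are skipped; rows with fewer than 15 tab-separated
    columns are collected as errors; columns beyond 17 are ignored.  Rows
    whose qualifier contains ``NOT`` are excluded from all counting.
    """
    result = GafResult()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith("!"):
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 15:
                result.errors.append((lineno, f"expected >=15 columns, got {len(cols)}"))
                continue
            qualifier = cols[3]
            if "NOT" in qualifier.split("|"):
                continue
            aspect = _ASPECT_FROM_GAF.get(cols[8])
            if aspect is None:
                result.errors.append((lineno, f"unknown aspect {cols[8]!r}"))
                continue
            result.annotations.append(
                GoAnnotation(
                    gene_id=cols[1],
                    term=cols[4],
                    aspect=aspect,
                    evidence_code=cols[6],
                    source_ref=cols[5],
                )
            )
    return result


def write_gaf(
    annotations: Iterable[GoAnnotation], path: Union[str, Path], db: str = "structome"
) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for a in annotations:
            cols = [
                db, a.gene_id, a.gene_id, "", a.term, a.source_ref or "STRUCTOME:consensus",
                a.evidence_code, "", _ASPECT_TO_GAF[a.aspect], "", "", "protein",
                "taxon:3218", "20130101", db, "", "",
            ]
            fh.write("\t".join(cols) + "\n")


def read_obo(path) -> nx.MultiDiGraph:
    """Read an OBO file into a networkx graph (edges child -> parent).

    Obsolete terms are dropped by the reader.  A cycle over is_a/part_of is
    an error.
    """
    graph = obonet.read_obo(path)
    sub = _relation_subgraph(graph)
    if not nx.is_directed_acyclic_graph(sub):
        raise ValueError("ontology contains a cycle over is_a/part_of relations")
    return graph


_RELATIONS = ("is_a", "part_of")


def _relation_subgraph(graph: nx.MultiDiGraph) -> nx.DiGraph:
    sub = nx.DiGraph()
    sub.add_nodes_from(graph.nodes)
    for u, v, key in graph.edges(keys=True):
        if key in _RELATIONS:
            sub.add_edge(u, v)
    return sub


def ancestors(graph: nx.MultiDiGraph, term: str) -> set[str]:
    """All ancestors of ``term`` over is_a and part_of (term excluded)."""
    if term not in graph:
        return set()
    sub = _relation_subgraph(graph)
    return set(nx.descendants(sub, term))
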