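"""Canonical in-memory gene-model representation.

Coordinates are 0-based half-open internally; GFF3 I/O converts from the
1-based inclusive convention at the boundary.  A :class:`Transcript` carries
its annotated exons and CDS intervals; untranslated regions and introns are
*derived* from exon/CDS geometry (UTR features present in input files are
ignored), so there is a single authority for region classification.

Intron region classes (UTR5/CDS/UTR3) are decided purely in spliced (mRNA)
coordinates: an intron's splice junction is compared with the spliced offsets
of the CDS start and stop.  Introns always fall strictly between exons, so no
straddle case exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

Interval = tuple[int, int]  # 0-based half-open genomic interval


class StructureError(ValueError):
    """Raised when a gene model violates structural invariants."""


def interval_len(iv: Interval) -> int:
    return iv[1] - iv[0]


def total_length(ivs: Iterable[Interval]) -> int:
    return sum(e - s for s, e in ivs)


def _check_sorted_disjoint(ivs: Sequence[Interval], what: str, owner: str) -> None:
    for s, e in ivs:
        if e <= s:
            raise StructureError(f"empty or inverted {what} {s}-{e} in {owner}")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise StructureError(f"overlapping/unsorted {what}s in {owner}")


@dataclass
class IntronRecord:
    """A derived intron with its region class and spliced-junction offsets.

    ``donor_offset``/``acceptor_offset`` are measured in mRNA coordinates
    (nucleotides from the transcript 5' end).  An intron has zero spliced
    length, so both offsets equal the junction position.
    """

    start: int
    end: int
    region: str  # "UTR5" | "CDS" | "UTR3"
    donor_offset: int
    acceptor_offset: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass
class Transcript:
    id: str
    scaffold: str
    strand: str  # "+" | "-"
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    est_supported: bool = False
    has_start_codon: bool = True
    # derived by derive_transcript_regions()
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    introns: list[IntronRecord] = field(default_factory=list)
    _derived: bool = field(default=False, repr=False)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def spliced_length(self) -> int:
        return total_length(self.exons)

    @property
    def cds_length(self) -> int:
        return total_length(self.cds)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def intron_intervals(self) -> list[Interval]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def cds_chain(self) -> tuple:
        """Hashable identity of the encoded protein (CDS interval chain)."""
        return (self.strand, tuple(self.cds))

    def spliced_offset(self, pos: int) -> int:
        """Spliced (mRNA) offset of the exonic genomic base at ``pos``."""
        if self.strand == "+":
            acc = 0
            for s, e in self.exons:
                if s <= pos < e:
                    return acc + (pos - s)
                acc += e - s
        else:
            acc = 0
            for s, e in reversed(self.exons):
                if s <= pos < e:
                    return acc + (e - 1 - pos)
                acc += e - s
        raise StructureError(f"position {pos} is not exonic in transcript {self.id}")


@dataclass
class Gene:
    id: str
    scaffold: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    @property
    def length(self) -> int:
        s, e = self.span
        return e - s


@dataclass
class GenomeAnnotation:
    species_label: str
    genes: list[Gene] = field(default_factory=list)
    genome_size: Optional[int] = None  # base pairs

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise StructureError(f"duplicate gene identifier {g.id}")
            seen.add(g.id)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def transcripts(self) -> Iterator[Transcript]:
        for g in self.genes:
            yield from g.transcripts

    def gene_by_id(self) -> dict[str, Gene]:
        return {g.id: g for g in self.genes}

    def transcript_by_id(self) -> dict[str, Transcript]:
        return {t.id: t for t in self.transcripts()}


@dataclass
class Cluster:
    """A gene-family cluster: (species, gene) membership."""

    id: str
    members: list[tuple[str, str]]

    def species(self) -> set[str]:
        return {sp for sp, _ in self.members}

    def members_of(self, species: str) -> list[str]:
        return [g for sp, g in self.members if sp == species]

    def counts_by_species(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sp, _ in self.members:
            out[sp] = out.get(sp, 0) + 1
        return out


@dataclass(frozen=True)
class GoAnnotation:
    gene_id: str
    term: str
    aspect: str  # "BP" | "MF" | "CC"
    evidence_code: str
    source_ref: str = ""


def cds_from_span(exons: Sequence[Interval], start: int, end: int) -> list[Interval]:
    """Intersect a genomic CDS span (which may bridge introns) with exons."""
    out = []
    for s, e in exons:
        a, b = max(s, start), min(e, end)
        if a < b:
            out.append((a, b))
    return out


def derive_transcript_regions(t: Transcript) -> Transcript:
    """Fill ``utr5``, ``utr3`` and ``introns`` from exon/CDS geometry.

    The 5'-UTR is the exonic sequence 5' of the CDS start in transcript
    orientation, the 3'-UTR the exonic sequence 3' of the CDS stop.  Each
    intron is classified by comparing its spliced junction offset ``j`` with
    the CDS start offset ``c5`` and stop offset ``c3`` (exclusive):
    ``j <= c5`` is UTR5, ``j >= c3`` is UTR3, otherwise CDS.  Transcripts
    without CDS get no UTRs and all introns classified CDS.
    """
    _check_sorted_disjoint(t.exons, "exon", t.id)
    _check_sorted_disjoint(sorted(t.cds), "CDS interval", t.id)
    for c in t.cds:
        if not any(s <= c[0] and c[1] <= e for s, e in t.exons):
            raise StructureError(
                f"CDS interval {c[0]}-{c[1]} of transcript {t.id} "
                "is not contained in any exon"
            )
    total = t.spliced_length
    if t.cds:
        cds_sorted = sorted(t.cds)
        cds_lo, cds_hi = cds_sorted[0][0], cds_sorted[-1][1]
        if t.strand == "+":
            c5 = t.spliced_offset(cds_lo)
        else:
            c5 = t.spliced_offset(cds_hi - 1)
        c3 = c5 + t.cds_length
        # UTRs: exonic sequence genomically outside [cds_lo, cds_hi)
        left = [(s, min(e, cds_lo)) for s, e in t.exons if s < cds_lo]
        left = [(s, e) for s, e in left if s < e]
        right = [(max(s, cds_hi), e) for s, e in t.exons if e > cds_hi]
        right = [(s, e) for s, e in right if s < e]
        if t.strand == "+":
            t.utr5, t.utr3 = left, right
        else:
            t.utr5, t.utr3 = right, left
    else:
        c5, c3 = None, None
        t.utr5, t.utr3 = [], []

    introns: list[IntronRecord] = []
    acc = 0
    for (s1, e1), (s2, _) in zip(t.exons, t.exons[1:]):
        acc += e1 - s1
        j = acc if t.strand == "+" else total - acc
        if c5 is None:
            region = "CDS"
        elif j <= c5:
            region = "UTR5"
        elif j >= c3:
            region = "UTR3"
        else:
            region = "CDS"
        introns.append(IntronRecord(e1, s2, region, j, j))
    if t.strand == "-":
        introns.reverse()  # transcript order: 5' -> 3'
    t.introns = introns
    t._derived = True
    return t


def derive_all(annotation: GenomeAnnotation) -> GenomeAnnotation:
    for t in annotation.transcripts():
        derive_transcript_regions(t)
    return annotation
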