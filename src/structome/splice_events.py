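"""Pairwise alternative-splicing event classification and locus reports.

Events between two isoforms of a locus are detected only inside the genomic
overlap of the two transcripts, so differing transcript termini (TSS/poly-A
variation) outside the partner's span produce no event.  The ten-category
taxonomy:

- ``alt_donor`` / ``alt_acceptor``: two introns share one splice site (the
  donor is the transcript-5' end of the intron, strand-aware) but not the
  other.
- ``retained_intron`` / ``spliced_intron``: an intron of one transcript lies
  strictly inside an exon of the other; the exon carrier retains, the intron
  carrier splices.  Always emitted as a complementary pair.
- ``retained_exon`` / ``skipped_exon``: a cassette exon — an exon of one
  transcript strictly inside an intron of the other whose flanking introns
  share that intron's outer splice sites.  Also a complementary pair.
- ``starts_in_intron`` / ``ends_in_intron``: a transcript terminus (5' or 3',
  strand-aware) falls strictly inside the partner's intron.
- ``alternate_exon``: the residual category — an exon in the overlap region
  with no exact match in the partner and not explained by any rule above
  (mutually-exclusive exon pairs yield one such event per unmatched exon).

Shared-boundary ties are resolved by strict containment: a boundary sitting
exactly on an exon/intron edge does not count as "inside".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .models import Gene, GenomeAnnotation, Interval, Transcript

EVENT_TYPES = (
    "alt_acceptor",
    "alt_donor",
    "alternate_exon",
    "ends_in_intron",
    "retained_exon",
    "retained_intron",
    "skipped_exon",
    "spliced_intron",
    "starts_in_intron",
)

_PAIRED = {
    "retained_intron": "spliced_intron",
    "spliced_intron": "retained_intron",
    "retained_exon": "skipped_exon",
    "skipped_exon": "retained_exon",
}


@dataclass(frozen=True)
class ASEvent:
    type: str
    carrier: str  # transcript id exhibiting the feature
    partner: str
    interval: Interval  # genomic interval of the affected feature

    def swapped(self) -> "ASEvent":
        """The same event as seen from the partner's side (for symmetry)."""
        new_type = _PAIRED.get(self.type, self.type)
        if self.type in _PAIRED:
            return ASEvent(new_type, self.partner, self.carrier, self.interval)
        return ASEvent(self.type, self.carrier, self.partner, self.interval)


def classify_pairwise_events(ta: Transcript, tb: Transcript) -> set[ASEvent]:
    """Classify the AS events between two isoforms of the same locus."""
    if ta.strand != tb.strand:
        raise ValueError(
            f"transcripts {ta.id} and {tb.id} are on different strands"
        )
    strand = ta.strand
    o_start = max(ta.span[0], tb.span[0])
    o_end = min(ta.span[1], tb.span[1])
    if o_start >= o_end:
        return set()

    sides = []
    for t in (ta, tb):
        introns = t.intron_intervals()
        sides.append(
            {
                "t": t,
                "exons": list(t.exons),
                "introns": introns,
                # introns eligible for the alt-site stage: fully inside overlap
                "eligible": [o_start <= s and e <= o_end for s, e in introns],
                "used": [False] * len(introns),
                # exon indices excluded from the residual (alternate_exon) rule
                "exon_excluded": set(),
            }
        )

    events: set[ASEvent] = set()

    def donor_acceptor(iv: Interval) -> tuple[int, int]:
        return (iv[0], iv[1]) if strand == "+" else (iv[1], iv[0])

    def exclude_adjacent_exons(side, j: int) -> None:
        side["exon_excluded"].update((j, j + 1))

    # --- transcript termini inside the partner's intron -------------------
    for X, Y in ((sides[0], sides[1]), (sides[1], sides[0])):
        tx = X["t"]
        if strand == "+":
            five, three = tx.span[0], tx.span[1] - 1
        else:
            five, three = tx.span[1] - 1, tx.span[0]
        for j, (s, e) in enumerate(Y["introns"]):
            for pos, etype in ((five, "starts_in_intron"), (three, "ends_in_intron")):
                if s < pos < e:  # strict: a terminus on the splice boundary is no event
                    events.add(ASEvent(etype, tx.id, Y["t"].id, (s, e)))
                    Y["eligible"][j] = False
                    exclude_adjacent_exons(Y, j)
                    # the terminal exon of X containing pos cannot match
                    for k, ex in enumerate(X["exons"]):
                        if ex[0] <= pos < ex[1]:
                            X["exon_excluded"].add(k)
    # --- cassette exons (retained_exon / skipped_exon) --------------------
    for X, Y in ((sides[0], sides[1]), (sides[1], sides[0])):
        for k in range(1, len(X["exons"]) - 1):
            es, ee = X["exons"][k]
            for j, (s, e) in enumerate(Y["introns"]):
                if not (s < es and ee < e):
                    continue
                il = X["introns"][k - 1]
                ir = X["introns"][k]
                if il[0] == s and ir[1] == e:
                    events.add(ASEvent("retained_exon", X["t"].id, Y["t"].id, (es, ee)))
                    events.add(ASEvent("skipped_exon", Y["t"].id, X["t"].id, (es, ee)))
                    X["eligible"][k - 1] = X["eligible"][k] = False
                    Y["eligible"][j] = False
                    X["exon_excluded"].add(k)

    # --- intron retention (retained_intron / spliced_intron) --------------
    for X, Y in ((sides[0], sides[1]), (sides[1], sides[0])):
        for j, (s, e) in enumerate(X["introns"]):
            if not (o_start <= s and e <= o_end):
                continue
            for k, (es, ee) in enumerate(Y["exons"]):
                if es < s and e < ee:
                    events.add(ASEvent("spliced_intron", X["t"].id, Y["t"].id, (s, e)))
                    events.add(ASEvent("retained_intron", Y["t"].id, X["t"].id, (s, e)))
                    X["eligible"][j] = False
                    exclude_adjacent_exons(X, j)
                    Y["exon_excluded"].add(k)

    # --- mutually-exclusive-exon shielding --------------------------------
    # an internal exon strictly inside a partner intron without flank sharing
    # is alternate-exon territory; its flanking introns and the containing
    # intron must not masquerade as alt donor/acceptor events.
    for X, Y in ((sides[0], sides[1]), (sides[1], sides[0])):
        for k in range(1, len(X["exons"]) - 1):
            if k in X["exon_excluded"]:
                continue
            es, ee = X["exons"][k]
            for j, (s, e) in enumerate(Y["introns"]):
                if s < es and ee < e:
                    X["eligible"][k - 1] = X["eligible"][k] = False
                    Y["eligible"][j] = False

    # --- alternative donors / acceptors -----------------------------------
    A, B = sides
    for ja, ia in enumerate(A["introns"]):
        if not A["eligible"][ja] or A["used"][ja]:
            continue
        for jb, ib in enumerate(B["introns"]):
            if not B["eligible"][jb] or B["used"][jb] or ia == ib:
                continue
            da, aa = donor_acceptor(ia)
            db_, ab = donor_acceptor(ib)
            etype = None
            if da == db_ and aa != ab:
                etype = "alt_acceptor"
            elif aa == ab and da != db_:
                etype = "alt_donor"
            if etype is None:
                continue
            # carrier convention: the transcript splicing the shorter intron
            # (the lengths always differ when exactly one site is shared)
            if (ia[1] - ia[0]) < (ib[1] - ib[0]):
                carrier, partner = A["t"].id, B["t"].id
            else:
                carrier, partner = B["t"].id, A["t"].id
            # affected interval: the region by which the two introns differ
            events.add(ASEvent(etype, carrier, partner, _diff_interval(ia, ib)))
            A["used"][ja] = B["used"][jb] = True
            exclude_adjacent_exons(A, ja)
            exclude_adjacent_exons(B, jb)
            break

    # --- residual: alternate exons ----------------------------------------
    def clipped(iv: Interval) -> Optional[Interval]:
        s, e = max(iv[0], o_start), min(iv[1], o_end)
        return (s, e) if s < e else None

    for X, Y in ((sides[0], sides[1]), (sides[1], sides[0])):
        partner_clipped = {clipped(iv) for iv in Y["exons"]}
        for k, iv in enumerate(X["exons"]):
            c = clipped(iv)
            if c is None or k in X["exon_excluded"]:
                continue
            if c in partner_clipped:
                continue
            events.add(ASEvent("alternate_exon", X["t"].id, Y["t"].id, c))

    return events


def _diff_interval(ia: Interval, ib: Interval) -> Interval:
    """Genomic interval by which two site-sharing introns differ."""
    if ia[0] == ib[0]:
        return (min(ia[1], ib[1]), max(ia[1], ib[1]))
    return (min(ia[0], ib[0]), max(ia[0], ib[0]))


@dataclass
class LocusSplicingReport:
    locus_id: str
    n_transcripts: int
    event_counts: dict[str, int]  # transcript-granularity event counts
    event_types_present: set[str]
    is_as: bool
    effect: str  # "CDS_altering" | "UTR_only" | "both" | "none"
    distinct_proteins: int
    events: list[ASEvent] = field(default_factory=list)


def _event_in_utr(ev: ASEvent, transcripts: dict[str, Transcript]) -> bool:
    """True when the affected interval lies outside both isoforms' CDS."""
    s, e = ev.interval
    for tid in (ev.carrier, ev.partner):
        t = transcripts.get(tid)
        if t is None or not t.is_coding:
            continue
        for cs, ce in t.cds:
            if max(cs, s) < min(ce, e):
                return False
    return True


def locus_splicing_report(gene: Gene) -> LocusSplicingReport:
    """Classify all unordered transcript pairs of a locus and summarize.

    The locus effect compares spliced CDS interval chains across isoforms
    (any difference is CDS-altering) and flags UTR involvement when an event
    interval avoids the CDS of both isoforms of its pair.
    """
    ts = gene.transcripts
    tmap = {t.id: t for t in ts}
    all_events: list[ASEvent] = []
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            all_events.extend(classify_pairwise_events(ts[i], ts[j]))

    chains = {t.cds_chain() for t in ts if t.is_coding}
    structures = {(tuple(t.exons)) for t in ts}
    is_as = len(structures) >= 2

    counts = {k: 0 for k in EVENT_TYPES}
    for ev in all_events:
        counts[ev.type] += 1

    cds_altering = len(chains) >= 2
    utr_involved = any(_event_in_utr(ev, tmap) for ev in all_events)
    if not is_as:
        effect = "none"
    elif cds_altering and utr_involved:
        effect = "both"
    elif cds_altering:
        effect = "CDS_altering"
    elif utr_involved:
        effect = "UTR_only"
    else:
        effect = "none" if not all_events else "UTR_only"
    return LocusSplicingReport(
        locus_id=gene.id,
        n_transcripts=len(ts),
        event_counts=counts,
        event_types_present={ev.type for ev in all_events},
        is_as=is_as,
        effect=effect,
        distinct_proteins=max(1, len(chains)) if any(t.is_coding for t in ts) else 0,
        events=all_events,
    )


def genome_as_summary(annotation: GenomeAnnotation) -> pd.DataFrame:
    """Per-event-type counts at transcript and locus granularity.

    Returns a table with one row per event type (columns ``n_events`` and
    ``n_loci``) plus summary rows: total loci, AS loci, the AS fraction
    (denominator: all annotated loci), and effect-class locus counts.
    """
    reports = [locus_splicing_report(g) for g in annotation.genes]
    rows = []
    for et in EVENT_TYPES:
        rows.append(
            {
                "row": et,
                "n_events": sum(r.event_counts[et] for r in reports),
                "n_loci": sum(1 for r in reports if et in r.event_types_present),
            }
        )
    n_loci = len(reports)
    n_as = sum(1 for r in reports if r.is_as)
    rows.append({"row": "loci_total", "n_events": None, "n_loci": n_loci})
    rows.append({"row": "loci_AS", "n_events": None, "n_loci": n_as})
    rows.append(
        {"row": "as_fraction", "n_events": None,
         "n_loci": n_as / n_loci if n_loci else float("nan")}
    )
    for eff in ("CDS_altering", "UTR_only", "both"):
        rows.append(
            {"row": f"effect_{eff}", "n_events": None,
             "n_loci": sum(1 for r in reports if r.effect == eff)}
        )
    return pd.DataFrame(rows).set_index("row")
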