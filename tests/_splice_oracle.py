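"""Independent brute-force splice-event classifier used as a test oracle.

Re-derives the event taxonomy from the documented definitions by global
predicate enumeration over every splice-site/exon containment relation,
with no sequential consumption bookkeeping.  Returns (type, carrier-id)
pairs, which is the granularity the equivalence tests compare.
"""

from __future__ import annotations


def _overlap(ta, tb):
    return max(ta.span[0], tb.span[0]), min(ta.span[1], tb.span[1])


def oracle_classify(ta, tb) -> set[tuple[str, str]]:
    o_start, o_end = _overlap(ta, tb)
    if o_start >= o_end:
        return set()
    strand = ta.strand
    sides = {}
    for t in (ta, tb):
        sides[t.id] = {
            "t": t,
            "exons": list(t.exons),
            "introns": t.intron_intervals(),
        }
    ids = [ta.id, tb.id]
    events: set[tuple[str, str]] = set()

    def donor(iv):
        return iv[0] if strand == "+" else iv[1]

    def acceptor(iv):
        return iv[1] if strand == "+" else iv[0]

    def pairs():
        yield sides[ids[0]], sides[ids[1]]
        yield sides[ids[1]], sides[ids[0]]

    # --- global predicates -------------------------------------------------
    def terminus_positions(t):
        if strand == "+":
            return {"5": t.span[0], "3": t.span[1] - 1}
        return {"5": t.span[1] - 1, "3": t.span[0]}

    # terminus events: (etype, carrier, partner intron index)
    terminus_hits = []
    for X, Y in pairs():
        tp = terminus_positions(X["t"])
        for j, (s, e) in enumerate(Y["introns"]):
            if s < tp["5"] < e:
                terminus_hits.append(("starts_in_intron", X["t"].id, Y["t"].id, j))
            if s < tp["3"] < e:
                terminus_hits.append(("ends_in_intron", X["t"].id, Y["t"].id, j))

    # cassette exons: internal exon of X strictly inside intron of Y whose
    # flanking introns share that intron's outer splice sites
    cassette_hits = []  # (X id, exon idx k, Y id, intron idx j)
    for X, Y in pairs():
        for k in range(1, len(X["exons"]) - 1):
            es, ee = X["exons"][k]
            for j, (s, e) in enumerate(Y["introns"]):
                if s < es and ee < e and X["introns"][k - 1][0] == s and X["introns"][k][1] == e:
                    cassette_hits.append((X["t"].id, k, Y["t"].id, j))

    # retention: intron of X strictly inside exon of Y
    retention_hits = []  # (X id, intron j, Y id, exon k)
    for X, Y in pairs():
        for j, (s, e) in enumerate(X["introns"]):
            for k, (es, ee) in enumerate(Y["exons"]):
                if es < s and e < ee:
                    retention_hits.append((X["t"].id, j, Y["t"].id, k))

    # exon-in-intron without flank sharing (mutually-exclusive-exon shape)
    mxe_hits = []  # (X id, exon k, Y id, intron j)
    cassette_exons = {(h[0], h[1]) for h in cassette_hits}
    for X, Y in pairs():
        for k in range(1, len(X["exons"]) - 1):
            if (X["t"].id, k) in cassette_exons:
                continue
            es, ee = X["exons"][k]
            for j, (s, e) in enumerate(Y["introns"]):
                if s < es and ee < e:
                    mxe_hits.append((X["t"].id, k, Y["t"].id, j))

    # introns shielded from the alt-site comparison
    shielded: set[tuple[str, int]] = set()
    for _, _, yid, j in terminus_hits:
        shielded.add((yid, j))
    for xid, k, yid, j in cassette_hits:
        shielded.add((yid, j))
        shielded.add((xid, k - 1))
        shielded.add((xid, k))
    for xid, j, _, _ in retention_hits:
        shielded.add((xid, j))
    for xid, k, yid, j in mxe_hits:
        shielded.add((yid, j))
        shielded.add((xid, k - 1))
        shielded.add((xid, k))
    for tid, side in sides.items():
        for j, (s, e) in enumerate(side["introns"]):
            if not (o_start <= s and e <= o_end):
                shielded.add((tid, j))

    # alt donor/acceptor between unshielded, non-identical introns
    alt_hits = []  # (etype, a id, intron ja, b id, intron jb)
    A, B = sides[ids[0]], sides[ids[1]]
    for ja, ia in enumerate(A["introns"]):
        if (ids[0], ja) in shielded:
            continue
        for jb, ib in enumerate(B["introns"]):
            if (ids[1], jb) in shielded or ia == ib:
                continue
            short = ids[0] if (ia[1] - ia[0]) < (ib[1] - ib[0]) else ids[1]
            if donor(ia) == donor(ib) and acceptor(ia) != acceptor(ib):
                alt_hits.append(("alt_acceptor", short, ids[0], ja, ids[1], jb))
            elif acceptor(ia) == acceptor(ib) and donor(ia) != donor(ib):
                alt_hits.append(("alt_donor", short, ids[0], ja, ids[1], jb))

    # --- emit events -------------------------------------------------------
    for etype, xid, _, _ in terminus_hits:
        events.add((etype, xid))
    for xid, _, yid, _ in cassette_hits:
        events.add(("retained_exon", xid))
        events.add(("skipped_exon", yid))
    for xid, _, yid, _ in retention_hits:
        events.add(("spliced_intron", xid))
        events.add(("retained_intron", yid))
    for etype, carrier, _, _, _, _ in alt_hits:
        events.add((etype, carrier))

    # residual alternate exons: clipped exon with no clipped match, not
    # excluded by any fired rule
    excluded: dict[str, set[int]] = {tid: set() for tid in ids}
    for etype, xid, yid, j in terminus_hits:
        excluded[yid].update((j, j + 1))
        tp = terminus_positions(sides[xid]["t"])
        pos = tp["5"] if etype == "starts_in_intron" else tp["3"]
        for k, (es, ee) in enumerate(sides[xid]["exons"]):
            if es <= pos < ee:
                excluded[xid].add(k)
    for xid, k, yid, j in cassette_hits:
        excluded[xid].add(k)
    for xid, j, yid, k in retention_hits:
        excluded[xid].update((j, j + 1))
        excluded[yid].add(k)
    for etype, _, aid, ja, bid, jb in alt_hits:
        excluded[aid].update((ja, ja + 1))
        excluded[bid].update((jb, jb + 1))

    def clipped(iv):
        s, e = max(iv[0], o_start), min(iv[1], o_end)
        return (s, e) if s < e else None

    for X, Y in pairs():
        xid = X["t"].id
        partner = {clipped(iv) for iv in Y["exons"]}
        for k, iv in enumerate(X["exons"]):
            c = clipped(iv)
            if c is None or k in excluded[xid] or c in partner:
                continue
            events.add(("alternate_exon", xid))
    return events
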