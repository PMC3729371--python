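"""GFF3/cluster/GAF/OBO parsing and the derived gene-model geometry."""

import textwrap

import pytest

from structome.io import (
    ClusterParseError,
    Gff3Dialect,
    ancestors,
    read_clusters,
    read_gaf,
    read_gff3,
    read_obo,
    write_gff3,
)
from structome.models import (
    StructureError,
    Transcript,
    derive_transcript_regions,
    total_length,
)
from structome.synthetic_data import GenomeConfig


class TestReadGff3:
    def test_toy_fixture_structure(self, toy_gff3):
        ann = read_gff3(toy_gff3)
        assert len(ann) == 3
        by_id = ann.gene_by_id()
        assert by_id["geneA"].strand == "+"
        assert by_id["geneB"].strand == "-"
        assert [len(t.exons) for t in by_id["geneA"].transcripts] == [2]
        assert [len(t.exons) for t in by_id["geneC"].transcripts] == [1]
        # coordinates converted to 0-based half-open
        assert by_id["geneA"].transcripts[0].exons == [(100, 200), (300, 500)]

    def test_single_exon_gene_minimal(self, tmp_path):
        p = tmp_path / "one.gff3"
        p.write_text(
            "##gff-version 3\n"
            "s\tx\tgene\t1\t300\t.\t+\t.\tID=g\n"
            "s\tx\tmRNA\t1\t300\t.\t+\t.\tID=g.1;Parent=g\n"
            "s\tx\texon\t1\t300\t.\t+\t.\tID=e;Parent=g.1\n"
            "s\tx\tCDS\t1\t300\t.\t+\t0\tID=c;Parent=g.1\n"
        )
        ann = read_gff3(p)
        (gene,) = ann.genes
        (t,) = gene.transcripts
        assert len(t.exons) == 1 and len(t.introns) == 0
        assert t.utr5 == [] and t.utr3 == []

    def test_round_trip_identity(self, toy_gff3, tmp_path):
        ann1 = read_gff3(toy_gff3)
        out = tmp_path / "rt.gff3"
        write_gff3(ann1, out)
        ann2 = read_gff3(out)
        for g1, g2 in zip(ann1.genes, ann2.genes):
            assert g1.id == g2.id and g1.strand == g2.strand
            for t1, t2 in zip(g1.transcripts, g2.transcripts):
                assert t1.exons == t2.exons
                assert sorted(t1.cds) == sorted(t2.cds)
                assert t1.utr5 == t2.utr5 and t1.utr3 == t2.utr3
                assert [(i.interval, i.region) for i in t1.introns] == [
                    (i.interval, i.region) for i in t2.introns
                ]

    def test_cds_outside_exon_is_structural_error(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "##gff-version 3\n"
            "s\tx\tgene\t1\t300\t.\t+\t.\tID=g\n"
            "s\tx\tmRNA\t1\t300\t.\t+\t.\tID=g.1;Parent=g\n"
            "s\tx\texon\t1\t100\t.\t+\t.\tID=e;Parent=g.1\n"
            "s\tx\tCDS\t150\t250\t.\t+\t0\tID=c;Parent=g.1\n"
        )
        with pytest.raises(StructureError, match="g.1"):
            read_gff3(p)

    def test_orphan_mrna(self, tmp_path):
        p = tmp_path / "orphan.gff3"
        p.write_text(
            "##gff-version 3\n"
            "s\tx\tmRNA\t1\t200\t.\t+\t.\tID=lonely.1\n"
            "s\tx\texon\t1\t200\t.\t+\t.\tID=e;Parent=lonely.1\n"
        )
        with pytest.raises(StructureError, match="lonely.1"):
            read_gff3(p)
        ann = read_gff3(p, dialect=Gff3Dialect(synthesize_orphan_genes=True))
        assert len(ann) == 1
        assert ann.genes[0].transcripts[0].id == "lonely.1"


class TestDeriveRegions:
    def test_plus_strand_geometry(self, tbuild):
        t = tbuild("t", [(0, 100), (200, 300), (400, 500)], cds_span=(249, 450))
        assert t.utr5 == [(0, 100), (200, 249)]
        assert total_length(t.utr5) == 149
        assert t.utr3 == [(450, 500)]
        assert [(i.interval, i.region) for i in t.introns] == [
            ((100, 200), "UTR5"),
            ((300, 400), "CDS"),
        ]

    def test_minus_strand_geometry(self, tbuild):
        t = tbuild("t", [(0, 100), (200, 300), (400, 500)], strand="-",
                   cds_span=(50, 250))
        assert t.utr5 == [(250, 300), (400, 500)]
        assert total_length(t.utr5) == 150
        intron_regions = {i.interval: i.region for i in t.introns}
        assert intron_regions[(300, 400)] == "UTR5"
        assert intron_regions[(100, 200)] == "CDS"

    def test_cds_covers_everything(self, tbuild):
        t = tbuild("t", [(0, 300)], cds_span=(0, 300))
        assert t.utr5 == [] and t.utr3 == [] and t.introns == []

    def test_noncoding_transcript_all_cds_introns(self, tbuild):
        t = tbuild("t", [(0, 100), (200, 300)])
        assert t.utr5 == [] and t.utr3 == []
        assert [i.region for i in t.introns] == ["CDS"]

    def test_partition_invariant_random_transcripts(self, rng):
        """UTR5 + CDS + UTR3 lengths always sum to the spliced length."""
        from structome.synthetic_data import _build_layout, _realize

        cfg = GenomeConfig()
        for i in range(200):
            strand = "+" if rng.random() < 0.5 else "-"
            t = _realize(_build_layout(rng, cfg), f"t{i}", "s", strand, 0)
            if not t.is_coding:
                continue
            assert (
                total_length(t.utr5) + t.cds_length + total_length(t.utr3)
                == t.spliced_length
            )
            assert len(t.introns) == len(t.exons) - 1

    def test_strand_mirror_symmetry(self, rng):
        """Mirroring coordinates and flipping the strand preserves every
        derived length and region class."""
        from structome.synthetic_data import _build_layout, _realize

        cfg = GenomeConfig()
        for i in range(100):
            t = _realize(_build_layout(rng, cfg), f"t{i}", "s", "+", 0)
            hi = t.span[1] + 17
            mirror = Transcript(
                t.id, "s", "-",
                exons=sorted((hi - e, hi - s) for s, e in t.exons),
                cds=sorted((hi - e, hi - s) for s, e in t.cds),
            )
            derive_transcript_regions(mirror)
            assert total_length(mirror.utr5) == total_length(t.utr5)
            assert total_length(mirror.utr3) == total_length(t.utr3)
            assert sorted((i.length, i.region) for i in mirror.introns) == sorted(
                (i.length, i.region) for i in t.introns
            )


class TestClusters:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("C1: Pp|g1 Pp|g2 At|g9\n")
        (c,) = read_clusters(p)
        assert c.id == "C1"
        assert c.members == [("Pp", "g1"), ("Pp", "g2"), ("At", "g9")]
        assert c.species() == {"Pp", "At"}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        assert read_clusters(p) == []

    def test_duplicate_member_collapsed(self, tmp_path, caplog):
        p = tmp_path / "dup.txt"
        p.write_text("C1: Pp|g1 Pp|g1\n")
        with caplog.at_level("WARNING"):
            (c,) = read_clusters(p)
        assert c.members == [("Pp", "g1")]
        assert any("duplicate" in r.message for r in caplog.records)

    def test_missing_separator_reports_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("C1: Pp|g1\nC2: broken_token\n")
        with pytest.raises(ClusterParseError, match="line 2"):
            read_clusters(p)


GAF_FIXTURE = textwrap.dedent(
    """\
    !gaf-version: 2.1
    db\tg1\tg1\t\tGO:0000001\tREF:1\tIEA\t\tP\t\t\tprotein\ttaxon:3218\t20130101\tdb
    db\tg1\tg1\t\tGO:0000002\tREF:1\tISS\t\tF\t\t\tprotein\ttaxon:3218\t20130101\tdb
    db\tg2\tg2\tNOT\tGO:0000001\tREF:1\tIEA\t\tP\t\t\tprotein\ttaxon:3218\t20130101\tdb
    db\tg2\tg2\t\tGO:0000003\tREF:2\tIDA\t\tC\t\t\tprotein\ttaxon:3218\t20130101\tdb
    db\tg3\tg3\t\tGO:0000001\tREF:3\tIEA\t\tP\t\t\tprotein\ttaxon:3218\t20130101\tdb
    """
)


class TestGaf:
    def test_fixture_counts_and_fields(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text(GAF_FIXTURE)
        res = read_gaf(p)
        # 5 data rows, one NOT-qualified row excluded
        assert len(res) == 4
        assert res.errors == []
        first = res.annotations[0]
        assert first.gene_id == "g1" and first.term == "GO:0000001"
        assert first.aspect == "BP" and first.evidence_code == "IEA"
        assert {a.aspect for a in res} == {"BP", "MF", "CC"}

    def test_bad_row_collected_parse_continues(self, tmp_path):
        p = tmp_path / "b.gaf"
        p.write_text(GAF_FIXTURE + "db\tg4\tbroken\n")
        res = read_gaf(p)
        assert len(res) == 4
        assert len(res.errors) == 1
        assert res.errors[0][0] == 7  # line number


class TestObo:
    def test_ancestor_transitive_closure(self, toy_obo):
        g = read_obo(toy_obo)
        assert ancestors(g, "GO:0000001") >= {"GO:0000002", "GO:0000003"}
        assert ancestors(g, "GO:0000004") == {"GO:0000003"}  # via part_of
        assert ancestors(g, "GO:0000005") == set()

    def test_cycle_is_error(self, tmp_path):
        p = tmp_path / "cyc.obo"
        p.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:1\nname: a\nis_a: GO:2\n\n"
            "[Term]\nid: GO:2\nname: b\nis_a: GO:1\n"
        )
        with pytest.raises(ValueError, match="cycle"):
            read_obo(p)
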