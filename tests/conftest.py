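from __future__ import annotations

import textwrap

import numpy as np
import pytest

from structome.models import Transcript, cds_from_span, derive_transcript_regions


def make_transcript(
    tid: str,
    exons,
    strand: str = "+",
    cds_span=None,
    cds=None,
    scaffold: str = "scaf1",
) -> Transcript:
    """1-exon-list helper: builds and derives a transcript; ``cds_span`` is a
    genomic (start0, end0) span intersected with the exons."""
    if cds is None:
        cds = cds_from_span(exons, *cds_span) if cds_span else []
    t = Transcript(tid, scaffold, strand, list(exons), cds=list(cds))
    return derive_transcript_regions(t)


@pytest.fixture
def tbuild():
    return make_transcript


@pytest.fixture
def rng():
    return np.random.default_rng(20130723)


TOY_GFF3 = textwrap.dedent(
    """\
    ##gff-version 3
    scaf1\ttest\tgene\t101\t500\t.\t+\t.\tID=geneA
    scaf1\ttest\tmRNA\t101\t500\t.\t+\t.\tID=geneA.1;Parent=geneA
    scaf1\ttest\texon\t101\t200\t.\t+\t.\tID=geneA.1.e1;Parent=geneA.1
    scaf1\ttest\texon\t301\t500\t.\t+\t.\tID=geneA.1.e2;Parent=geneA.1
    scaf1\ttest\tCDS\t151\t200\t.\t+\t0\tID=geneA.1.c1;Parent=geneA.1
    scaf1\ttest\tCDS\t301\t400\t.\t+\t0\tID=geneA.1.c2;Parent=geneA.1
    scaf1\ttest\tgene\t1001\t1600\t.\t-\t.\tID=geneB
    scaf1\ttest\tmRNA\t1001\t1600\t.\t-\t.\tID=geneB.1;Parent=geneB
    scaf1\ttest\texon\t1001\t1200\t.\t-\t.\tID=geneB.1.e1;Parent=geneB.1
    scaf1\ttest\texon\t1401\t1600\t.\t-\t.\tID=geneB.1.e2;Parent=geneB.1
    scaf1\ttest\tCDS\t1101\t1200\t.\t-\t0\tID=geneB.1.c1;Parent=geneB.1
    scaf1\ttest\tCDS\t1401\t1500\t.\t-\t0\tID=geneB.1.c2;Parent=geneB.1
    scaf2\ttest\tgene\t11\t310\t.\t+\t.\tID=geneC
    scaf2\ttest\tmRNA\t11\t310\t.\t+\t.\tID=geneC.1;Parent=geneC
    scaf2\ttest\texon\t11\t310\t.\t+\t.\tID=geneC.1.e1;Parent=geneC.1
    scaf2\ttest\tCDS\t11\t310\t.\t+\t0\tID=geneC.1.c1;Parent=geneC.1
    """
)


@pytest.fixture
def toy_gff3(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF3)
    return p


TOY_OBO = textwrap.dedent(
    """\
    format-version: 1.2

    [Term]
    id: GO:0000001
    name: leaf term
    namespace: biological_process
    is_a: GO:0000002 ! mid term

    [Term]
    id: GO:0000002
    name: mid term
    namespace: biological_process
    is_a: GO:0000003 ! top term

    [Term]
    id: GO:0000003
    name: top term
    namespace: biological_process

    [Term]
    id: GO:0000004
    name: part term
    namespace: biological_process
    relationship: part_of GO:0000003 ! top term

    [Term]
    id: GO:0000005
    name: unrelated
    namespace: biological_process
    """
)


@pytest.fixture
def toy_obo(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    return p
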