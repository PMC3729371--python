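"""Structure summaries, 5'-UTR intron profiles and the two-sample tests."""

import math

import numpy as np
import pytest

from structome.models import Gene, GenomeAnnotation
from structome.structure_stats import (
    bh_fdr,
    compare_groups,
    genome_structure_summary,
    intron_length_profile,
    proximal_utr5_intron_distances,
    two_proportion_exact,
    utr5_intron_count_frequencies,
)
from structome.synthetic_data import GenomeConfig, generate_genome


def one_gene_annotation(tbuild, exons, cds_span, strand="+", genome_size=None):
    t = tbuild("g1.1", exons, strand=strand, cds_span=cds_span)
    return GenomeAnnotation(
        "test", [Gene("g1", t.scaffold, strand, [t])], genome_size=genome_size
    )


class TestGenomeSummary:
    def test_single_gene_geometry(self, tbuild):
        ann = one_gene_annotation(tbuild, [(0, 100), (200, 300)], (50, 250))
        st = genome_structure_summary(ann)
        assert st.means["transcript_length"] == 200
        # CDS 51..250 bridges the intron: 50 nt in each exon
        assert st.means["cds_length"] == 100
        assert st.means["utr5_length"] == 50
        assert st.means["utr3_length"] == 50
        assert st.means["exons_per_gene"] == 2
        assert st.means["introns_per_gene"] == 1
        assert st.fractions["single_exon_transcripts"] == 0.0

    def test_gene_density_from_printed_counts(self, tbuild):
        # genome size 480 Mb over 32,275 loci prints as 14.9 kb per gene
        t = tbuild("x.1", [(0, 100)], cds_span=(0, 100))
        genes = [Gene(f"g{i}", "s", "+", [t]) for i in range(32275)]
        ann = GenomeAnnotation("pp", genes, genome_size=480_000_000)
        st = genome_structure_summary(ann)
        assert st.gene_density_kb == pytest.approx(14.9, abs=0.05)

    def test_empty_annotation_is_error(self):
        with pytest.raises(ValueError, match="no genes"):
            genome_structure_summary(GenomeAnnotation("x", []))

    def test_oracle_equivalence_small_annotation(self, rng):
        """All summary fields match a naive per-interval recomputation."""
        cfg = GenomeConfig(seed=11, n_genes=50, as_fraction=0.1)
        ann, _ = generate_genome(cfg)
        st = genome_structure_summary(ann)
        ts = [t for g in ann.genes for t in g.transcripts]
        coding = [t for t in ts if t.cds]

        def naive_gene_len(g):
            lo = min(t.exons[0][0] for t in g.transcripts)
            hi = max(t.exons[-1][1] for t in g.transcripts)
            return hi - lo

        assert st.counts["transcripts"] == len(ts)
        assert st.means["gene_length"] == pytest.approx(
            np.mean([naive_gene_len(g) for g in ann.genes])
        )
        assert st.means["transcript_length"] == pytest.approx(
            np.mean([sum(e - s for s, e in t.exons) for t in ts])
        )
        assert st.means["exon_length"] == pytest.approx(
            np.mean([e - s for t in ts for s, e in t.exons])
        )
        naive_introns = [
            s2 - e1
            for t in ts
            for (_, e1), (s2, _) in zip(t.exons, t.exons[1:])
        ]
        assert st.means["intron_length"] == pytest.approx(np.mean(naive_introns))
        assert st.medians["intron_length"] == pytest.approx(np.median(naive_introns))
        assert st.counts["with_utr5"] == sum(1 for t in coding if t.utr5)
        assert st.counts["multi_exon_utr5"] == sum(
            1 for t in coding if len(t.utr5) > 1
        )
        n_single = sum(1 for t in ts if len(t.exons) == 1)
        assert st.counts["single_exon_transcripts"] == n_single
        assert st.counts["multi_exon_transcripts"] == len(ts) - n_single

    def test_summary_internal_consistency(self):
        cfg = GenomeConfig(seed=5, n_genes=300)
        ann, _ = generate_genome(cfg)
        st = genome_structure_summary(ann)
        assert (
            st.counts["single_exon_transcripts"] + st.counts["multi_exon_transcripts"]
            == st.counts["transcripts"]
        )
        assert st.counts["multi_exon_utr5"] <= st.counts["with_utr5"]
        assert all(0 <= f <= 1 for f in st.fractions.values() if not math.isnan(f))

    def test_adding_intronless_gene_cannot_raise_intron_mean(self, tbuild):
        ann, _ = generate_genome(GenomeConfig(seed=2, n_genes=30))
        before = genome_structure_summary(ann).means["introns_per_gene"]
        extra = tbuild("solo.1", [(10, 400)], cds_span=(10, 400), scaffold="scafX")
        ann.genes.append(Gene("solo", "scafX", "+", [extra]))
        after = genome_structure_summary(ann).means["introns_per_gene"]
        assert after <= before

    def test_representative_scope_uses_one_transcript_per_gene(self):
        cfg = GenomeConfig(seed=9, n_genes=120, as_fraction=0.3)
        ann, _ = generate_genome(cfg)
        st = genome_structure_summary(ann, scope="representative_only")
        assert st.counts["transcripts"] == st.counts["genes"]


class TestParameterRecovery:
    def test_generator_targets_recovered_at_n2000(self):
        """Realized exon-count and per-region intron-length means land
        within 3 sigma of the generator targets (520/264/268 bp)."""
        cfg = GenomeConfig(seed=1, n_genes=2000, as_fraction=0.0)
        ann, _ = generate_genome(cfg)
        st = genome_structure_summary(ann)
        exons = [len(t.exons) for t in ann.transcripts()]
        se = np.std(exons, ddof=1) / math.sqrt(len(exons))
        assert abs(st.means["exons_per_gene"] - cfg.exon_mean) < 3 * se
        prof = intron_length_profile(ann)
        targets = {
            "UTR5": cfg.intron_mean_utr5,
            "CDS": cfg.intron_mean_cds,
            "UTR3": cfg.intron_mean_utr3,
        }
        for region, target in targets.items():
            xs = np.asarray(prof.lengths[region], dtype=float)
            se = xs.std(ddof=1) / math.sqrt(len(xs))
            assert abs(xs.mean() - target) < 3 * se, region


class TestIntronProfile:
    def test_direct_fraction_count(self, tbuild):
        t1 = tbuild("a.1", [(0, 50), (650, 700), (1400, 1500)], cds_span=(1400, 1500))
        # introns 600 and 700 bp, both in the 5'-UTR
        t2 = tbuild("b.1", [(0, 100), (200, 300), (500, 600)], cds_span=(0, 600))
        ann = GenomeAnnotation(
            "x", [Gene("a", "scaf1", "+", [t1]), Gene("b", "scaf1", "+", [t2])]
        )
        prof = intron_length_profile(ann)
        assert sorted(prof.lengths["UTR5"]) == [600, 700]
        assert sorted(prof.lengths["CDS"]) == [100, 200]
        assert prof.frac_gt_threshold["UTR5"] == 1.0
        assert prof.frac_gt_threshold["CDS"] == 0.0

    def test_threshold_is_strictly_greater(self, tbuild):
        t = tbuild("a.1", [(0, 100), (600, 700)], cds_span=(0, 700))
        ann = GenomeAnnotation("x", [Gene("a", "scaf1", "+", [t])])
        prof = intron_length_profile(ann, threshold=500)
        assert prof.lengths["CDS"] == [500]
        assert prof.frac_gt_threshold["CDS"] == 0.0

    def test_empty_classes_yield_nan(self, tbuild):
        t = tbuild("a.1", [(0, 300)], cds_span=(0, 300))
        ann = GenomeAnnotation("x", [Gene("a", "scaf1", "+", [t])])
        prof = intron_length_profile(ann)
        assert all(math.isnan(v) for v in prof.means.values())


class TestUtr5Frequencies:
    def test_fraction_with_at_least_one_intron(self, tbuild):
        genes = []
        for i in range(10):
            if i < 4:  # one 5'-UTR intron
                t = tbuild(f"g{i}.1", [(0, 50), (150, 400)], cds_span=(200, 400))
            else:  # intron-free 5'-UTR
                t = tbuild(f"g{i}.1", [(0, 400)], cds_span=(200, 400))
            genes.append(Gene(f"g{i}", "scaf1", "+", [t]))
        freqs = utr5_intron_count_frequencies(GenomeAnnotation("x", genes))
        assert freqs.n_with_utr5 == 10
        assert freqs.frequencies[0] == pytest.approx(0.6)
        assert freqs.frequencies[1] == pytest.approx(0.4)
        assert sum(freqs.frequencies.values()) == pytest.approx(1.0)

    def test_no_utr5_flagged_empty(self, tbuild):
        t = tbuild("a.1", [(0, 300)], cds_span=(0, 300))
        freqs = utr5_intron_count_frequencies(
            GenomeAnnotation("x", [Gene("a", "scaf1", "+", [t])])
        )
        assert freqs.empty and freqs.frequencies == {}

    def test_all_single_exon(self, tbuild):
        t = tbuild("a.1", [(0, 300)], cds_span=(100, 300))
        freqs = utr5_intron_count_frequencies(
            GenomeAnnotation("x", [Gene("a", "scaf1", "+", [t])])
        )
        assert freqs.frequencies == {0: 1.0}


class TestProximalDistances:
    def test_hand_computed_distances(self, tbuild):
        t = tbuild("a.1", [(0, 100), (200, 300)], cds_span=(250, 300))
        prof = proximal_utr5_intron_distances(
            GenomeAnnotation("x", [Gene("a", "scaf1", "+", [t])])
        )
        assert list(prof.distance_to_atg) == [50]
        assert list(prof.distance_to_tss) == [100]

    def test_min_rule_picks_proximal_intron(self, tbuild):
        # two 5'-UTR introns with acceptor offsets 30 and 120; CDS starts at 150
        t = tbuild(
            "a.1",
            [(0, 30), (130, 220), (320, 500)],
            cds_span=(350, 500),
        )
        prof = proximal_utr5_intron_distances(
            GenomeAnnotation("x", [Gene("a", "scaf1", "+", [t])])
        )
        assert list(prof.distance_to_atg) == [30]
        assert list(prof.distance_to_tss) == [120]

    def test_acceptor_adjacent_to_atg(self, tbuild):
        t = tbuild("a.1", [(0, 100), (200, 300)], cds_span=(200, 300))
        prof = proximal_utr5_intron_distances(
            GenomeAnnotation("x", [Gene("a", "scaf1", "+", [t])])
        )
        assert list(prof.distance_to_atg) == [0]


class TestCompareGroups:
    def test_identical_proportions(self):
        res = compare_groups((10, 100), (10, 100), test="two_proportion_exact")
        assert res.p_greater >= 0.5
        assert res.p_two_sided == 1.0

    def test_paper_scale_exact_tail(self):
        """Moss vs rice multi-exon 5'-UTR counts give p below 2E-238."""
        res = two_proportion_exact(7120, 18180, 7940, 31793)
        assert res.log10_p <= math.log10(2e-238)
        assert res.p <= 2e-238

    def test_rank_sum_identical_samples(self):
        res = compare_groups([1, 2, 3], [1, 2, 3], test="rank_sum")
        assert res.p == pytest.approx(1.0)

    def test_rank_sum_shift_detected(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(1.5, 1, 200)
        assert compare_groups(a, b).p < 1e-10

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0], test="rank_sum")
        with pytest.raises(ValueError):
            compare_groups((5, 0), (1, 10), test="two_proportion_exact")
        with pytest.raises(ValueError):
            compare_groups((11, 10), (1, 10), test="two_proportion_exact")

    def test_monotone_tail(self):
        # a larger observed count can only shrink the focal-enrichment tail
        ps = [two_proportion_exact(k, 100, 20, 200).p_greater for k in (10, 20, 30)]
        assert ps[0] > ps[1] > ps[2]

    def test_bh_fdr_matches_known_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert bh_fdr([]).size == 0
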