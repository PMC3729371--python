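"""Representative selection, family profiles, orphans and intron loss."""

import pytest

from structome.family_evolution import (
    classify_orphans,
    family_profile,
    infer_intron_loss,
    pairwise_uncorrected_distance,
    select_representative,
)
from structome.models import Cluster, GenomeAnnotation
from structome.synthetic_data import ClusterConfig, generate_cluster_set


class TestPDistance:
    def test_identical(self):
        assert pairwise_uncorrected_distance("ACGT", "ACGT") == 0.0

    def test_one_mismatch_of_four(self):
        assert pairwise_uncorrected_distance("ACGT", "ACGA") == 0.25

    def test_gap_positions_excluded(self):
        assert pairwise_uncorrected_distance("AC-T", "ACGT") == 0.0

    def test_all_gap_undefined(self):
        assert pairwise_uncorrected_distance("---", "AC-") is None

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            pairwise_uncorrected_distance("ACG", "AC")


class TestSelectRepresentative:
    iso_to_locus = {"g1.1": "g1", "g1.2": "g1"}

    def test_tier1_min_distance(self):
        c = Cluster("C1", [("Pp", "g1.1"), ("Pp", "g1.2"), ("At", "a1")])
        dist = {("g1.1", "a1"): 0.10, ("g1.2", "a1"): 0.25}
        (choice,) = select_representative(c, "Pp", self.iso_to_locus, distances=dist)
        assert choice.transcript_id == "g1.1"
        assert choice.tier == "min_distance"
        assert choice.value == 0.10

    def test_tier1_missing_isoform_errors(self):
        c = Cluster("C1", [("Pp", "g1.1"), ("Pp", "g1.2"), ("At", "a1")])
        with pytest.raises(KeyError, match="g1.2"):
            select_representative(
                c, "Pp", self.iso_to_locus, distances={("g1.1", "a1"): 0.1}
            )

    def test_tier2_best_hit_coverage(self):
        c = Cluster("C1", [("Pp", "g1.1"), ("Pp", "g1.2")])
        (choice,) = select_representative(
            c, "Pp", self.iso_to_locus,
            hit_coverage={"g1.1": 0.9, "g1.2": 0.5},
        )
        assert choice.transcript_id == "g1.1"
        assert choice.tier == "best_hit_coverage"

    def test_tier3_longest_transcript(self):
        c = Cluster("C1", [("Pp", "g1.1"), ("Pp", "g1.2")])
        (choice,) = select_representative(
            c, "Pp", self.iso_to_locus,
            transcript_lengths={"g1.1": 900, "g1.2": 1400},
        )
        assert choice.transcript_id == "g1.2"
        assert choice.tier == "longest_transcript"
        assert choice.value == 1400

    def test_deterministic_tie_break(self):
        c = Cluster("C1", [("Pp", "g1.2"), ("Pp", "g1.1")])
        (choice,) = select_representative(
            c, "Pp", self.iso_to_locus,
            transcript_lengths={"g1.1": 1000, "g1.2": 1000},
        )
        assert choice.transcript_id == "g1.1"


class TestFamilyProfile:
    def example_clusters(self):
        return [
            Cluster("C1", [("Pp", "p1"), ("Pp", "p2"), ("Pp", "p3"), ("At", "a1")]),
            Cluster("C2", [("Pp", "p4"), ("Pp", "p5")]),
            Cluster("C3", [("Pp", "p6"), ("Os", "o1"), ("Os", "o2"), ("Os", "o3"), ("Os", "o4")]),
        ]

    def test_direct_counts(self):
        fam = family_profile(self.example_clusters(), "Pp")
        assert fam.focal_only_locus_fraction == pytest.approx(2 / 6)
        by_id = {p.cluster_id: p for p in fam.profiles}
        # 3 focal vs max other 1: an expansion, and strong since 3 > 2x1
        assert by_id["C1"].expansion and by_id["C1"].strong_expansion
        assert not by_id["C3"].expansion
        assert by_id["C2"].focal_only

    def test_strong_expansion_strictly_twice(self):
        clusters = [
            Cluster("C1", [("Pp", f"p{i}") for i in range(5)] + [("At", "a1"), ("At", "a2")]),
            Cluster("C2", [("Pp", f"q{i}") for i in range(4)] + [("At", "b1"), ("At", "b2")]),
        ]
        fam = family_profile(clusters, "Pp")
        by_id = {p.cluster_id: p for p in fam.profiles}
        assert by_id["C1"].strong_expansion  # 5 > 4
        assert not by_id["C2"].strong_expansion  # 4 > 4 is false
        assert by_id["C2"].expansion

    def test_singleton_cluster(self):
        fam = family_profile([Cluster("C1", [("Pp", "p1")])], "Pp")
        (p,) = fam.profiles
        assert p.focal_only and not p.expansion
        assert fam.focal_only_locus_fraction == 1.0

    def test_size_distribution_restricted_to_shared(self):
        fam = family_profile(self.example_clusters(), "Pp")
        assert set(fam.size_distributions.index) == {"C1", "C3"}

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            family_profile([], "Pp")

    def test_oracle_equivalence_naive_recount(self, rng):
        clusters = []
        species = ["Pp", "At", "Os"]
        for i in range(20):
            members = []
            for sp in species:
                for j in range(int(rng.integers(0, 4))):
                    members.append((sp, f"{sp}{i}_{j}"))
            if not members:
                members = [("Pp", f"Pp{i}_solo")]
            clusters.append(Cluster(f"C{i}", members))
        fam = family_profile(clusters, "Pp")
        for p, c in zip(fam.profiles, clusters):
            counts = {}
            for sp, _ in c.members:
                counts[sp] = counts.get(sp, 0) + 1
            assert p.counts == counts
            others = [n for sp, n in counts.items() if sp != "Pp"]
            focal = counts.get("Pp", 0)
            assert p.expansion == (focal > 0 and bool(others) and focal > max(others))


class TestOrphans:
    def test_rule_table(self):
        clusters = [
            Cluster("C1", [("Pp", "inFam"), ("At", "a1")]),
            Cluster("C2", [("Pp", "withHit")]),
            Cluster("C3", [("Pp", "estOnly")]),
            Cluster("C4", [("Pp", "nothing")]),
        ]
        hits = {"inFam": False, "withHit": True, "estOnly": False, "nothing": False}
        est = {"inFam": False, "withHit": False, "estOnly": True, "nothing": False}
        calls = {o.gene_id: o.klass for o in classify_orphans(clusters, "Pp", hits, est)}
        assert calls == {
            "inFam": "has_plant_family",
            "withHit": "focal_only_with_homolog",
            "estOnly": "orphan_with_est",
            "nothing": "orphan_no_homolog",
        }


class TestIntronLoss:
    def make_annotations(self, focal_specs, other_specs):
        """Each spec: gene id -> (n_exons, transcript_length)."""
        from structome.synthetic_data import _uniform_gene

        anns = {}
        for sp, specs in (("Pp", focal_specs), ("At", other_specs)):
            genes, origin = [], 100
            for gid, (n_exons, length) in specs.items():
                g = _uniform_gene(gid, f"{sp}_s", n_exons, length, origin)
                origin = g.span[1] + 500
                genes.append(g)
            anns[sp] = GenomeAnnotation(sp, genes)
        return anns

    def test_full_loss_rule(self):
        anns = self.make_annotations(
            {"f1": (1, 1500)}, {"o1": (5, 1500), "o2": (7, 1500), "o3": (9, 1500)}
        )
        clusters = [Cluster("C1", [("Pp", "f1"), ("At", "o1"), ("At", "o2"), ("At", "o3")])]
        res = infer_intron_loss(clusters, anns, "Pp")
        (call,) = res.calls
        assert call.call == "full_loss"
        assert call.median_other_introns == 6

    def test_equal_median_is_no_call(self):
        anns = self.make_annotations(
            {"f1": (5, 1500)}, {"o1": (5, 1500), "o2": (5, 1500)}
        )
        clusters = [Cluster("C1", [("Pp", "f1"), ("At", "o1"), ("At", "o2")])]
        (call,) = infer_intron_loss(clusters, anns, "Pp").calls
        assert call.call == "none"  # 4 < 4 is false

    def test_fragmentary_exclusion_at_threshold(self):
        anns = self.make_annotations(
            {"f1": (1, 300)}, {"o1": (5, 1200), "o2": (5, 1200)}
        )
        clusters = [Cluster("C1", [("Pp", "f1"), ("At", "o1"), ("At", "o2")])]
        res = infer_intron_loss(clusters, anns, "Pp", length_ratio_threshold=0.5)
        (call,) = res.calls
        assert call.excluded_fragmentary and call.call == "none"
        assert res.n_reduced == 0

    def test_unknown_member_errors(self):
        anns = self.make_annotations({"f1": (2, 1000)}, {"o1": (5, 1000)})
        clusters = [Cluster("C1", [("Pp", "f1"), ("At", "missing")])]
        with pytest.raises(KeyError, match="missing"):
            infer_intron_loss(clusters, anns, "Pp")

    def test_loss_monotone_under_intron_removal(self):
        # an already-called gene stays called when it loses more introns
        anns = self.make_annotations(
            {"f1": (4, 1500)}, {"o1": (5, 1500), "o2": (7, 1500), "o3": (9, 1500)}
        )
        clusters = [Cluster("C1", [("Pp", "f1"), ("At", "o1"), ("At", "o2"), ("At", "o3")])]
        first = infer_intron_loss(clusters, anns, "Pp").calls[0].call
        assert first == "reduced_introns"
        anns2 = self.make_annotations(
            {"f1": (2, 1500)}, {"o1": (5, 1500), "o2": (7, 1500), "o3": (9, 1500)}
        )
        second = infer_intron_loss(clusters, anns2, "Pp").calls[0].call
        assert second == "reduced_introns"

    def test_planted_fraction_recovered_exactly(self):
        cfg = ClusterConfig(seed=17, n_focal_genes=1000)
        clusters, anns, hits, est, truth = generate_cluster_set(cfg)
        res = infer_intron_loss(
            clusters, anns, cfg.focal_species,
            length_ratio_threshold=cfg.length_ratio_threshold,
        )
        assert res.reduced_fraction == pytest.approx(cfg.loss_fraction)
        assert res.full_loss_fraction == pytest.approx(cfg.full_loss_fraction)
        # fragmentary decoys excluded, never called
        frag = {g for g, k in truth.loss_class.items() if k == "fragmentary"}
        called = {c.gene_id for c in res.calls if c.call != "none"}
        assert not (frag & called)

    def test_planted_full_loss_precision_recall(self):
        cfg = ClusterConfig(seed=23, n_focal_genes=500, fragmentary_rate=0.0)
        clusters, anns, *_ , truth = generate_cluster_set(cfg)
        res = infer_intron_loss(clusters, anns, cfg.focal_species)
        called_full = {g for g, c in res.per_locus.items() if c == "full_loss"}
        true_full = {g for g, k in truth.loss_class.items() if k == "full_loss"}
        assert called_full == true_full
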