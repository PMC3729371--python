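"""Per-genome gene-structure statistics and 5'-UTR intron profiling.

Computes the standard per-genome summary (means x̄ and interpolated medians x̃
for gene/transcript/CDS/exon/intron/UTR lengths, exon counts, UTR presence
fractions, gene density), region-classified intron-length profiles with the
fraction of introns longer than a threshold (default 500 bp, strictly
greater), 5'-UTR intron-count frequencies (denominator: transcripts with a
5'-UTR), and the spliced-coordinate distances of the proximal 5'-UTR intron
to the translation (ATG) and transcription start sites.

Also houses the two-sample machinery: tie-corrected normal-approximation
rank-sum, a one-sided exact two-proportion (hypergeometric) test computed in
log space so p-values far below float underflow remain reportable, and
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .models import GenomeAnnotation, Transcript, total_length

LENGTH_ROWS = (
    "gene_length",
    "transcript_length",
    "cds_length",
    "exon_length",
    "intron_length",
    "exons_per_gene",
    "introns_per_gene",
    "utr5_exon_length",
    "utr5_intron_length",
    "utr3_exon_length",
    "utr3_intron_length",
    "utr5_length",
    "utr3_length",
)

COUNT_ROWS = (
    "genes",
    "transcripts",
    "multi_exon_transcripts",
    "single_exon_transcripts",
    "with_utr5",
    "with_utr3",
    "with_both_utrs",
    "without_utr",
    "multi_exon_utr5",
    "single_exon_utr5",
    "multi_exon_utr3",
    "single_exon_utr3",
)


@dataclass
class StructStats:
    species_label: str
    means: dict[str, float]
    medians: dict[str, float]
    counts: dict[str, int]
    fractions: dict[str, float]
    gene_density_kb: Optional[float] = None
    scope: str = "all_transcripts"

    def to_rows(self) -> list[dict]:
        rows = []
        for k in LENGTH_ROWS:
            rows.append(
                {"statistic": k, "mean": self.means.get(k), "median": self.medians.get(k)}
            )
        for k in COUNT_ROWS:
            rows.append(
                {"statistic": k, "count": self.counts.get(k),
                 "fraction": self.fractions.get(k)}
            )
        if self.gene_density_kb is not None:
            rows.append({"statistic": "gene_density_kb_per_gene",
                         "mean": self.gene_density_kb})
        return rows


def representative_transcript(gene) -> Transcript:
    """Longest spliced transcript; ties broken by smallest id."""
    return min(gene.transcripts, key=lambda t: (-t.spliced_length, t.id))


def _scoped_transcripts(annotation: GenomeAnnotation, scope: str) -> list[Transcript]:
    if scope == "all_transcripts":
        return list(annotation.transcripts())
    if scope == "representative_only":
        return [representative_transcript(g) for g in annotation.genes]
    raise ValueError(f"unknown scope {scope!r}")


def _mean(xs) -> float:
    xs = list(xs)
    return float(np.mean(xs)) if xs else float("nan")


def _median(xs) -> float:
    xs = list(xs)
    return float(np.median(xs)) if xs else float("nan")


def genome_structure_summary(
    annotation: GenomeAnnotation, scope: str = "all_transcripts"
) -> StructStats:
    """Compute the per-genome structure summary.

    Length statistics are pooled over the units in scope; CDS/UTR rows are
    restricted to coding transcripts.  Gene density (kb per gene) is computed
    when ``annotation.genome_size`` is set.
    """
    if not annotation.genes:
        raise ValueError("no genes in annotation")
    ts = _scoped_transcripts(annotation, scope)

    gene_lengths = [g.length for g in annotation.genes]
    transcript_lengths = [t.spliced_length for t in ts]
    coding = [t for t in ts if t.is_coding]
    cds_lengths = [t.cds_length for t in coding]
    exon_lengths = [e - s for t in ts for s, e in t.exons]
    intron_lengths = [i.length for t in ts for i in t.introns]
    exons_per = [len(t.exons) for t in ts]
    introns_per = [len(t.exons) - 1 for t in ts]
    utr5_exon = [e - s for t in coding for s, e in t.utr5]
    utr3_exon = [e - s for t in coding for s, e in t.utr3]
    utr5_intron = [i.length for t in coding for i in t.introns if i.region == "UTR5"]
    utr3_intron = [i.length for t in coding for i in t.introns if i.region == "UTR3"]
    utr5_total = [total_length(t.utr5) for t in coding if t.utr5]
    utr3_total = [total_length(t.utr3) for t in coding if t.utr3]

    samples = {
        "gene_length": gene_lengths,
        "transcript_length": transcript_lengths,
        "cds_length": cds_lengths,
        "exon_length": exon_lengths,
        "intron_length": intron_lengths,
        "exons_per_gene": exons_per,
        "introns_per_gene": introns_per,
        "utr5_exon_length": utr5_exon,
        "utr5_intron_length": utr5_intron,
        "utr3_exon_length": utr3_exon,
        "utr3_intron_length": utr3_intron,
        "utr5_length": utr5_total,
        "utr3_length": utr3_total,
    }
    means = {k: _mean(v) for k, v in samples.items()}
    medians = {k: _median(v) for k, v in samples.items()}

    n_multi = sum(1 for t in ts if len(t.exons) > 1)
    with5 = [t for t in coding if t.utr5]
    with3 = [t for t in coding if t.utr3]
    counts = {
        "genes": len(annotation.genes),
        "transcripts": len(ts),
        "multi_exon_transcripts": n_multi,
        "single_exon_transcripts": len(ts) - n_multi,
        "with_utr5": len(with5),
        "with_utr3": len(with3),
        "with_both_utrs": sum(1 for t in coding if t.utr5 and t.utr3),
        "without_utr": sum(1 for t in ts if not (t.is_coding and (t.utr5 or t.utr3))),
        "multi_exon_utr5": sum(1 for t in with5 if len(t.utr5) > 1),
        "single_exon_utr5": sum(1 for t in with5 if len(t.utr5) == 1),
        "multi_exon_utr3": sum(1 for t in with3 if len(t.utr3) > 1),
        "single_exon_utr3": sum(1 for t in with3 if len(t.utr3) == 1),
    }
    n = len(ts)
    fractions = {
        "multi_exon_transcripts": n_multi / n,
        "single_exon_transcripts": (n - n_multi) / n,
        "with_utr5": counts["with_utr5"] / n,
        "with_utr3": counts["with_utr3"] / n,
        "with_both_utrs": counts["with_both_utrs"] / n,
        "without_utr": counts["without_utr"] / n,
        "multi_exon_utr5": (counts["multi_exon_utr5"] / len(with5)) if with5 else float("nan"),
        "single_exon_utr5": (counts["single_exon_utr5"] / len(with5)) if with5 else float("nan"),
        "multi_exon_utr3": (counts["multi_exon_utr3"] / len(with3)) if with3 else float("nan"),
        "single_exon_utr3": (counts["single_exon_utr3"] / len(with3)) if with3 else float("nan"),
    }
    density = None
    if annotation.genome_size is not None:
        density = annotation.genome_size / len(annotation.genes) / 1000.0
    return StructStats(
        species_label=annotation.species_label,
        means=means,
        medians=medians,
        counts=counts,
        fractions=fractions,
        gene_density_kb=density,
        scope=scope,
    )


@dataclass
class IntronLengthProfile:
    threshold: int
    lengths: dict[str, list[int]]
    means: dict[str, float]
    medians: dict[str, float]
    frac_gt_threshold: dict[str, float]
    histograms: dict[str, np.ndarray]
    bin_edges: np.ndarray


def intron_length_profile(
    annotation: GenomeAnnotation,
    threshold: int = 500,
    bin_width: int = 100,
    max_bin: int = 3000,
) -> IntronLengthProfile:
    """Region-classified intron lengths; fraction strictly longer than
    ``threshold`` per class.  Empty classes yield empty profiles (NaN stats)."""
    lengths: dict[str, list[int]] = {"UTR5": [], "CDS": [], "UTR3": []}
    for t in annotation.transcripts():
        for i in t.introns:
            lengths[i.region].append(i.length)
    edges = np.arange(0, max_bin + bin_width, bin_width)
    means, medians, fracs, hists = {}, {}, {}, {}
    for k, v in lengths.items():
        means[k] = _mean(v)
        medians[k] = _median(v)
        fracs[k] = (sum(1 for x in v if x > threshold) / len(v)) if v else float("nan")
        hists[k] = np.histogram(np.clip(v, 0, max_bin), bins=edges)[0] if v else np.zeros(
            len(edges) - 1, dtype=int
        )
    return IntronLengthProfile(threshold, lengths, means, medians, fracs, hists, edges)


@dataclass
class Utr5IntronFrequencies:
    frequencies: dict[int, float]
    counts: dict[int, int]
    n_with_utr5: int

    @property
    def empty(self) -> bool:
        return self.n_with_utr5 == 0


def utr5_intron_count_frequencies(annotation: GenomeAnnotation) -> Utr5IntronFrequencies:
    """Distribution of 5'-UTR intron counts per transcript.

    Denominator: transcripts with a non-empty 5'-UTR.  Frequencies sum to 1.
    """
    counts: dict[int, int] = {}
    n = 0
    for t in annotation.transcripts():
        if not t.utr5:
            continue
        n += 1
        k = sum(1 for i in t.introns if i.region == "UTR5")
        counts[k] = counts.get(k, 0) + 1
    freqs = {k: v / n for k, v in sorted(counts.items())} if n else {}
    return Utr5IntronFrequencies(freqs, dict(sorted(counts.items())), n)


@dataclass
class Utr5PositionProfile:
    """Per qualifying transcript: the 5'-UTR intron closest to the ATG."""

    transcript_ids: list[str]
    distance_to_atg: np.ndarray  # spliced nt, acceptor end -> first CDS base
    distance_to_tss: np.ndarray  # spliced nt, transcript 5' end -> donor end
    atg_threshold: int = 65

    @property
    def frac_atg_below_threshold(self) -> float:
        if len(self.distance_to_atg) == 0:
            return float("nan")
        return float(np.mean(self.distance_to_atg < self.atg_threshold))

    def cumulative(self, which: str = "atg") -> tuple[np.ndarray, np.ndarray]:
        d = self.distance_to_atg if which == "atg" else self.distance_to_tss
        xs = np.sort(d)
        return xs, np.arange(1, len(xs) + 1) / len(xs)


def proximal_utr5_intron_distances(
    annotation: GenomeAnnotation, atg_threshold: int = 65
) -> Utr5PositionProfile:
    """Spliced-coordinate distances of the proximal 5'-UTR intron.

    For each coding transcript with at least one 5'-UTR intron, the intron
    with the smallest distance to the CDS start (ATG) is selected;
    ``distance_to_atg`` is the spliced distance from its acceptor end to the
    first CDS base and ``distance_to_tss`` from the transcript 5' end to its
    donor end.  The '<65 bp' fraction uses strictly-less.
    """
    ids, atg, tss = [], [], []
    for t in annotation.transcripts():
        if not t.is_coding:
            continue
        u5 = [i for i in t.introns if i.region == "UTR5"]
        if not u5:
            continue
        cds_sorted = sorted(t.cds)
        if t.strand == "+":
            c5 = t.spliced_offset(cds_sorted[0][0])
        else:
            c5 = t.spliced_offset(cds_sorted[-1][1] - 1)
        best = min(u5, key=lambda i: c5 - i.acceptor_offset)
        ids.append(t.id)
        atg.append(c5 - best.acceptor_offset)
        tss.append(best.donor_offset)
    return Utr5PositionProfile(
        ids, np.asarray(atg, dtype=int), np.asarray(tss, dtype=int), atg_threshold
    )


@dataclass
class TestResult:
    statistic: float
    p: float  # two-sided for rank_sum; one-sided 'greater' for the exact test
    p_greater: Optional[float] = None
    p_less: Optional[float] = None
    p_two_sided: Optional[float] = None
    log10_p: Optional[float] = None


def log_hypergeom_sf(a: int, N: int, K: int, n: int) -> float:
    """log P(X >= a) for X ~ Hypergeom(N, K, n), summed in log space."""
    lo = max(0, n + K - N)
    hi = min(n, K)
    if a <= lo:
        return 0.0
    ks = np.arange(a, hi + 1)
    if len(ks) == 0:
        return -math.inf
    return float(logsumexp(hypergeom.logpmf(ks, N, K, n)))


def log_hypergeom_cdf(a: int, N: int, K: int, n: int) -> float:
    """log P(X <= a) for X ~ Hypergeom(N, K, n), summed in log space."""
    lo = max(0, n + K - N)
    hi = min(n, K)
    if a >= hi:
        return 0.0
    if a < lo:
        return -math.inf
    ks = np.arange(lo, a + 1)
    return float(logsumexp(hypergeom.logpmf(ks, N, K, n)))


def two_proportion_exact(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """One-sided exact two-proportion test (conditional hypergeometric tail).

    Tests whether the first proportion exceeds the second (``p_greater``) and
    the reverse (``p_less``); ``p_two_sided`` is the doubled smaller tail
    capped at 1.  Computed in log space: ``log10_p`` stays finite down to
    arbitrarily extreme tails even when ``p`` underflows to 0.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("empty sample")
        if k > n or k < 0:
            raise ValueError("successes out of range")
    N, K = n1 + n2, k1 + k2
    log_pg = log_hypergeom_sf(k1, N, K, n1)
    log_pl = log_hypergeom_cdf(k1, N, K, n1)
    pg, pl = math.exp(min(0.0, log_pg)), math.exp(min(0.0, log_pl))
    log_min = min(log_pg, log_pl)
    p_two = min(1.0, 2.0 * math.exp(log_min))
    return TestResult(
        statistic=float(k1),
        p=pg,
        p_greater=pg,
        p_less=pl,
        p_two_sided=p_two,
        log10_p=log_pg / math.log(10),
    )


def rank_sum(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum, normal approximation with tie correction."""
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise ValueError("empty sample")
    res = mannwhitneyu(sample_a, sample_b, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue)
    return TestResult(
        statistic=float(res.statistic),
        p=p,
        p_two_sided=p,
        log10_p=math.log10(p) if p > 0 else -math.inf,
    )


def compare_groups(sample_a, sample_b, test: str = "rank_sum") -> TestResult:
    """Two-sample comparison used throughout the comparative analyses.

    ``rank_sum`` takes two length samples; ``two_proportion_exact`` takes two
    ``(successes, total)`` pairs.
    """
    if test == "rank_sum":
        return rank_sum(sample_a, sample_b)
    if test == "two_proportion_exact":
        (k1, n1), (k2, n2) = sample_a, sample_b
        return two_proportion_exact(k1, n1, k2, n2)
    raise ValueError(f"unknown test {test!r}")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
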