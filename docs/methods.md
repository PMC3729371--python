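# Methods

This note records the models, conventions and design choices behind each
analysis step, in the order a pipeline run visits them.

## Gene-model geometry

External files use GFF3's 1-based inclusive coordinates; everything in
memory is 0-based half-open, which removes off-by-one cases from interval
arithmetic. UTR features present in an input GFF3 are ignored and re-derived
from exon/CDS geometry, so there is exactly one authority for region
classification and the partition invariant |5'-UTR| + |CDS| + |3'-UTR| =
spliced length is testable on any transcript.

Intron region classes are decided purely in spliced (mRNA) coordinates: an
intron's junction offset `j` (nucleotides from the transcript 5' end) is
compared with the CDS start offset `c5` and stop offset `c3` (exclusive);
`j <= c5` is a 5'-UTR intron, `j >= c3` a 3'-UTR intron, otherwise CDS. An
intron abutting the ATG (`j == c5`) is counted as 5'-UTR. Introns always lie
strictly between exons, so no straddle case exists. Transcripts without CDS
are retained but excluded from CDS/UTR statistics; their introns are
classified CDS by convention.

## Structure statistics

All length statistics are pooled over the units in scope; medians are
interpolated (mean of the middle pair). Two scopes are exposed because
per-gene rows are ambiguous whenever loci carry several isoforms:
`all_transcripts` (default) averages per-transcript values over every
isoform, `representative_only` keeps one transcript per locus (longest
spliced length, ties to the smallest identifier). Gene density is
genome_size / locus count, reported in kb per gene.

Boundary conventions are fixed and strict: "longer than 500 bp" means
`> 500`; "closer than 65 bp to the ATG" means `< 65`. The proximal 5'-UTR
intron of a transcript is the one minimizing the spliced distance from its
acceptor end to the first CDS base; `distance_to_tss` is its donor offset.
Distances are measured in spliced coordinates, because the functional length
of a 5'-UTR is its spliced length; whether genomic distances were intended
in the original analyses is unknown, so the choice is documented rather than
guessed and the profile retains per-transcript values for re-aggregation.

## Two-sample tests

Rank-sum comparisons use the normal approximation with tie correction
(two-sided). The two-proportion test is the one-sided exact conditional
(hypergeometric) tail, summed in log space from the log-pmf, because the
interesting genome-scale comparisons produce p-values far below the
smallest normal double (~1e-308): the multi-exon 5'-UTR comparison of
7,120/18,180 vs 7,940/31,793 yields log10 p ≈ −238, which a linear-space
`sf` would return as exactly 0. Both one-sided directions and the doubled
two-sided p are reported, alongside log10(p). Multiple testing is handled
with Benjamini–Hochberg FDR.

## Alternative-splicing classification

Events between two isoforms are detected only inside the genomic overlap of
their spans, so transcription-start and poly-A variation produces no event.
The rules, in precedence order:

1. a transcript terminus strictly inside the partner's intron →
   `starts_in_intron` / `ends_in_intron` (5'/3' terminus, strand-aware);
2. cassette exon: an internal exon strictly inside a partner intron whose
   flanking introns share that intron's outer splice sites →
   `retained_exon` on the exon carrier, `skipped_exon` on the partner;
3. an intron strictly inside a partner exon → `spliced_intron` on the
   intron carrier, `retained_intron` on the exon carrier;
4. two introns sharing exactly one splice site (donor = transcript-5' end
   of the intron) → `alt_acceptor` / `alt_donor`; the carrier is the
   transcript splicing the shorter intron, which makes classification
   symmetric in its arguments;
5. residual: an exon in the overlap with no exact (overlap-clipped) match
   in the partner and not explained above → `alternate_exon`. A
   mutually-exclusive exon pair therefore yields one `alternate_exon` per
   unmatched exon, and the introns flanking such exons are shielded from
   rule 4 so the pair is not misread as alternative splice sites.

All ties at shared boundaries resolve by strict containment (a boundary on
an edge is not "inside"). Retained/spliced intron and retained/skipped exon
are always emitted as complementary pairs, which locus-level counts must
preserve — an invariant the tests check on arbitrary inputs. The classifier
is verified against an independent brute-force re-implementation (global
predicate enumeration over all splice-site/exon containment relations) on
randomized two-isoform loci.

A locus is alternatively spliced iff it has ≥ 2 structurally distinct
isoforms. Its effect class compares CDS interval chains across isoforms
(any difference → CDS-altering) and flags UTR involvement when an event's
interval avoids the CDS of both isoforms in its pair; distinct protein
count is the number of distinct CDS chains.

## Gene families and intron loss

Representative isoforms per focal locus are chosen by a three-tier rule:
(1) minimum uncorrected p-distance (gap columns excluded) to any non-focal
cluster member; (2) for focal-only clusters, best coverage of the closest
homology hit; (3) longest transcript. All ties break to the
lexicographically smallest transcript identifier, making selection
deterministic.

Intron-loss inference compares, per cluster, the focal representative's
intron count against the interpolated median intron count `m` of non-focal
representatives: strictly fewer introns → `reduced_introns`; zero introns
with `m >= 1` → additionally `full_loss`. "Significantly shorter"
fragmentary models are excluded by a transcript-length ratio threshold
(default 0.5 of the median non-focal transcript length) — the original
criterion is verbal, so the threshold is exposed as a parameter rather than
hard-coded. A locus appearing in several clusters is evaluated per cluster
and reported with its most severe call. Genome fractions use all focal
genes as denominator, fragmentary exclusions included (they simply receive
no call).

Family expansion flags: focal count strictly greater than the largest
single non-focal species count; strong expansion strictly greater than
twice that. By this rule 3-vs-1 is already a strong expansion. Orphan
classes are decided in order: membership in a multi-species cluster beats
everything; then any homology hit; then transcript (EST) evidence
separates `orphan_with_est` from `orphan_no_homolog`.

## Functional annotation

Slim mapping replaces a term by its *minimal* slim ancestors over
is_a ∪ part_of (slim hits that are ancestors of other hits are dropped);
terms already in the slim map to themselves, making the operation
idempotent. Terms missing from the ontology are dropped with a warning;
terms with no slim ancestor are dropped by default or mapped to the aspect
root on request.

pred2GOA pools one vote per predictor tool per protein (the best-scoring
call when a tool reports several), maps compartment labels to GO CC terms
through per-tool configuration, and assigns a term iff its supporting
weight strictly exceeds `majority_fraction` (default 0.5) of the total
voting weight — an exact half is not a majority. For proteins whose gene
model lacks an annotated UTR or start codon, the N-terminus may be missing,
so targeting-peptide predictors (N-terminal-only tools) cannot be trusted
alone: assignment additionally requires at least one supporting tool that
reads beyond the N-terminus. Default tool weights are uniform because the
original per-tool weighting is unpublished; weights and flags are
configuration. Consensus terms carry evidence code ISS and are merged into
the existing annotation without deletions; conflicting compartments remain
side by side with their provenance.

Two-species enrichment tests each term's 2×2 table of annotated-gene
counts against per-aspect universes (genes with ≥ 1 annotation in the
aspect by default; configurable to whole-genome universes, since the
original universe definition is unpublished). One-sided exact tails are
computed in both directions in log space; q-values are BH-adjusted per
aspect on the two-sided p. The "weight01"-style ontology decorrelation is
out of scope; the classic per-term exact test is the documented method.

## Effective number of codons

Wright's estimator with the homozygosity F̂ = (n·Σp̂² − 1)/(n − 1) per amino
acid, averaged within degeneracy classes (9 two-fold, Ile alone three-fold,
5 four-fold, 3 six-fold; Met/Trp excluded, stops excluded):
Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. Amino acids observed fewer than twice
or with F̂ ≤ 0 are skipped; a missing three-fold class is interpolated as
(F̄₂ + F̄₄)/2; an empty required class makes the statistic undefined (None).
The estimate is clamped to ≤ 61, so exactly uniform usage reports 61.0
(the finite-sample F̂ under uniform counts is slightly below 1/k, which
would otherwise push Nc marginally above the theoretical maximum).

## Synthetic data: what it emulates, and what it does not

The genome generator draws exon counts from a shifted Poisson (mean 5
exons/gene), per-region intron lengths from lognormals targeting means of
520 bp (5'-UTR), 264 bp (CDS) and 268 bp (3'-UTR) with σ = 0.75, UTR
presence probabilities of 0.474 (5') and 0.496 (3'), a multi-exon 5'-UTR
share of 0.392 among UTR-bearing transcripts, and CDS lengths from a
lognormal targeting 1,062 bp rounded to codon multiples — the structural
conditions the comparative analyses measure. Alternative splicing is
*planted*: exactly `round(as_fraction × n_genes)` loci (default 10.8%)
receive a second isoform constructed to exhibit one requested event type
and nothing else, with the event placed in the CDS or a UTR with equal
probability. The cluster generator likewise plants loss, fragmentary,
expansion and orphan counts exactly (constructed, not sampled), so
downstream recoveries can be asserted as equalities; sampled quantities
(intron-length means, exon counts) are asserted with 3σ CLT bounds at
n = 2,000 genes — sizes chosen so the whole suite and the acceptance run
finish in seconds while leaving the CLT bounds tight.

Deliberately not emulated: nucleotide sequence (no FASTA; splice-site
dinucleotides, codon content and compositional bias do not exist except in
the dedicated codon-bias generator, which emits codon strings only);
ATG-proximal positioning of 5'-UTR introns (UTR exon segments are drawn
independently of the CDS, so the "< 65 nt to the ATG" fraction of real
genomes is not reproduced — the statistic is computed, not calibrated);
overlapping genes, trans-splicing, and isoform-expression levels. Passing
tests therefore demonstrate the correctness of the *measurements and
inference rules* under known truth, not the realism of any particular
genome.

All generators are driven by a single integer seed through one RNG; emitted
coordinates are integers, so identical seeds give byte-identical files.

## Known limitations

- The AS taxonomy is defined on annotated isoform structures; assembling
  isoforms from raw transcript evidence is upstream of this package, and
  the transcript/locus granularities here correspond only approximately to
  assembly/subcluster counts of alignment-assembly pipelines.
- Intron-loss calls are relative to the family median, not to a resolved
  phylogeny; genuinely intron-poor families yield no signal.
- The enrichment layer tests terms independently; parent/child correlation
  inflates the effective number of tests relative to ontology-aware
  methods.
- pred2GOA treats predictor errors as independent; correlated tool errors
  (shared training data) would overstate consensus confidence.
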