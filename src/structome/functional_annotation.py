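"""GO annotation layer: slim mapping, weighted subcellular-prediction
consensus (pred2GOA), GOA summaries and two-species term enrichment.

pred2GOA turns per-protein votes from several subcellular-localization
predictors into cellular-component GO terms: each tool's compartment call is
mapped to a slim CC term and weighted; a term is assigned when its supporting
weight strictly exceeds ``majority_fraction`` of the total weight of the
tools that voted on that protein.  For proteins whose N-terminus may be
missing (no annotated UTR or no start codon) the assignment additionally
requires support from at least one predictor that looks beyond the
N-terminal region, since targeting-peptide predictors are blind on truncated
models.  Consensus assignments carry the ISS evidence code and are merged
with the existing annotation without deleting anything.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .io import _relation_subgraph
from .models import GoAnnotation
from .structure_stats import bh_fdr, log_hypergeom_cdf, log_hypergeom_sf

log = logging.getLogger(__name__)

ASPECT_ROOTS = {"BP": "GO:0008150", "MF": "GO:0003674", "CC": "GO:0005575"}


class SlimMapper:
    """Maps detailed GO terms to their minimal slim ancestors."""

    def __init__(self, ontology: nx.MultiDiGraph, slim_terms: Iterable[str]):
        self.graph = _relation_subgraph(ontology)
        self.slim = set(slim_terms)
        self._cache: dict[str, frozenset[str]] = {}

    def ancestors(self, term: str) -> set[str]:
        if term not in self.graph:
            return set()
        return set(nx.descendants(self.graph, term))

    def map_term(self, term: str) -> frozenset[str]:
        """Minimal slim ancestors of ``term`` (itself if already in slim)."""
        if term in self._cache:
            return self._cache[term]
        if term in self.slim:
            out = frozenset({term})
        else:
            hits = self.ancestors(term) & self.slim
            # minimality: drop slim terms that are ancestors of another hit
            redundant = set()
            for s in hits:
                redundant |= self.ancestors(s) & hits
            out = frozenset(hits - redundant)
        self._cache[term] = out
        return out


def map_to_slim(
    goa: Iterable[GoAnnotation],
    ontology: nx.MultiDiGraph,
    slim_terms: Iterable[str],
    unmapped: str = "drop",
) -> list[GoAnnotation]:
    """Replace each annotation by its minimal slim ancestors.

    Terms absent from the ontology (e.g. obsolete) are dropped with a
    warning.  Terms with no slim ancestor map to the aspect root when
    ``unmapped='root'``, else are dropped.  Output is deduplicated per
    (gene, term, aspect); idempotent over slim-level input.
    """
    mapper = SlimMapper(ontology, slim_terms)
    out: list[GoAnnotation] = []
    seen: set[tuple[str, str, str]] = set()
    for a in goa:
        if a.term not in mapper.graph:
            log.warning("term %s not in ontology (obsolete?); dropped", a.term)
            continue
        targets = mapper.map_term(a.term)
        if not targets:
            if unmapped == "root":
                targets = frozenset({ASPECT_ROOTS[a.aspect]})
            else:
                continue
        for t in sorted(targets):
            key = (a.gene_id, t, a.aspect)
            if key in seen:
                continue
            seen.add(key)
            out.append(GoAnnotation(a.gene_id, t, a.aspect, a.evidence_code, a.source_ref))
    return out


@dataclass
class ToolConfig:
    name: str
    weight: float = 1.0
    n_terminal_only: bool = False
    compartment_map: dict[str, str] = field(default_factory=dict)  # label -> GO CC

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError(f"tool {self.name}: weight must be positive")


@dataclass(frozen=True)
class PredictorCall:
    tool: str
    protein: str
    compartment: str
    score: Optional[float] = None


@dataclass
class ConsensusAssignment:
    protein: str
    term: str  # GO CC slim term
    weight: float  # supporting weight as a fraction of the total voting weight
    evidence_code: str = "ISS"
    tools: tuple[str, ...] = ()


def pred2goa(
    calls: Sequence[PredictorCall],
    tools: Mapping[str, ToolConfig],
    complete: Mapping[str, bool],
    existing_goa: Sequence[GoAnnotation] = (),
    majority_fraction: float = 0.5,
) -> tuple[list[ConsensusAssignment], list[GoAnnotation]]:
    """Weighted majority-rule consensus of subcellular predictions.

    Returns the consensus assignments and the merged GOA (existing
    annotations preserved; consensus terms appended with evidence ISS).
    An unmappable compartment label is an error naming tool and label.
    """
    by_protein: dict[str, list[PredictorCall]] = {}
    for c in calls:
        tc = tools.get(c.tool)
        if tc is None:
            raise ValueError(f"unknown predictor tool {c.tool!r}")
        if c.compartment not in tc.compartment_map:
            raise ValueError(
                f"tool {c.tool}: compartment label {c.compartment!r} has no GO mapping"
            )
        by_protein.setdefault(c.protein, []).append(c)

    assignments: list[ConsensusAssignment] = []
    for protein in sorted(by_protein):
        pcalls = by_protein[protein]
        # one vote per tool: keep the best-scoring call of each tool
        best_by_tool: dict[str, PredictorCall] = {}
        for c in pcalls:
            prev = best_by_tool.get(c.tool)
            if prev is None or (c.score or 0.0) > (prev.score or 0.0):
                best_by_tool[c.tool] = c
        total_weight = sum(tools[t].weight for t in best_by_tool)
        support: dict[str, list[str]] = {}
        for tname, c in best_by_tool.items():
            term = tools[tname].compartment_map[c.compartment]
            support.setdefault(term, []).append(tname)
        is_complete = complete.get(protein, True)
        for term in sorted(support):
            voters = support[term]
            w = sum(tools[t].weight for t in voters)
            if w <= majority_fraction * total_weight:
                continue
            if not is_complete and all(tools[t].n_terminal_only for t in voters):
                continue  # N-terminal gating for incomplete gene models
            assignments.append(
                ConsensusAssignment(
                    protein=protein,
                    term=term,
                    weight=w / total_weight,
                    tools=tuple(sorted(voters)),
                )
            )

    merged = list(existing_goa)
    have = {(a.gene_id, a.term, a.aspect) for a in merged}
    for a in assignments:
        key = (a.protein, a.term, "CC")
        if key not in have:
            have.add(key)
            merged.append(
                GoAnnotation(a.protein, a.term, "CC", "ISS", "STRUCTOME:pred2goa")
            )
    return assignments, merged


@dataclass
class GoaSummary:
    total_terms: int  # non-redundant (gene, term) pairs
    terms_by_aspect: dict[str, int]
    genes_with_terms: int
    genes_by_aspect: dict[str, int]
    coverage: float
    coverage_by_aspect: dict[str, float]


def goa_summary(goa: Iterable[GoAnnotation], total_gene_count: int) -> GoaSummary:
    """Non-redundant per-aspect term and gene counts plus coverage."""
    pairs: set[tuple[str, str, str]] = set()
    for a in goa:
        pairs.add((a.gene_id, a.term, a.aspect))
    by_aspect = {"BP": 0, "MF": 0, "CC": 0}
    genes_by_aspect: dict[str, set[str]] = {"BP": set(), "MF": set(), "CC": set()}
    genes: set[str] = set()
    for gid, term, aspect in pairs:
        by_aspect[aspect] += 1
        genes_by_aspect[aspect].add(gid)
        genes.add(gid)
    return GoaSummary(
        total_terms=len(pairs),
        terms_by_aspect=by_aspect,
        genes_with_terms=len(genes),
        genes_by_aspect={k: len(v) for k, v in genes_by_aspect.items()},
        coverage=len(genes) / total_gene_count if total_gene_count else float("nan"),
        coverage_by_aspect={
            k: len(v) / total_gene_count if total_gene_count else float("nan")
            for k, v in genes_by_aspect.items()
        },
    )


@dataclass
class EnrichmentResult:
    term: str
    aspect: str
    a: int  # focal genes annotated with the term
    A: int  # focal universe
    b: int  # other genes annotated
    B: int  # other universe
    odds_ratio: float
    p_greater: float  # focal-enriched
    p_less: float  # focal-depleted
    p: float  # two-sided (doubled smaller tail, capped at 1)
    q: float = float("nan")
    log10_p_greater: float = float("nan")

    @property
    def direction(self) -> str:
        return "focal-enriched" if self.p_greater <= self.p_less else "focal-depleted"


def term_enrichment(
    goa_focal: Iterable[GoAnnotation],
    goa_other: Iterable[GoAnnotation],
    universes: Optional[Mapping[str, tuple[int, int]]] = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-term two-species enrichment (exact hypergeometric, log-space).

    For every term present in either annotation set, a 2x2 table of
    annotated-gene counts against the per-aspect universes (defaulting to
    the number of genes with at least one annotation in that aspect) is
    tested one-sided in each direction; Benjamini-Hochberg q-values are
    computed per aspect on the two-sided p.  Results sorted by q then term;
    significance is q < alpha (callers filter).
    """
    def collect(goa):
        genes_by_term: dict[tuple[str, str], set[str]] = {}
        genes_by_aspect: dict[str, set[str]] = {}
        for a in goa:
            genes_by_term.setdefault((a.aspect, a.term), set()).add(a.gene_id)
            genes_by_aspect.setdefault(a.aspect, set()).add(a.gene_id)
        return genes_by_term, genes_by_aspect

    focal_terms, focal_genes = collect(goa_focal)
    other_terms, other_genes = collect(goa_other)

    results: list[EnrichmentResult] = []
    for aspect in ("BP", "MF", "CC"):
        if universes and aspect in universes:
            A, B = universes[aspect]
        else:
            A = len(focal_genes.get(aspect, ()))
            B = len(other_genes.get(aspect, ()))
        if A == 0 or B == 0:
            continue
        terms = {t for (asp, t) in list(focal_terms) + list(other_terms) if asp == aspect}
        aspect_results = []
        for term in sorted(terms):
            a = len(focal_terms.get((aspect, term), ()))
            b = len(other_terms.get((aspect, term), ()))
            N, K = A + B, a + b
            log_pg = log_hypergeom_sf(a, N, K, A)
            log_pl = log_hypergeom_cdf(a, N, K, A)
            pg = math.exp(min(0.0, log_pg))
            pl = math.exp(min(0.0, log_pl))
            p_two = min(1.0, 2.0 * min(pg, pl))
            with np.errstate(divide="ignore", invalid="ignore"):
                odds = _odds_ratio(a, A, b, B)
            aspect_results.append(
                EnrichmentResult(
                    term=term, aspect=aspect, a=a, A=A, b=b, B=B,
                    odds_ratio=odds, p_greater=pg, p_less=pl, p=p_two,
                    log10_p_greater=log_pg / math.log(10),
                )
            )
        qs = bh_fdr([r.p for r in aspect_results])
        for r, q in zip(aspect_results, qs):
            r.q = max(float(q), r.p)  # BH never reports below the raw p
        results.extend(aspect_results)
    results.sort(key=lambda r: (r.q, r.term))
    return results


def _odds_ratio(a: int, A: int, b: int, B: int) -> float:
    num = a * (B - b)
    den = b * (A - a)
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den
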