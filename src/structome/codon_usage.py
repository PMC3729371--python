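"""Wright's effective number of codons (Nc).

Nc measures codon-usage bias on a scale from 20 (exactly one codon used per
amino acid, maximal bias) to 61 (uniform synonymous usage).  Per amino acid
the homozygosity is estimated as F = (n * sum(p_i^2) - 1) / (n - 1) over its
n observed codons; F-bar_k averages F over amino acids of synonymous-family
size (degeneracy) k, and

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

for the standard genetic code (2 single-codon amino acids Met and Trp
contribute the leading 2; stop codons are excluded).  The estimate is
clamped to <= 61.
"""

from __future__ import annotations

from typing import Optional

from Bio.Data import CodonTable

_VALID = set("ACGT")


def _synonym_families() -> dict[str, list[str]]:
    """amino acid -> list of codons, standard code, stops excluded."""
    table = CodonTable.unambiguous_dna_by_id[1]
    fams: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return fams


_FAMILIES = _synonym_families()
_CODON_TO_AA = {c: aa for aa, cs in _FAMILIES.items() for c in cs}
# amino acids per degeneracy class in the standard code: 9 two-fold, 1
# three-fold (Ile), 5 four-fold, 3 six-fold; Met and Trp are single-codon.
_CLASS_WEIGHT = {2: 9, 3: 1, 4: 5, 6: 3}


def effective_number_of_codons(cds_sequence: str) -> Optional[float]:
    """Compute Nc for a CDS nucleotide sequence.

    The sequence is read in codons from the first base (trailing partial
    codon trimmed); codons containing ambiguous bases and stop codons are
    skipped.  Amino acids observed fewer than twice, or with a degenerate
    homozygosity estimate F <= 0, do not contribute to their class average.
    When no three-fold class estimate is available (Ile unobserved), F3 is
    interpolated as the mean of F2 and F4.  Returns ``None`` when the
    statistic is undefined (no scorable codons or an empty required class).
    """
    seq = cds_sequence.upper().replace("U", "T")
    counts: dict[str, dict[str, int]] = {}
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if not set(codon) <= _VALID:
            continue
        aa = _CODON_TO_AA.get(codon)
        if aa is None:  # stop codon
            continue
        counts.setdefault(aa, {})
        counts[aa][codon] = counts[aa].get(codon, 0) + 1

    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codon_counts in counts.items():
        k = len(_FAMILIES[aa])
        if k == 1:
            continue
        n = sum(codon_counts.values())
        if n < 2:
            continue
        sum_p2 = sum((c / n) ** 2 for c in codon_counts.values())
        f = (n * sum_p2 - 1) / (n - 1)
        if f > 0:
            f_by_class[k].append(f)

    fbar: dict[int, float] = {
        k: sum(v) / len(v) for k, v in f_by_class.items() if v
    }
    if 2 not in fbar or 4 not in fbar or 6 not in fbar:
        return None
    if 3 not in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    nc = 2.0 + sum(_CLASS_WEIGHT[k] / fbar[k] for k in (2, 3, 4, 6))
    return min(nc, 61.0)
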