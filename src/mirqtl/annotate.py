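"""Functional annotation of SNPs relative to gene models.

Every SNP receives exactly one of eight categories: utr3, utr5, intronic,
coding_synonymous, coding_nonsynonymous, upstream, downstream, intergenic.
When a SNP overlaps features of several genes, a fixed precedence applies
(coding > utr3 > utr5 > intronic > upstream > downstream > intergenic),
chosen so that the screen's target class (utr3) is never shadowed by an
intron call from an overlapping gene. Coding SNPs are sub-classified by
translating the affected codon with the standard genetic code; for
minus-strand genes the allele is complemented before substitution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.Seq import Seq

from .core import GeneModel, Variant, complement

CATEGORIES = ("utr3", "utr5", "intronic", "coding_synonymous",
              "coding_nonsynonymous", "upstream", "downstream", "intergenic")

#: precedence rank; lower wins. Both coding labels share the top rank.
_RANK = {"coding": 0, "utr3": 1, "utr5": 2, "intronic": 3,
         "upstream": 4, "downstream": 5}


@dataclass
class SnpAnnotation:
    rsid: str
    gene_id: str
    category: str
    in_target_gene: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def cds_index_of(model: GeneModel, pos: int) -> int:
    """0-based index of a genomic position within the spliced CDS
    (transcript orientation)."""
    ivs = model.cds if model.strand == "+" else model.cds[::-1]
    idx = 0
    for s, e in ivs:
        if s <= pos < e:
            return idx + (pos - s if model.strand == "+" else e - 1 - pos)
        idx += e - s
    raise ValueError(f"position {pos} not in CDS of {model.gene_id}")


def classify_coding_effect(model: GeneModel, v: Variant,
                           cds_sequence: str) -> str:
    """'coding_synonymous' or 'coding_nonsynonymous' by codon translation.

    ``cds_sequence`` is the spliced CDS in mRNA sense orientation.
    """
    if len(cds_sequence) % 3:
        raise ValueError(f"{model.gene_id}: CDS length not divisible by 3")
    i = cds_index_of(model, v.pos)
    ref, alt = v.ref_allele, v.alt_allele
    if model.strand == "-":
        ref, alt = complement(ref), complement(alt)
    if cds_sequence[i].upper() != ref:
        raise ValueError(
            f"{v.rsid}: CDS base {cds_sequence[i]} at index {i} does not "
            f"match variant ref {ref} (sense strand)"
        )
    codon_start = 3 * (i // 3)
    codon_ref = cds_sequence[codon_start:codon_start + 3]
    k = i - codon_start
    codon_alt = codon_ref[:k] + alt + codon_ref[k + 1:]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    return "coding_synonymous" if aa_ref == aa_alt else "coding_nonsynonymous"


def _gene_category(v: Variant, m: GeneModel, flank_bp: int) -> str | None:
    """This gene's best label for the SNP, or None if out of reach."""
    if m.contains(v.pos):
        if m.in_intervals(v.pos, m.cds):
            return "coding"
        if m.in_intervals(v.pos, m.utr3):
            return "utr3"
        if m.in_intervals(v.pos, m.utr5):
            return "utr5"
        return "intronic"
    # strand-aware flanks measured from the gene-body boundaries
    if m.strand == "+":
        upstream = m.start - flank_bp <= v.pos < m.start
        downstream = m.end <= v.pos < m.end + flank_bp
    else:
        upstream = m.end <= v.pos < m.end + flank_bp
        downstream = m.start - flank_bp <= v.pos < m.start
    if upstream:
        return "upstream"
    if downstream:
        return "downstream"
    return None


def annotate_snp(v: Variant, models: list[GeneModel], flank_bp: int = 2000,
                 cds_sequences: dict[str, str] | None = None,
                 target_genes: set[str] | None = None) -> SnpAnnotation:
    """Assign the single highest-precedence category across all gene models.

    Ties at equal precedence resolve to the lexicographically smallest
    gene_id for determinism. ``cds_sequences`` (gene_id -> spliced sense
    CDS) is required only when a SNP actually lands in a CDS.
    """
    best: tuple[int, str, str, GeneModel] | None = None
    for m in models:
        if m.chrom != v.chrom:
            continue
        cat = _gene_category(v, m, flank_bp)
        if cat is None:
            continue
        key = (_RANK[cat], m.gene_id)
        if best is None or key < (best[0], best[2]):
            best = (_RANK[cat], cat, m.gene_id, m)
    if best is None:
        return SnpAnnotation(v.rsid, "", "intergenic", False)
    _, cat, gene_id, model = best
    if cat == "coding":
        if not cds_sequences or gene_id not in cds_sequences:
            raise ValueError(
                f"{v.rsid} lies in the CDS of {gene_id}; a CDS sequence is "
                "required to classify the coding effect"
            )
        cat = classify_coding_effect(model, v, cds_sequences[gene_id])
    in_target = bool(target_genes) and gene_id in (target_genes or set())
    return SnpAnnotation(v.rsid, gene_id, cat, in_target)


def partition_report(annotations: list[SnpAnnotation]) -> dict[str, int]:
    """Counts per category; sums to the input size by construction."""
    counts = {cat: 0 for cat in CATEGORIES}
    counts.update(Counter(a.category for a in annotations))
    assert sum(counts.values()) == len(annotations)
    return counts


def filter_utr3_in_genes_of_interest(
        annotations: list[SnpAnnotation],
        genes_of_interest: list[str]) -> tuple[list[SnpAnnotation], int]:
    """3'-UTR SNPs inside the study's genes of interest.

    Returns the kept annotations and the number of distinct genes they
    fall in; 3'-UTR SNPs of nearby genes outside the list are excluded.
    """
    if not genes_of_interest:
        raise ValueError("gene list must be non-empty")
    wanted = set(genes_of_interest)
    kept = [a for a in annotations if a.category == "utr3" and a.gene_id in wanted]
    return kept, len({a.gene_id for a in kept})
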