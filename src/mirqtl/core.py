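"""Shared domain types and coordinate conventions.

All internal interval arithmetic is 0-based half-open; file readers convert
from each format's native convention (VCF/GTF are 1-based closed, BED is
0-based half-open) on the way in, and writers convert back on the way out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DNA = set("ACGT")
RNA = set("ACGU")

#: sentinel for a missing genotype dosage
MISSING = -1

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class Variant:
    """One biallelic SNP.

    ``pos`` is the 0-based genomic position (converted from the 1-based VCF
    POS on read). ``maf`` is the folded minor-allele frequency in [0, 0.5].
    """

    chrom: str
    pos: int
    rsid: str
    ref_allele: str
    alt_allele: str
    maf: float = 0.0

    def __post_init__(self) -> None:
        if self.ref_allele not in DNA or self.alt_allele not in DNA:
            raise ValueError(
                f"{self.rsid}: alleles must be single DNA bases, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.rsid}: maf {self.maf} outside [0, 0.5]")


@dataclass
class GenotypeMatrix:
    """Diploid dosages (samples x variants), values in {0,1,2} or MISSING."""

    sample_ids: list[str]
    variants: list[Variant]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        ok = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2} or the missing sentinel")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, j: int) -> np.ndarray:
        return self.dosages[:, j]

    def index_of(self, rsid: str) -> int:
        for j, v in enumerate(self.variants):
            if v.rsid == rsid:
                return j
        raise KeyError(rsid)


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (haplotypes x variants), 0=ref, 1=alt.

    Haplotypes come in consecutive pairs, two per diploid sample.
    """

    haplotype_ids: list[str]
    variants: list[Variant]
    alleles: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.haplotype_ids), len(self.variants)):
            raise ValueError("allele matrix shape does not match id lists")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be strictly binary")
        if len(self.haplotype_ids) % 2:
            raise ValueError("odd haplotype count; diploid pairs expected")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    def column(self, j: int) -> np.ndarray:
        return self.alleles[:, j]

    def index_of(self, rsid: str) -> int:
        for j, v in enumerate(self.variants):
            if v.rsid == rsid:
                return j
        raise KeyError(rsid)

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse haplotype pairs into a dosage matrix."""
        dos = self.alleles[0::2] + self.alleles[1::2]
        sample_ids = [hid.rsplit("_", 1)[0] for hid in self.haplotype_ids[0::2]]
        return GenotypeMatrix(sample_ids, list(self.variants), dos)


@dataclass
class ExpressionMatrix:
    """Real-valued expression (samples x features) for one tissue."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    tissue: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("expression matrix shape does not match id lists")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    def feature(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(feature_id)]


Interval = tuple[int, int]  # 0-based half-open


def _check_disjoint(ivs: list[Interval], label: str) -> None:
    ivs = sorted(ivs)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError(f"{label} intervals overlap: {(s1, e1)} and {(s2, e2)}")


def _covered(inner: list[Interval], outer: list[Interval]) -> bool:
    """True if the union of `inner` lies inside the union of `outer`."""
    outer = sorted(outer)
    for s, e in sorted(inner):
        if not any(os <= s and e <= oe for os, oe in outer):
            # may still be covered by a union of adjacent outer intervals;
            # exons are disjoint so single-interval containment suffices
            return False
    return True


@dataclass
class GeneModel:
    """Single-transcript gene model with derived UTRs.

    Intervals are 0-based half-open genomic coordinates, sorted ascending
    regardless of strand. ``tss``/``tes`` are the genomic positions of the
    first and last transcribed base (strand-aware).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model has no exons")
        self.exons = sorted(tuple(iv) for iv in self.exons)
        self.cds = sorted(tuple(iv) for iv in self.cds)
        for ivs, label in ((self.exons, "exon"), (self.cds, "CDS")):
            _check_disjoint(ivs, f"{self.gene_id} {label}")
            for s, e in ivs:
                if s >= e:
                    raise ValueError(f"{self.gene_id}: empty {label} interval {(s, e)}")
        if self.cds and not _covered(self.cds, self.exons):
            raise ValueError(f"{self.gene_id}: CDS outside exons")
        if not self.utr5 and not self.utr3 and self.cds:
            self.utr5, self.utr3 = derive_utrs(self.exons, self.cds, self.strand)
        self.utr5 = sorted(tuple(iv) for iv in self.utr5)
        self.utr3 = sorted(tuple(iv) for iv in self.utr3)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def in_intervals(self, pos: int, ivs: list[Interval]) -> bool:
        return any(s <= pos < e for s, e in ivs)


def derive_utrs(
    exons: list[Interval], cds: list[Interval], strand: str
) -> tuple[list[Interval], list[Interval]]:
    """Subtract the CDS from the exons and split the remainder into UTRs.

    Exonic sequence 5' of the CDS (in transcript orientation) is the 5'-UTR,
    sequence 3' of it the 3'-UTR.
    """
    cds_start = min(s for s, _ in cds)
    cds_end = max(e for _, e in cds)
    left: list[Interval] = []
    right: list[Interval] = []
    for s, e in exons:
        if s < cds_start:
            left.append((s, min(e, cds_start)))
        if e > cds_end:
            right.append((max(s, cds_end), e))
    if strand == "+":
        return left, right
    return right, left


@dataclass
class Utr3Record:
    """A 3'-UTR sequence in mRNA sense orientation with its genomic map.

    ``genomic_positions[i]`` is the genomic coordinate of sequence base
    ``i``; for minus-strand genes the map descends and the stored base is
    the complement of the genomic reference base.
    """

    gene_id: str
    sequence: str
    genomic_positions: np.ndarray
    chrom: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        self.sequence = rna_to_dna(self.sequence)
        if set(self.sequence) - DNA:
            raise ValueError(f"{self.gene_id}: UTR alphabet outside ACGT")
        self.genomic_positions = np.asarray(self.genomic_positions, dtype=np.int64)
        if len(self.genomic_positions) != len(self.sequence):
            raise ValueError(f"{self.gene_id}: coordinate map length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    def offset_of(self, genomic_pos: int) -> int:
        """UTR offset of a genomic position; KeyError if outside the UTR."""
        hits = np.nonzero(self.genomic_positions == genomic_pos)[0]
        if len(hits) != 1:
            raise KeyError(f"position {genomic_pos} not in 3'-UTR of {self.gene_id}")
        return int(hits[0])

    def sense_alleles(self, v: Variant) -> tuple[str, str]:
        """Ref/alt alleles of `v` expressed on the mRNA sense strand."""
        if self.strand == "+":
            return v.ref_allele, v.alt_allele
        return complement(v.ref_allele), complement(v.alt_allele)


@dataclass(frozen=True)
class MicroRNA:
    """A mature miRNA; the seed is nucleotides 2-8 of the mature sequence."""

    name: str
    mature_sequence: str

    def __post_init__(self) -> None:
        seq = self.mature_sequence.upper().replace("T", "U")
        object.__setattr__(self, "mature_sequence", seq)
        if len(seq) < 8:
            raise ValueError(f"{self.name}: mature sequence shorter than 8 nt")
        if set(seq) - RNA:
            raise ValueError(f"{self.name}: mature alphabet outside ACGU")

    @property
    def seed(self) -> str:
        """Seed region, miR positions 2-8 (1-based), 5'->3' RNA."""
        return self.mature_sequence[1:8]


def compute_maf(g: GenotypeMatrix, j: int) -> float:
    """Folded minor-allele frequency of variant column ``j``.

    min(p, 1-p) with p the alt-allele frequency over non-missing calls;
    invariant under swapping the ref/alt labels.
    """
    col = g.column(j)
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError(f"variant {g.variants[j].rsid}: all genotypes missing")
    p = float(obs.sum()) / (2 * obs.size)
    return min(p, 1.0 - p)
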