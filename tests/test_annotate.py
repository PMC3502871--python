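"""Eight-way SNP annotation, codon effects, and the partition accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirqtl.annotate import (CATEGORIES, SnpAnnotation, annotate_snp,
                             classify_coding_effect,
                             filter_utr3_in_genes_of_interest,
                             partition_report)
from mirqtl.core import GeneModel, Variant, revcomp

from oracles import oracle_coding_effect


def v_at(pos, ref="A", alt="G", rsid="rs1", chrom="chr1"):
    return Variant(chrom, pos, rsid, ref, alt)


class TestAnnotateSnp:
    def setup_method(self):
        # + strand gene: exon [1000,2000), CDS [1300,1600)
        self.gene = GeneModel("gA", "chr1", "+", exons=[(1000, 2000)],
                              cds=[(1300, 1600)])

    def test_utr3_and_utr5_calls(self):
        assert annotate_snp(v_at(1700), [self.gene]).category == "utr3"
        assert annotate_snp(v_at(1100), [self.gene]).category == "utr5"

    def test_upstream_within_flank_plus_strand(self):
        # 1,500 bp 5' of the TSS with a 2,000 bp flank
        ann = annotate_snp(v_at(1000 - 1500), [self.gene], flank_bp=2000)
        assert ann.category == "upstream"

    def test_upstream_is_strand_aware(self):
        minus = GeneModel("gM", "chr1", "-", exons=[(1000, 2000)],
                          cds=[(1300, 1600)])
        assert annotate_snp(v_at(2000 + 500), [minus]).category == "upstream"
        assert annotate_snp(v_at(1000 - 500), [minus]).category == "downstream"

    def test_beyond_flank_is_intergenic(self):
        ann = annotate_snp(v_at(1000 - 2500), [self.gene], flank_bp=2000)
        assert ann.category == "intergenic"
        assert ann.gene_id == ""

    def test_utr3_beats_intron_of_overlapping_gene(self):
        # gene B's intron spans gene A's 3'-UTR position
        gene_b = GeneModel("gB", "chr1", "+", exons=[(500, 600), (3000, 3100)],
                           cds=[(520, 580)])
        ann = annotate_snp(v_at(1700), [gene_b, self.gene])
        assert ann.category == "utr3"
        assert ann.gene_id == "gA"

    def test_intronic_inside_gene_outside_exons(self):
        two_exon = GeneModel("gI", "chr1", "+", exons=[(1000, 1200), (1800, 2000)],
                             cds=[(1050, 1200), (1800, 1900)])
        assert annotate_snp(v_at(1500), [two_exon]).category == "intronic"

    def test_coding_requires_cds_sequence(self):
        with pytest.raises(ValueError, match="CDS sequence"):
            annotate_snp(v_at(1400), [self.gene])

    def test_strand_mirror_symmetry(self):
        """Reflecting gene and SNPs through a coordinate mirror and flipping
        strand leaves every category unchanged."""
        L = 10_000
        plus = GeneModel("g", "chr1", "+", exons=[(1000, 1200), (1800, 2000)],
                         cds=[(1050, 1200), (1800, 1900)])
        minus = GeneModel("g", "chr1", "-",
                          exons=[(L - e, L - s) for s, e in plus.exons],
                          cds=[(L - e, L - s) for s, e in plus.cds])
        # non-CDS positions only: codon classes need sequence, geometry is
        # the point here
        for pos in (500, 999, 1020, 1500, 1950, 2500, 4500):
            a_plus = annotate_snp(v_at(pos), [plus], flank_bp=1000)
            a_minus = annotate_snp(v_at(L - 1 - pos), [minus], flank_bp=1000)
            assert a_plus.category == a_minus.category, pos


class TestClassifyCodingEffect:
    def setup_method(self):
        # CDS 1300..1600 on + strand, single exon
        self.gene = GeneModel("gA", "chr1", "+", exons=[(1000, 2000)],
                              cds=[(1300, 1600)])

    def _cds(self, seq300):
        assert len(seq300) == 300
        return seq300

    def test_third_position_gaa_to_gag_synonymous(self):
        cds = "GAA" * 100
        v = v_at(1302, ref="A", alt="G")  # third base of first codon
        assert classify_coding_effect(self.gene, v, cds) == "coding_synonymous"

    def test_second_position_gaa_to_gta_nonsynonymous(self):
        cds = "GAA" * 100
        v = v_at(1301, ref="A", alt="T")
        assert classify_coding_effect(self.gene, v, cds) == \
            "coding_nonsynonymous"

    def test_minus_strand_complements_allele(self):
        # sense codon GGC -> AGC (Gly -> Ser); genomic alleles are
        # complemented: sense first base G is genomic C at the CDS 3' end
        gene = GeneModel("gM", "chr1", "-", exons=[(1000, 2000)],
                         cds=[(1300, 1600)])
        cds = "GGC" + "GAA" * 99
        # sense index 0 maps to genomic position 1599 on the minus strand
        v = v_at(1599, ref="C", alt="T")  # sense G -> A
        assert classify_coding_effect(gene, v, cds) == "coding_nonsynonymous"

    def test_cds_not_multiple_of_three_errors(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            classify_coding_effect(self.gene, v_at(1300), "GAAG")

    def test_snp_outside_cds_errors(self):
        with pytest.raises(ValueError, match="not in CDS"):
            classify_coding_effect(self.gene, v_at(1700), "GAA" * 100)

    def test_agrees_with_full_cds_translation_oracle(self):
        rng = np.random.default_rng(77)
        bases = "ACGT"
        for _ in range(60):
            cds = "ATG" + "".join(rng.choice(list(bases), size=294)) + "TAA"
            i = int(rng.integers(3, 297))  # stay off start/stop for clarity
            ref = cds[i]
            alt = rng.choice([b for b in bases if b != ref])
            v = v_at(1300 + i, ref=ref, alt=str(alt))
            assert classify_coding_effect(self.gene, v, cds) == \
                oracle_coding_effect(cds, i, str(alt))


class TestPartitionReport:
    def test_published_eight_way_partition_sums_to_308(self):
        sizes = {"utr3": 20, "utr5": 3, "intronic": 171,
                 "coding_synonymous": 8, "coding_nonsynonymous": 6,
                 "upstream": 12, "downstream": 15, "intergenic": 73}
        annots = [SnpAnnotation(f"rs{c}_{i}", "g" if c != "intergenic" else "",
                                c) for c, n in sizes.items() for i in range(n)]
        counts = partition_report(annots)
        assert counts == sizes
        assert sum(counts.values()) == 308

    def test_empty_input_all_zero(self):
        assert sum(partition_report([]).values()) == 0

    @given(st.lists(st.sampled_from(CATEGORIES), max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_partition_property_sum_equals_size(self, cats):
        annots = [SnpAnnotation(f"rs{i}", "g" if c != "intergenic" else "", c)
                  for i, c in enumerate(cats)]
        assert sum(partition_report(annots).values()) == len(cats)


class TestFilterUtr3InGenesOfInterest:
    def test_published_27_of_112_in_14_genes(self):
        goi = [f"XMET{i}" for i in range(14)]
        annots = []
        # 27 3'-UTR SNPs spread over the 14 genes of interest
        for i in range(27):
            annots.append(SnpAnnotation(f"rs_goi{i}", goi[i % 14], "utr3", True))
        # 85 3'-UTR SNPs in nearby genes
        for i in range(85):
            annots.append(SnpAnnotation(f"rs_near{i}", f"OTHER{i}", "utr3"))
        assert sum(1 for a in annots if a.category == "utr3") == 112
        kept, n_genes = filter_utr3_in_genes_of_interest(annots, goi)
        assert (len(kept), n_genes) == (27, 14)

    def test_no_matches_empty(self):
        annots = [SnpAnnotation("rs1", "OTHER", "utr3")]
        kept, n_genes = filter_utr3_in_genes_of_interest(annots, ["XMET1"])
        assert (kept, n_genes) == ([], 0)

    def test_single_gene(self):
        annots = [SnpAnnotation(f"rs{i}", "XMET1", "utr3") for i in range(5)]
        kept, n_genes = filter_utr3_in_genes_of_interest(annots, ["XMET1"])
        assert (len(kept), n_genes) == (5, 1)

    def test_empty_gene_list_errors(self):
        with pytest.raises(ValueError):
            filter_utr3_in_genes_of_interest([], [])
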