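"""Domain types, MAF arithmetic, and file-format round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirqtl import io
from mirqtl.core import (GeneModel, GenotypeMatrix, HaplotypePanel, Utr3Record,
                         Variant, compute_maf)


def make_gm(dosages):
    d = np.asarray(dosages).reshape(-1, 1)
    v = Variant("chr1", 10, "rs1", "A", "G")
    return GenotypeMatrix([f"s{i}" for i in range(len(d))], [v], d)


class TestVariant:
    def test_rejects_identical_alleles(self):
        with pytest.raises(ValueError):
            Variant("chr1", 5, "rs1", "A", "A")

    def test_rejects_non_dna_alleles_and_bad_maf(self):
        with pytest.raises(ValueError):
            Variant("chr1", 5, "rs1", "A", "N")
        with pytest.raises(ValueError):
            Variant("chr1", 5, "rs1", "A", "G", maf=0.7)


class TestComputeMaf:
    @pytest.mark.parametrize("dosages,expected", [
        ([0, 0, 0, 0], 0.0),          # monomorphic ref
        ([2, 2, 2, 2], 0.0),          # alt frequency 1 folds to 0
        ([0, 1, 1, 2], 0.5),          # 4 alt alleles over 8 chromosomes
    ])
    def test_worked_examples(self, dosages, expected):
        assert compute_maf(make_gm(dosages), 0) == pytest.approx(expected)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="missing"):
            compute_maf(make_gm([-1, -1, -1]), 0)

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_invariant_under_allele_label_swap(self, dosages):
        flipped = [2 - d for d in dosages]
        assert compute_maf(make_gm(dosages), 0) == pytest.approx(
            compute_maf(make_gm(flipped), 0))


class TestGeneModelUtrDerivation:
    def test_plus_strand_single_exon(self, single_exon_gene):
        # exon 101-200, CDS 131-170 (1-based closed): UTR5 101-130, UTR3 171-200
        assert single_exon_gene.utr5 == [(100, 130)]
        assert single_exon_gene.utr3 == [(170, 200)]

    def test_minus_strand_flips_utrs(self):
        g = GeneModel("geneB", "chr1", "-", exons=[(100, 200)], cds=[(130, 170)])
        assert g.utr3 == [(100, 130)]
        assert g.utr5 == [(170, 200)]

    def test_cds_outside_exons_errors(self):
        with pytest.raises(ValueError, match="CDS outside exons"):
            GeneModel("bad", "chr1", "+", exons=[(100, 200)], cds=[(250, 280)])

    def test_no_exons_errors(self):
        with pytest.raises(ValueError, match="no exons"):
            GeneModel("bad", "chr1", "+", exons=[])


class TestGeneModelIo:
    GTF = ('chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
           'chr1\tsrc\tCDS\t131\t170\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n')
    BED = "chr1\t100\t200\tg1\t0\t+\t130\t170\t0\t1\t100\t0\n"

    def test_gtf_and_bed12_dialects_equivalent(self, tmp_path):
        (tmp_path / "m.gtf").write_text(self.GTF)
        (tmp_path / "m.bed").write_text(self.BED)
        g_gtf = io.read_gene_models(tmp_path / "m.gtf")[0]
        g_bed = io.read_gene_models(tmp_path / "m.bed")[0]
        assert g_gtf.exons == g_bed.exons == [(100, 200)]
        assert g_gtf.cds == g_bed.cds == [(130, 170)]
        assert g_gtf.utr5 == g_bed.utr5 and g_gtf.utr3 == g_bed.utr3

    def test_cds_without_exon_lines_errors(self, tmp_path):
        bad = 'chr1\tsrc\tCDS\t131\t170\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
        (tmp_path / "bad.gtf").write_text(bad)
        with pytest.raises(ValueError, match="no exon lines"):
            io.read_gene_models(tmp_path / "bad.gtf")

    def test_round_trip_both_formats(self, tmp_path):
        g = GeneModel("g2", "chr2", "-", exons=[(50, 120), (200, 320)],
                      cds=[(80, 120), (200, 260)])
        io.write_gtf([g], tmp_path / "rt.gtf")
        io.write_bed12([g], tmp_path / "rt.bed")
        for path in (tmp_path / "rt.gtf", tmp_path / "rt.bed"):
            back = io.read_gene_models(path)[0]
            assert (back.exons, back.cds, back.utr5, back.utr3, back.strand) \
                == (g.exons, g.cds, g.utr5, g.utr3, g.strand)


VCF_HEADER = ("##fileformat=VCFv4.2\n"
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
              "##contig=<ID=chr1>\n"
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB\n")


class TestHaplotypePanelIo:
    def test_two_sample_two_snp_dimensions(self, tmp_path):
        body = ("chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
                "chr1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1\n")
        (tmp_path / "p.vcf").write_text(VCF_HEADER + body)
        panel = io.read_haplotype_panel(tmp_path / "p.vcf")
        assert panel.n_haplotypes == 4
        assert len(panel.variants) == 2
        assert panel.column(0).tolist() == [0, 1, 1, 1]

    def test_indel_among_snps_skipped_with_count(self, tmp_path):
        body = ("chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
                "chr1\t150\trs_indel\tAT\tA\t.\tPASS\t.\tGT\t0|1\t1|1\n"
                "chr1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1\n")
        (tmp_path / "p.vcf").write_text(VCF_HEADER + body)
        panel = io.read_haplotype_panel(tmp_path / "p.vcf")
        assert len(panel.variants) == 2
        assert panel.n_skipped == 1

    def test_unphased_genotype_errors_naming_record(self, tmp_path):
        body = "chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1\n"
        (tmp_path / "p.vcf").write_text(VCF_HEADER + body)
        with pytest.raises(ValueError, match="rs1"):
            io.read_haplotype_panel(tmp_path / "p.vcf")

    def test_round_trip(self, tmp_path):
        variants = [Variant("chr1", 99, "rs1", "A", "G", maf=0.25),
                    Variant("chr1", 199, "rs2", "C", "T", maf=0.25)]
        alleles = np.array([[0, 1], [1, 0], [1, 1], [0, 0]], dtype=np.int8)
        panel = HaplotypePanel(["sA_1", "sA_2", "sB_1", "sB_2"], variants, alleles)
        io.write_haplotype_panel(panel, tmp_path / "rt.vcf")
        back = io.read_haplotype_panel(tmp_path / "rt.vcf")
        assert np.array_equal(back.alleles, panel.alleles)
        assert [v.rsid for v in back.variants] == ["rs1", "rs2"]
        assert [v.pos for v in back.variants] == [99, 199]

    def test_collapse_to_genotypes(self):
        variants = [Variant("chr1", 99, "rs1", "A", "G")]
        alleles = np.array([[0], [1], [1], [1]], dtype=np.int8)
        panel = HaplotypePanel(["sA_1", "sA_2", "sB_1", "sB_2"], variants, alleles)
        gm = panel.to_genotypes()
        assert gm.dosages[:, 0].tolist() == [1, 2]
        assert gm.sample_ids == ["sA", "sB"]


class TestUtr3Record:
    def test_minus_strand_sense_alleles_and_offsets(self):
        rec = Utr3Record("g", "ACGT", np.array([103, 102, 101, 100]),
                         chrom="chr1", strand="-")
        v = Variant("chr1", 102, "rs9", "G", "A")  # genomic G -> sense C
        assert rec.offset_of(102) == 1
        assert rec.sense_alleles(v) == ("C", "T")

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            Utr3Record("g", "ACGT", np.array([1, 2, 3]))
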