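"""Seed-site scanners, allele-specific effect calls, and consensus."""

import numpy as np
import pytest

from mirqtl.core import MicroRNA, Utr3Record, Variant, revcomp
from mirqtl.mirtarget import (MirSnpCall, classify_snp_effect, consensus,
                              scan_exact_match, scan_taxonomy, site_sequence)
from mirqtl.synth import gen_mir_catalog

from oracles import oracle_exact_match, oracle_site_sequence, oracle_taxonomy


class TestSiteSequence:
    @pytest.mark.parametrize("site_type,expected", [
        ("7mer_m8", "CTACCTC"),
        ("8mer", "CTACCTCA"),
        ("7mer_A1", "TACCTCA"),
    ])
    def test_let7_worked_examples(self, let7, site_type, expected):
        assert site_sequence(let7, site_type) == expected

    def test_matches_biopython_oracle_for_random_mirs(self, catalog):
        for mir in catalog:
            for st in ("8mer", "7mer_m8", "7mer_A1"):
                assert site_sequence(mir, st) == \
                    oracle_site_sequence(mir.mature_sequence, st)

    def test_short_mature_errors(self):
        with pytest.raises(ValueError):
            MicroRNA("tiny", "UGAGGUA")


class TestScanTaxonomy:
    def test_8mer_found_and_subsumes_7mers(self, let7):
        calls = scan_taxonomy("AAACTACCTCAAAA", [let7])
        assert [(c.site_type, c.utr_start, c.utr_end) for c in calls] == \
            [("8mer", 3, 11)]

    def test_7mer_m8_without_terminal_a(self, let7):
        calls = scan_taxonomy("AACTACCTCG", [let7])
        assert [(c.site_type, c.utr_start) for c in calls] == [("7mer_m8", 2)]

    def test_7mer_a1_alone(self, let7):
        # TACCTCA present, full CTACCTCA absent (G before it)
        calls = scan_taxonomy("AAGTACCTCAAA", [let7])
        assert [(c.site_type, c.utr_start) for c in calls] == [("7mer_A1", 3)]

    def test_poly_a_utr_empty(self, catalog):
        assert scan_taxonomy("A" * 60, catalog) == []

    def test_u_t_equivalence(self, let7):
        as_rna = "AAACUACCUCAAAA"
        as_dna = "AAACTACCTCAAAA"
        mir_dna = MicroRNA("let7-dna", "TGAGGTAGTAGGTTGTATAGTT")
        for seq in (as_rna, as_dna):
            for mir in (let7, mir_dna):
                calls = scan_taxonomy(seq, [mir])
                assert [(c.site_type, c.utr_start) for c in calls] == \
                    [("8mer", 3)]

    def test_antisense_orientation_never_reported(self, catalog):
        rng = np.random.default_rng(8)
        for _ in range(20):
            utr = "".join(rng.choice(list("ACGT"), size=300))
            sense = {(c.mir_name, c.utr_start) for c in scan_taxonomy(utr, catalog)}
            anti = {(c.mir_name, c.utr_start)
                    for c in scan_taxonomy(revcomp(utr), catalog)}
            # a site found in the sense scan appears in the antisense scan
            # only by palindromic coincidence, never by construction
            for name, start in sense:
                assert (name, start) not in anti or utr != revcomp(utr)

    def test_reported_site_is_wc_partner_of_seed(self, let7, catalog):
        rng = np.random.default_rng(9)
        utr = "".join(rng.choice(list("ACGT"), size=500))
        utr = utr[:100] + "CTACCTCA" + utr[108:]
        for c in scan_taxonomy(utr, [let7] + catalog):
            mir = next(m for m in [let7] + catalog if m.name == c.mir_name)
            mature_dna = mir.mature_sequence.replace("U", "T")
            s, e = c.seed_span()
            span = utr[s:e]
            if c.site_type == "7mer_A1":
                assert revcomp(span) == mature_dna[1:7]
            else:
                assert revcomp(span) == mature_dna[1:8]


class TestScanExactMatch:
    def test_seven_mer_pairing_is_a_hit(self, let7):
        calls = scan_exact_match("GGCTACCTCGG", [let7])
        assert len(calls) == 1
        assert calls[0].match_len >= 7

    def test_six_mer_core_alone_is_not_a_hit(self, let7):
        # TACCTC pairs miR 2-7 only; 7-mer cutoff excludes it
        assert scan_exact_match("GGGTACCTCGGG".replace("GTACCTCG", "GTACCTGG"),
                                [let7]) == []
        assert scan_exact_match("AATACCTCTT", [let7]) == []

    def test_min_match_len_8_drops_7mer_matches(self, let7):
        seq = "GGCTACCTCGG"  # best contiguous match is exactly 7
        assert scan_exact_match(seq, [let7], min_match_len=7) != []
        assert scan_exact_match(seq, [let7], min_match_len=8) == []

    def test_agrees_with_pairing_oracle_on_random_sequences(self, catalog):
        rng = np.random.default_rng(10)
        for _ in range(30):
            utr = "".join(rng.choice(list("ACGT"), size=250))
            got = {(c.mir_name, c.utr_start + 6, c.match_len)
                   for c in scan_exact_match(utr, catalog)}
            want = oracle_exact_match(utr, catalog)
            want = {(n, u, m) for n, u, m in want}
            assert got == want


class TestClassifySnpEffect:
    def make_utr(self, seq):
        return Utr3Record("g", seq, np.arange(len(seq)), chrom="chr1")

    def test_change_8mer_to_7mer_m8(self, let7):
        seq = "GGGGGGGGGGCTACCTCAGGGGGGGGGG"
        utr = self.make_utr(seq)
        v = Variant("chr1", 17, "rs_c", "A", "G")  # the 8mer's terminal A
        call = classify_snp_effect(utr, v, let7, "taxonomy")
        assert call.effect == "change"
        assert not call.snp_in_seed  # the A1 position is outside the seed

    def test_create_by_completing_the_site(self, let7):
        seq = "GGGGGGGGGGCTACGTCAGGGGGGGGGG"  # CTACgTCA: one base off
        utr = self.make_utr(seq)
        v = Variant("chr1", 14, "rs_c", "G", "C")
        call = classify_snp_effect(utr, v, let7, "taxonomy")
        assert call.effect == "create"
        assert call.snp_in_seed

    def test_create_abolish_antisymmetry(self, let7):
        ref_seq = "GGGGGGGGGGCTACGTCAGGGGGGGGGG"
        alt_seq = "GGGGGGGGGGCTACCTCAGGGGGGGGGG"
        utr_ref = self.make_utr(ref_seq)
        utr_alt = self.make_utr(alt_seq)
        fwd = classify_snp_effect(utr_ref, Variant("chr1", 14, "r", "G", "C"),
                                  let7, "taxonomy")
        rev = classify_snp_effect(utr_alt, Variant("chr1", 14, "r", "C", "G"),
                                  let7, "taxonomy")
        assert (fwd.effect, rev.effect) == ("create", "abolish")

    def test_reference_mismatch_errors(self, let7):
        utr = self.make_utr("ACGTACGTACGT")
        with pytest.raises(ValueError, match="reference mismatch"):
            classify_snp_effect(utr, Variant("chr1", 0, "r", "G", "C"),
                                let7, "taxonomy")

    def test_minus_strand_utr_uses_sense_alleles(self, let7):
        seq = "GGGGGGGGGGCTACCTCAGGGGGGGGGG"
        n = len(seq)
        positions = np.arange(1000 + n - 1, 999, -1)  # descending map
        utr = Utr3Record("g", seq, positions, chrom="chr1", strand="-")
        # sense offset 14 (the C of CTACCTCA core) sits at genomic 1000+n-1-14
        gpos = int(positions[14])
        # sense C corresponds to genomic G on the minus strand
        v = Variant("chr1", gpos, "rs_m", "G", "C")  # sense C -> G: abolish
        call = classify_snp_effect(utr, v, let7, "taxonomy")
        assert call.effect in ("abolish", "change")

    def test_edge_truncated_window_is_no_site(self, let7):
        # only 6 nt of the site fit before the UTR end: never a match
        seq = "GGGGGGGGGGGGCTACCT"
        utr = self.make_utr(seq)
        v = Variant("chr1", 14, "rs_e", "A", "C")
        call = classify_snp_effect(utr, v, let7, "taxonomy")
        assert call.effect == "none"


class TestConsensus:
    @staticmethod
    def call(rsid, mir, effect, algo):
        return MirSnpCall(rsid, mir, effect, algo, True)

    def test_26_of_27_positive_in_both_algorithms(self):
        rsids = [f"rs_{i}" for i in range(26)] + ["rs11807"]
        exact = [self.call(r, "miR-x", "abolish", "exact_match") for r in rsids]
        tax = [self.call(r, "miR-x",
                         "none" if r == "rs11807" else "create", "taxonomy")
               for r in rsids]
        cons = consensus(exact, tax)
        assert sum(c.positive_both for c in cons) == 26
        assert len(cons) == 27

    def test_both_empty_not_positive(self):
        cons = consensus([self.call("rs1", "m", "none", "exact_match")],
                         [self.call("rs1", "m", "none", "taxonomy")])
        assert cons[0].positive_both is False

    def test_disjoint_mir_sets_positive_with_empty_intersection(self):
        cons = consensus([self.call("rs1", "miR-a", "create", "exact_match")],
                         [self.call("rs1", "miR-b", "abolish", "taxonomy")])
        assert cons[0].positive_both is True
        assert cons[0].mir_names_both == set()

    def test_coverage_mismatch_errors(self):
        with pytest.raises(ValueError, match="one algorithm only"):
            consensus([self.call("rs1", "m", "none", "exact_match")],
                      [self.call("rs2", "m", "none", "taxonomy")])


class TestScannerOracleEquivalence:
    def test_taxonomy_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for rep in range(40):
            catalog = gen_mir_catalog(int(rng.integers(2, 12)),
                                      seed=int(rng.integers(2**31)))
            utr = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 400))))
            got = {(c.mir_name, c.site_type, c.utr_start)
                   for c in scan_taxonomy(utr, catalog)}
            assert got == oracle_taxonomy(utr, catalog)
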