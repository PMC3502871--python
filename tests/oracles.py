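"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's scanner/LD/translation code paths:
site sequences are rebuilt with Biopython, window matching is exhaustive
enumeration, r^2 is the squared Pearson correlation, and coding effects
come from translating the full ref and alt CDS and diffing the proteins.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

WC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_site_sequence(mature_rna: str, site_type: str) -> str:
    """Site DNA string via Biopython reverse_complement (independent path)."""
    dna = Seq(mature_rna.replace("U", "T").replace("u", "t").upper())
    if site_type == "7mer_m8":
        return str(dna[1:8].reverse_complement())
    if site_type == "8mer":
        return str(dna[1:8].reverse_complement()) + "A"
    if site_type == "7mer_A1":
        return str(dna[1:7].reverse_complement()) + "A"
    raise ValueError(site_type)


def oracle_taxonomy(seq: str, catalog) -> set[tuple[str, str, int]]:
    """Every window of width 7/8 tested against every site string, with the
    longest-type rule applied at shared loci."""
    seq = seq.upper().replace("U", "T")
    out: set[tuple[str, str, int]] = set()
    for mir in catalog:
        s8 = oracle_site_sequence(mir.mature_sequence, "8mer")
        sm8 = oracle_site_sequence(mir.mature_sequence, "7mer_m8")
        sa1 = oracle_site_sequence(mir.mature_sequence, "7mer_A1")
        starts8 = {i for i in range(len(seq) - 7) if seq[i:i + 8] == s8}
        for i in starts8:
            out.add((mir.name, "8mer", i))
        for i in range(len(seq) - 6):
            if seq[i:i + 7] == sm8 and i not in starts8:
                out.add((mir.name, "7mer_m8", i))
            if seq[i:i + 7] == sa1 and (i - 1) not in starts8:
                out.add((mir.name, "7mer_A1", i))
    return out


def oracle_exact_match(seq: str, catalog, min_match_len: int = 7
                       ) -> set[tuple[str, int, int]]:
    """(mir, window start of seed core, match length) by per-base pairing.

    For each UTR position pairing miR position 2, count the contiguous run
    of Watson-Crick pairs toward the miR 3' end.
    """
    seq = seq.upper().replace("U", "T")
    out: set[tuple[str, int, int]] = set()
    for mir in catalog:
        mature = mir.mature_sequence.replace("U", "T")
        # UTR position u pairs miR position 2 when seq[u] == WC[mature[1]],
        # miR position k pairs UTR position u - (k - 2)
        for u in range(len(seq)):
            m = 0
            for k in range(2, len(mature) + 1):
                pos = u - (k - 2)
                if pos < 0 or seq[pos] != WC[mature[k - 1]]:
                    break
                m += 1
            if m >= min_match_len:
                out.add((mir.name, u, m))
    return out


def pearson_r2(hap_a, hap_b) -> float:
    return float(np.corrcoef(hap_a, hap_b)[0, 1] ** 2)


def oracle_coding_effect(cds_ref: str, cds_index: int, alt_sense: str) -> str:
    """Translate the whole ref and alt CDS and diff the proteins."""
    alt_cds = cds_ref[:cds_index] + alt_sense + cds_ref[cds_index + 1:]
    p_ref = str(Seq(cds_ref).translate())
    p_alt = str(Seq(alt_cds).translate())
    return "coding_synonymous" if p_ref == p_alt else "coding_nonsynonymous"
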