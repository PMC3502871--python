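"""Allele-specific miRNA target-site prediction and SNP effect calls.

Two scanners are implemented. ``scan_taxonomy`` follows the canonical
seed-site taxonomy: a site is an exact occurrence of the 8mer, 7mer-m8 or
7mer-A1 sequence implied by the miRNA seed (the reverse complement of miR
positions 2-8, with the 8mer and 7mer-A1 carrying an A opposite miR
position 1). ``scan_exact_match`` is a seed-anchored alignment mode: a hit
requires perfect Watson-Crick pairing of UTR bases to miR positions 2-7
extended contiguously toward the miR 3' end until the first mismatch, with
a configurable minimum matched length (default 7, i.e. 6mer matches are
never positive). Neither mode allows G:U wobble, and no context or
conservation scoring is applied.

``classify_snp_effect`` rescans a window around a 3'-UTR SNP under each
allele and diffs the site lists: an alt-only site creates, a ref-only site
abolishes, differing site type or position changes, identical lists mean
no effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import MicroRNA, Utr3Record, Variant, revcomp, rna_to_dna

SITE_TYPES = ("8mer", "7mer_m8", "7mer_A1")
SITE_WIDTH = {"8mer": 8, "7mer_m8": 7, "7mer_A1": 7}


@dataclass(frozen=True, order=True)
class SeedSiteCall:
    """One predicted site; coordinates are 0-based half-open in the UTR."""

    mir_name: str
    utr_start: int
    utr_end: int
    site_type: str
    allele_context: str = "ref"
    match_len: int = 7

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type}")
        if self.utr_end - self.utr_start != SITE_WIDTH[self.site_type]:
            raise ValueError("site width inconsistent with site type")
        if self.match_len < 7:
            raise ValueError("match_len below the 7-mer cutoff")

    def seed_span(self) -> tuple[int, int]:
        """UTR span pairing the miR seed (positions 2-8 / 2-7 for 7mer_A1).

        The A of 8mer/7mer_A1 sites sits opposite miR position 1 and is not
        part of the seed pairing.
        """
        if self.site_type == "8mer":
            return self.utr_start, self.utr_end - 1
        if self.site_type == "7mer_A1":
            return self.utr_start, self.utr_end - 1
        return self.utr_start, self.utr_end


@dataclass
class MirSnpCall:
    """SNP-level effect of one variant on one miRNA's predicted sites."""

    rsid: str
    mir_name: str
    effect: str  # create | abolish | change | none
    algorithm: str  # exact_match | taxonomy
    snp_in_seed: bool
    sites_ref: list[SeedSiteCall] = field(default_factory=list)
    sites_alt: list[SeedSiteCall] = field(default_factory=list)


@dataclass
class ConsensusCall:
    rsid: str
    mir_names_both: set[str]
    positive_both: bool


def site_sequence(mir: MicroRNA, site_type: str) -> str:
    """DNA sequence a UTR must contain to be a site of the given type.

    7mer_m8: reverse complement of miR positions 2-8; 8mer: the same
    followed by A; 7mer_A1: reverse complement of positions 2-7 followed
    by A.
    """
    mature = rna_to_dna(mir.mature_sequence)
    if len(mature) < 8:
        raise ValueError(f"{mir.name}: mature sequence shorter than 8 nt")
    if site_type == "7mer_m8":
        return revcomp(mature[1:8])
    if site_type == "8mer":
        return revcomp(mature[1:8]) + "A"
    if site_type == "7mer_A1":
        return revcomp(mature[1:7]) + "A"
    raise ValueError(f"unknown site type {site_type}")


def _find_all(text: str, pattern: str) -> list[int]:
    hits, i = [], text.find(pattern)
    while i != -1:
        hits.append(i)
        i = text.find(pattern, i + 1)
    return hits


def scan_taxonomy(utr: Utr3Record | str, catalog: list[MicroRNA],
                  allele_context: str = "ref") -> list[SeedSiteCall]:
    """All 8mer/7mer_m8/7mer_A1 occurrences for every catalog miRNA.

    At a shared locus only the longest type is reported: an 8mer subsumes
    the 7mer_m8 at its start and the 7mer_A1 one base downstream.
    """
    text = utr.sequence if isinstance(utr, Utr3Record) else rna_to_dna(utr)
    calls: list[SeedSiteCall] = []
    for mir in catalog:
        s8 = site_sequence(mir, "8mer")
        sm8 = site_sequence(mir, "7mer_m8")
        sa1 = site_sequence(mir, "7mer_A1")
        starts8 = set(_find_all(text, s8))
        for i in starts8:
            calls.append(SeedSiteCall(mir.name, i, i + 8, "8mer",
                                      allele_context, match_len=7))
        for i in _find_all(text, sm8):
            if i in starts8:
                continue  # subsumed by the 8mer at the same start
            calls.append(SeedSiteCall(mir.name, i, i + 7, "7mer_m8",
                                      allele_context, match_len=7))
        for i in _find_all(text, sa1):
            if i - 1 in starts8:
                continue  # the terminal 7 nt of an 8mer
            calls.append(SeedSiteCall(mir.name, i, i + 7, "7mer_A1",
                                      allele_context, match_len=7))
    calls.sort(key=lambda c: (c.utr_start, c.mir_name, c.site_type))
    return calls


def scan_exact_match(utr: Utr3Record | str, catalog: list[MicroRNA],
                     min_match_len: int = 7,
                     allele_context: str = "ref") -> list[SeedSiteCall]:
    """Seed-anchored contiguous-extension scan.

    Anchors at perfect pairing of miR positions 2-7, extends toward the miR
    3' end (the UTR 5' direction) until the first mismatch, and reports
    matches of length >= ``min_match_len``. Because a 7-mer extension
    necessarily reaches miR position 8, every hit is typed 8mer or 7mer_m8
    by the presence of an A opposite miR position 1.
    """
    if min_match_len < 7:
        raise ValueError("min_match_len must be >= 7")
    text = utr.sequence if isinstance(utr, Utr3Record) else rna_to_dna(utr)
    calls: list[SeedSiteCall] = []
    for mir in catalog:
        mature = rna_to_dna(mir.mature_sequence)
        core6 = revcomp(mature[1:7])  # pairs miR positions 2-7
        for i in _find_all(text, core6):
            m = 6
            j = i - 1  # UTR base pairing miR position m+2
            while j >= 0 and m + 1 < len(mature) \
                    and text[j] == revcomp(mature[m + 1]):
                m += 1
                j -= 1
            if m < min_match_len:
                continue
            # window/type follow the taxonomy convention for comparability
            has_a1 = i + 6 < len(text) and text[i + 6] == "A"
            if has_a1:
                calls.append(SeedSiteCall(mir.name, i - 1, i + 7, "8mer",
                                          allele_context, match_len=m))
            else:
                calls.append(SeedSiteCall(mir.name, i - 1, i + 6, "7mer_m8",
                                          allele_context, match_len=m))
    calls.sort(key=lambda c: (c.utr_start, c.mir_name, c.site_type))
    return calls


def _scan(mode: str, seq: str, catalog: list[MicroRNA], min_match_len: int,
          allele_context: str) -> list[SeedSiteCall]:
    if mode == "taxonomy":
        return scan_taxonomy(seq, catalog, allele_context)
    if mode == "exact_match":
        return scan_exact_match(seq, catalog, min_match_len, allele_context)
    raise ValueError(f"unknown scanner mode {mode!r}")


def classify_snp_effect(utr: Utr3Record, v: Variant, mir: MicroRNA,
                        mode: str = "taxonomy", min_match_len: int = 7,
                        rescan_window: int = 25,
                        change_includes_position: bool = True) -> MirSnpCall:
    """Classify a 3'-UTR SNP's effect on one miRNA's target sites.

    Both alleles are applied in turn to a window of ``rescan_window`` nt on
    each side of the SNP (clipped at the UTR edges; sites farther away
    cannot overlap the SNP) and the per-allele site lists are diffed.
    """
    off = utr.offset_of(v.pos)
    sense_ref, sense_alt = utr.sense_alleles(v)
    if utr.sequence[off] != sense_ref:
        raise ValueError(
            f"{v.rsid}: reference mismatch at {utr.gene_id} offset {off}: "
            f"UTR has {utr.sequence[off]}, variant ref (sense) is {sense_ref}"
        )
    lo = max(0, off - rescan_window)
    hi = min(len(utr.sequence), off + rescan_window + 1)
    window_ref = utr.sequence[lo:hi]
    window_alt = window_ref[: off - lo] + sense_alt + window_ref[off - lo + 1:]

    def rebase(calls: list[SeedSiteCall], ctx: str) -> list[SeedSiteCall]:
        return [SeedSiteCall(c.mir_name, c.utr_start + lo, c.utr_end + lo,
                             c.site_type, ctx, c.match_len) for c in calls]

    sites_ref = rebase(_scan(mode, window_ref, [mir], min_match_len, "ref"), "ref")
    sites_alt = rebase(_scan(mode, window_alt, [mir], min_match_len, "alt"), "alt")

    def key(c: SeedSiteCall):
        return (c.site_type, c.utr_start) if change_includes_position \
            else (c.site_type,)

    ref_keys = {key(c) for c in sites_ref}
    alt_keys = {key(c) for c in sites_alt}
    if ref_keys == alt_keys:
        effect = "none"
    elif sites_ref and sites_alt:
        effect = "change"
    elif sites_ref:
        effect = "abolish"
    else:
        effect = "create"

    implicated = ([c for c in sites_ref if key(c) not in alt_keys]
                  + [c for c in sites_alt if key(c) not in ref_keys])
    snp_in_seed = any(s <= off < e for s, e in (c.seed_span() for c in implicated))
    return MirSnpCall(v.rsid, mir.name, effect, mode, snp_in_seed,
                      sites_ref, sites_alt)


def classify_all(utr: Utr3Record, v: Variant, catalog: list[MicroRNA],
                 mode: str, min_match_len: int = 7, rescan_window: int = 25,
                 change_includes_position: bool = True) -> list[MirSnpCall]:
    """Effect calls for every miRNA in the catalog (including 'none' calls)."""
    return [classify_snp_effect(utr, v, mir, mode, min_match_len,
                                rescan_window, change_includes_position)
            for mir in catalog]


def consensus(calls_exact: list[MirSnpCall],
              calls_taxonomy: list[MirSnpCall]) -> list[ConsensusCall]:
    """Two-algorithm consensus per SNP.

    ``positive_both`` is true when each algorithm yields at least one
    non-none effect for the SNP; ``mir_names_both`` is the intersection of
    the miRNAs each algorithm implicates.
    """
    by_snp_exact: dict[str, list[MirSnpCall]] = {}
    by_snp_tax: dict[str, list[MirSnpCall]] = {}
    for c in calls_exact:
        by_snp_exact.setdefault(c.rsid, []).append(c)
    for c in calls_taxonomy:
        by_snp_tax.setdefault(c.rsid, []).append(c)
    if set(by_snp_exact) != set(by_snp_tax):
        only = set(by_snp_exact) ^ set(by_snp_tax)
        raise ValueError(f"SNPs covered by one algorithm only: {sorted(only)}")
    out = []
    for rsid in sorted(by_snp_exact):
        mirs_e = {c.mir_name for c in by_snp_exact[rsid] if c.effect != "none"}
        mirs_t = {c.mir_name for c in by_snp_tax[rsid] if c.effect != "none"}
        out.append(ConsensusCall(rsid, mirs_e & mirs_t,
                                 bool(mirs_e) and bool(mirs_t)))
    return out
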